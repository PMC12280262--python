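"""Forecasting engines and the one-step-ahead evaluation protocol.

Four engines share a common protocol: a zero-anomaly (climatological mean)
baseline, univariate Simplex projection with leave-one-out embedding-dimension
selection, Multiview embedding (an ensemble of small multivariate embeddings
ranked by in-sample skill), and an ARIMA(p,0,q) grid selected by AICc. All
engines train on the first 111 points of a 123-point standardized series and
issue one-step-ahead forecasts of points 112-123, always conditioning on the
observed (never the predicted) history.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class EmbeddingSpec:
    """A delay embedding: E lagged coordinates of one or more series.

    coordinates are (variable, lag) pairs; for a univariate embedding they
    are ((target, 0), (target, tau), ..., (target, (E-1)*tau)).
    """

    coordinates: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if len(self.coordinates) < 1:
            raise ValueError("embedding needs at least one coordinate")
        if len(set(self.coordinates)) != len(self.coordinates):
            raise ValueError("embedding coordinates must be unique")
        if any(lag < 0 for _, lag in self.coordinates):
            raise ValueError("lags must be >= 0")

    @property
    def dim(self) -> int:
        return len(self.coordinates)


@dataclass
class ForecastResult:
    """One-step-ahead predictions for the 12 test points of one series."""

    method: str
    target: str
    predictions: np.ndarray
    observations: np.ndarray
    hyperparams: dict = field(default_factory=dict)
    rmse_std: float = np.nan
    rmse_orig: float | None = None


# ---------------------------------------------------------------------------
# delay embedding and simplex projection

def delay_embed(x, E: int, tau: int = 1):
    """Build the delay-embedding matrix with aligned one-step-ahead targets.

    Row for time t is (x_t, x_{t-tau}, ..., x_{t-(E-1)tau}) with target
    x_{t+1}; rows with any out-of-range lag are dropped. Returns
    (X, y, times) where times[i] is the t of row i.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if E < 1 or tau < 1:
        raise ValueError("E and tau must be >= 1")
    t0 = (E - 1) * tau
    if t0 + 1 >= n:
        raise ValueError(f"series of length {n} too short for E={E}, tau={tau}")
    times = np.arange(t0, n - 1)
    X = np.column_stack([x[times - k * tau] for k in range(E)])
    y = x[times + 1]
    return X, y, times


def simplex_predict(library_X, library_y, query, n_neighbors: int | None = None) -> float:
    """Simplex projection: exponentially weighted average of the successors
    of the E+1 nearest embedded neighbours.

    Weights are w_j = exp(-d_j / d_min); when the nearest distance is zero the
    prediction is the unweighted mean of the targets of all zero-distance
    neighbours (exact-match rule).
    """
    X = np.asarray(library_X, dtype=float)
    y = np.asarray(library_y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] == 0:
        raise ValueError("empty library")
    q = np.atleast_1d(np.asarray(query, dtype=float))
    d = np.sqrt(((X - q[None, :]) ** 2).sum(axis=1))
    return _simplex_from_distances(d, y, n_neighbors or (X.shape[1] + 1))


def _simplex_from_distances(d: np.ndarray, y: np.ndarray, k: int) -> float:
    k = min(k, len(d))
    order = np.argsort(d, kind="stable")[:k]
    dn = d[order]
    d_min = dn[0]
    if d_min == 0.0:
        exact = d == 0.0
        return float(y[exact].mean())
    w = np.exp(-dn / d_min)
    return float(np.sum(w * y[order]) / np.sum(w))


def _loo_simplex_rmse(X: np.ndarray, y: np.ndarray, times: np.ndarray,
                      theiler: int, k: int) -> float:
    """Leave-one-out one-step simplex skill within a library.

    Each query row excludes itself and all rows within ``theiler`` time steps
    from its neighbour set.
    """
    D = cdist(X, X)
    tdiff = np.abs(times[:, None] - times[None, :])
    D[tdiff <= theiler] = np.inf
    preds = np.empty(len(y))
    for i in range(len(y)):
        d = D[i]
        finite = np.isfinite(d)
        if not finite.any():
            preds[i] = np.nan
            continue
        preds[i] = _simplex_from_distances(d[finite], y[finite], k)
    ok = np.isfinite(preds)
    return float(np.sqrt(np.mean((preds[ok] - y[ok]) ** 2)))


def select_embedding_dim(train, e_range=range(1, 9), tau: int = 1) -> int:
    """Choose E by leave-one-out one-step simplex skill on the training window.

    A Theiler exclusion window of E time steps keeps a query from matching its
    own temporally overlapping neighbours. Ties go to the smallest E.
    """
    train = np.asarray(train, dtype=float)
    best_e, best_rmse = None, np.inf
    for E in e_range:
        try:
            X, y, times = delay_embed(train, E, tau)
        except ValueError:
            continue
        if len(y) < E + 2:
            continue
        r = _loo_simplex_rmse(X, y, times, theiler=E, k=E + 1)
        if r < best_rmse - 1e-12:
            best_e, best_rmse = E, r
    if best_e is None:
        raise ValueError("training series too short for every E in range")
    return best_e


# ---------------------------------------------------------------------------
# forecaster objects (fit on the training window, predict from observed state)

class Forecaster:
    """Interface for one-step-ahead engines: fit(train) then predict_test().

    ``fit`` sees only the training window; ``predict_test`` receives the full
    observed series (training + observed test prefix) and returns one
    prediction per test point, each conditioned on data through t-1 only.
    Additional engines (e.g. tree ensembles) plug in by subclassing.
    """

    name = "base"

    def fit(self, train: np.ndarray, predictors: dict[str, np.ndarray] | None = None):
        raise NotImplementedError

    def predict_test(self, full: np.ndarray, n_train: int,
                     predictors: dict[str, np.ndarray] | None = None) -> np.ndarray:
        raise NotImplementedError

    @property
    def hyperparams(self) -> dict:
        return {}


class MeanForecaster(Forecaster):
    """Climatological baseline: predicts the zero anomaly.

    On a detrended, standardized series the mean is zero by construction, so
    this baseline predicts 0 and its RMSE over a full-window standardized
    series is exactly 1 under the population-SD convention.
    """

    name = "mean"

    def fit(self, train, predictors=None):
        return self

    def predict_test(self, full, n_train, predictors=None):
        return np.zeros(len(full) - n_train)


class SimplexForecaster(Forecaster):
    """Univariate simplex projection with LOO-selected embedding dimension."""

    name = "simplex"

    def __init__(self, e_range=range(1, 9), tau: int = 1, library: str = "frozen"):
        if library not in ("frozen", "growing"):
            raise ValueError(f"unknown library policy {library!r}")
        self.e_range = e_range
        self.tau = tau
        self.library = library
        self.E_: int | None = None

    def fit(self, train, predictors=None):
        self.E_ = select_embedding_dim(train, self.e_range, self.tau)
        return self

    def predict_test(self, full, n_train, predictors=None):
        if self.E_ is None:
            raise RuntimeError("fit before predict")
        full = np.asarray(full, dtype=float)
        E, tau = self.E_, self.tau
        X, y, times = delay_embed(full, E, tau)
        in_train = times + 1 <= n_train - 1  # target inside the training window
        preds = []
        for s in range(n_train, len(full)):
            if self.library == "frozen":
                mask = in_train
            else:
                mask = times + 1 <= s - 1
            query = full[s - 1 - np.arange(E) * tau]
            preds.append(simplex_predict(X[mask], y[mask], query, n_neighbors=E + 1))
        return np.asarray(preds)

    @property
    def hyperparams(self):
        return {"E": self.E_, "tau": self.tau, "library": self.library}


class ArimaForecaster(Forecaster):
    """ARIMA(p,0,q) grid selected by AICc on the training window.

    Test predictions condition on all observed values through t-1 with the
    parameters frozen at the training fit. Detrending precedes forecasting,
    hence d=0. If no candidate converges, falls back to AR(1) with a warning.
    """

    name = "arima"

    def __init__(self, max_p: int = 3, max_q: int = 3):
        self.max_p = max_p
        self.max_q = max_q
        self.order_: tuple[int, int, int] | None = None
        self._res = None

    def fit(self, train, predictors=None):
        from statsmodels.tsa.arima.model import ARIMA

        train = np.asarray(train, dtype=float)
        best = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for p, q in itertools.product(range(self.max_p + 1), range(self.max_q + 1)):
                try:
                    res = ARIMA(train, order=(p, 0, q), trend="c").fit()
                    if not np.isfinite(res.aicc):
                        continue
                except Exception:
                    continue
                if best is None or res.aicc < best[0]:
                    best = (res.aicc, (p, 0, q), res)
            if best is None:
                warnings.warn("no ARIMA candidate converged; falling back to (1,0,0)")
                res = ARIMA(train, order=(1, 0, 0), trend="c").fit()
                best = (res.aicc, (1, 0, 0), res)
        self.order_ = best[1]
        self._res = best[2]
        return self

    def predict_test(self, full, n_train, predictors=None):
        if self._res is None:
            raise RuntimeError("fit before predict")
        full = np.asarray(full, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            applied = self._res.apply(full)  # frozen parameters, new data
            pred = applied.get_prediction(start=n_train, end=len(full) - 1)
        return np.asarray(pred.predicted_mean)

    @property
    def hyperparams(self):
        return {"order": self.order_}


class MultiviewForecaster(Forecaster):
    """Multiview embedding: ensemble of top-ranked small multivariate views.

    Candidate views are combinations of ``view_dim`` lagged coordinates
    (lags 0..max_lag) drawn from all predictor variables, each required to
    contain at least one coordinate of the target. Views are ranked by
    in-train leave-one-out simplex RMSE and the forecast is the mean of the
    top ceil(sqrt(#views)) single-view simplex predictions.
    """

    name = "multiview"

    def __init__(self, target: str, view_dim: int = 3, max_lag: int = 2,
                 max_views: int = 5000, seed: int = 0):
        self.target = target
        self.view_dim = view_dim
        self.max_lag = max_lag
        self.max_views = max_views
        self.seed = seed
        self.views_: list[EmbeddingSpec] | None = None
        self.top_views_: list[EmbeddingSpec] | None = None

    def _embed_view(self, spec: EmbeddingSpec, data: dict[str, np.ndarray],
                    n_limit: int):
        """Embedding rows of one view with targets within the first n_limit points."""
        max_lag = max(lag for _, lag in spec.coordinates)
        times = np.arange(max_lag, n_limit - 1)
        X = np.column_stack([data[var][times - lag] for var, lag in spec.coordinates])
        y = data[self.target][times + 1]
        return X, y, times

    def fit(self, train, predictors=None):
        if predictors is None:
            predictors = {}
        data = dict(predictors)
        data[self.target] = np.asarray(train, dtype=float)
        n_train = len(data[self.target])
        for k, v in data.items():
            v = np.asarray(v, dtype=float)[:n_train]
            if len(v) != n_train:
                raise ValueError(f"predictor {k!r} shorter than the training window")
            data[k] = v

        coords = [(var, lag) for var in sorted(data) for lag in range(self.max_lag + 1)]
        target_coords = {(self.target, lag) for lag in range(self.max_lag + 1)}
        views = [EmbeddingSpec(c) for c in itertools.combinations(coords, self.view_dim)
                 if set(c) & target_coords]
        if not views:
            raise ValueError("no valid view: too few predictor coordinates")
        rng = np.random.default_rng(self.seed)
        if len(views) > self.max_views:
            keep = rng.choice(len(views), size=self.max_views, replace=False)
            views = [views[i] for i in sorted(keep)]

        scored = []
        for spec in views:
            X, y, times = self._embed_view(spec, data, n_train)
            if len(y) < self.view_dim + 2:
                continue
            r = _loo_simplex_rmse(X, y, times, theiler=self.view_dim,
                                  k=self.view_dim + 1)
            scored.append((r, spec))
        if not scored:
            raise ValueError("no view had enough training rows")
        scored.sort(key=lambda t: t[0])
        k_top = math.ceil(math.sqrt(len(scored)))
        self.views_ = [s for _, s in scored]
        self.top_views_ = [s for _, s in scored[:k_top]]
        self._train_data = data
        return self

    def predict_test(self, full, n_train, predictors=None):
        if self.top_views_ is None:
            raise RuntimeError("fit before predict")
        if predictors is None:
            predictors = {}
        data = dict(predictors)
        data[self.target] = np.asarray(full, dtype=float)
        preds = np.zeros(len(data[self.target]) - n_train)
        for spec in self.top_views_:
            X, y, _ = self._embed_view(spec, data, n_train)  # frozen library
            for j, s in enumerate(range(n_train, len(data[self.target]))):
                query = [data[var][s - 1 - lag] for var, lag in spec.coordinates]
                preds[j] += simplex_predict(X, y, query, n_neighbors=self.view_dim + 1)
        return preds / len(self.top_views_)

    @property
    def hyperparams(self):
        return {
            "view_dim": self.view_dim,
            "max_lag": self.max_lag,
            "n_views": None if self.views_ is None else len(self.views_),
            "k_top": None if self.top_views_ is None else len(self.top_views_),
        }


def arima_forecast(train, full=None, max_p: int = 3, max_q: int = 3):
    """Functional wrapper: fit the AICc-selected ARIMA(p,0,q) on ``train`` and,
    if ``full`` is given, return frozen-parameter one-step predictions for the
    points beyond the training window. Returns (predictions, order)."""
    fc = ArimaForecaster(max_p=max_p, max_q=max_q).fit(np.asarray(train, float))
    if full is None:
        return None, fc.order_
    preds = fc.predict_test(np.asarray(full, float), n_train=len(np.asarray(train)))
    return preds, fc.order_


_ENGINES = {
    "mean": lambda target, seed, kw: MeanForecaster(),
    "simplex": lambda target, seed, kw: SimplexForecaster(
        e_range=kw.get("e_range", range(1, 9)), tau=kw.get("tau", 1),
        library=kw.get("library", "frozen")),
    "arima": lambda target, seed, kw: ArimaForecaster(
        max_p=kw.get("max_p", 3), max_q=kw.get("max_q", 3)),
    "multiview": lambda target, seed, kw: MultiviewForecaster(
        target=target, view_dim=kw.get("view_dim", 3),
        max_lag=kw.get("max_lag", 2), max_views=kw.get("max_views", 5000),
        seed=seed),
}


def one_step_protocol(series, method: str, target: str = "target",
                      n_train: int = 111, predictors: dict | None = None,
                      transformed=None, seed: int = 0, **kwargs) -> ForecastResult:
    """Train on points 1..n_train, forecast the rest one step ahead.

    ``series`` is the standardized 123-point series (training + test);
    hyperparameter selection and model fitting see only the first ``n_train``
    points, then each test point t is predicted from observed data through
    t-1. If ``transformed`` (a TransformedSeries) is given, predictions and
    observations are also back-transformed and scored on the original scale.
    """
    from .metrics import rmse
    from .preprocess import back_transform

    x = np.asarray(series, dtype=float)
    if method not in _ENGINES:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_ENGINES)}")
    if n_train >= len(x):
        raise ValueError("training window must leave at least one test point")
    engine = _ENGINES[method](target, seed, kwargs)
    train = x[:n_train]
    train_predictors = None
    if predictors:
        train_predictors = {k: np.asarray(v, float)[:n_train] for k, v in predictors.items()}
    engine.fit(train, train_predictors)
    preds = engine.predict_test(x, n_train, predictors)
    obs = x[n_train:]
    result = ForecastResult(
        method=method,
        target=target,
        predictions=np.asarray(preds, dtype=float),
        observations=obs,
        hyperparams=engine.hyperparams,
        rmse_std=rmse(preds, obs),
    )
    if transformed is not None:
        idx = np.arange(n_train, len(x))
        p_orig = back_transform(preds, transformed, idx)
        o_orig = back_transform(obs, transformed, idx)
        result.rmse_orig = rmse(p_orig, o_orig)
    return result
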