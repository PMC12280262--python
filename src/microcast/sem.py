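"""Multigroup path analysis over observed variables.

A recursive structural model relating richness, the three time-series
diagnostics (lag-5 autocorrelation, coefficient of variation, permutation
entropy) and forecast error, estimated separately in each light condition.
Each structural equation is estimated by least squares within its group
(maximum-likelihood-equivalent for recursive observed-variable models);
residual covariances may be freed among the diagnostics. The global fit
statistic compares model-implied and sample covariance matrices,

    chi^2 = sum_g (N_g - 1) * F_ML(S_g, Sigma_g),
    F_ML  = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p,

with df = total distinct covariance moments minus total free parameters.
A fully saturated specification reproduces S exactly (chi^2 = 0, df = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st


@dataclass(frozen=True)
class SEMSpec:
    """Path-model specification over observed variables.

    ``equations`` maps each endogenous variable to its regressors;
    ``residual_cov`` lists endogenous pairs whose residuals may covary;
    ``exog`` are exogenous variables (their (co)variances are free).
    """

    exog: tuple[str, ...]
    equations: dict[str, tuple[str, ...]]
    residual_cov: tuple[tuple[str, str], ...] = ()

    def variables(self) -> list[str]:
        return list(self.exog) + list(self.equations)

    def validate(self) -> None:
        order = {v: i for i, v in enumerate(self.variables())}
        for dep, preds in self.equations.items():
            for p in preds:
                if p not in order:
                    raise ValueError(f"unknown regressor {p!r} in equation for {dep!r}")
                if p in self.equations and order[p] >= order[dep]:
                    raise ValueError(
                        f"non-recursive structure: {p!r} -> {dep!r} violates the ordering")
        for a, b in self.residual_cov:
            if a not in self.equations or b not in self.equations:
                raise ValueError("residual covariances must link endogenous variables")

    def n_free_per_group(self) -> int:
        k = len(self.exog)
        free = k * (k + 1) // 2                       # exogenous (co)variances
        free += sum(len(p) for p in self.equations.values())  # paths
        free += len(self.equations)                   # residual variances
        free += len(self.residual_cov)                # residual covariances
        return free


def forecast_error_sem_spec() -> SEMSpec:
    """The default structure: richness feeds each diagnostic and the error;
    each diagnostic feeds the error; diagnostic residuals covary freely."""
    return SEMSpec(
        exog=("richness",),
        equations={
            "ac5": ("richness",),
            "cv": ("richness",),
            "pe": ("richness",),
            "error": ("richness", "ac5", "cv", "pe"),
        },
        residual_cov=(("ac5", "cv"), ("ac5", "pe"), ("cv", "pe")),
    )


@dataclass
class GroupPaths:
    group: str
    n: int
    paths: pd.DataFrame          # dep, predictor, coef, se, t, p
    r_squared: dict[str, float]
    implied_cov: pd.DataFrame
    sample_cov: pd.DataFrame
    fml: float


class SEMFit:
    """Results of a multigroup path-model fit."""

    def __init__(self, spec: SEMSpec, groups: list[GroupPaths]):
        self.spec = spec
        self.groups = {g.group: g for g in groups}
        p = len(spec.variables())
        moments = p * (p + 1) // 2
        self.df = len(groups) * (moments - spec.n_free_per_group())
        self.chi2 = float(sum((g.n - 1) * g.fml for g in groups))
        self.p_value = float(st.chi2.sf(self.chi2, self.df)) if self.df > 0 else np.nan

    def paths(self, group: str) -> pd.DataFrame:
        return self.groups[group].paths

    def r_squared(self, group: str, dep: str = "error") -> float:
        return self.groups[group].r_squared[dep]

    def summary(self) -> str:
        lines = [f"Multigroup path model: chi2 = {self.chi2:.3f}, df = {self.df}"
                 + ("" if np.isnan(self.p_value) else f", p = {self.p_value:.3f}")]
        for name, g in self.groups.items():
            lines.append(f"\ngroup {name!r} (n = {g.n}):")
            for _, r in g.paths.iterrows():
                lines.append(
                    f"  {r['predictor']:<10} -> {r['dep']:<8} "
                    f"{r['coef']:>8.3f}  (se {r['se']:.3f}, p {r['p']:.3f})")
            lines.append("  R^2: " + ", ".join(
                f"{k} = {v:.3f}" for k, v in g.r_squared.items()))
        return "\n".join(lines)


class PathModel:
    """Recursive path model fitted per group by equation-wise least squares."""

    def __init__(self, data: pd.DataFrame, spec: SEMSpec | None = None,
                 group_col: str = "light"):
        self.spec = spec or forecast_error_sem_spec()
        self.spec.validate()
        self.group_col = group_col
        cols = self.spec.variables()
        sub = data[cols + [group_col]].dropna()
        if len(sub) < len(data):
            sub = sub.reset_index(drop=True)
        self.data = sub

    def _fit_group(self, name: str, df: pd.DataFrame) -> GroupPaths:
        spec = self.spec
        variables = spec.variables()
        p = len(variables)
        pos = {v: i for i, v in enumerate(variables)}
        Z = df[variables].to_numpy(dtype=float)
        n = Z.shape[0]
        Zc = Z - Z.mean(axis=0)
        S = (Zc.T @ Zc) / n  # ML covariance
        try:
            np.linalg.cholesky(S + 0.0)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"sample covariance for group {name!r} is not positive definite")

        B = np.zeros((p, p))
        Psi = np.zeros((p, p))
        k = len(spec.exog)
        Psi[:k, :k] = S[:k, :k]
        resid = {}
        rows = []
        r2 = {}
        for dep, preds in spec.equations.items():
            yi = Zc[:, pos[dep]]
            X = Zc[:, [pos[q] for q in preds]]
            coef, *_ = np.linalg.lstsq(X, yi, rcond=None)
            e = yi - X @ coef
            resid[dep] = e
            sigma2 = float(e @ e) / n
            Psi[pos[dep], pos[dep]] = sigma2
            r2[dep] = 1.0 - sigma2 / S[pos[dep], pos[dep]]
            # OLS standard errors with ML residual variance
            XtX_inv = np.linalg.inv(X.T @ X)
            dfree = max(n - X.shape[1] - 1, 1)
            se = np.sqrt(np.diag(XtX_inv) * float(e @ e) / dfree)
            for q, c, s_ in zip(preds, coef, se):
                B[pos[dep], pos[q]] = c
                t = c / s_ if s_ > 0 else np.nan
                rows.append((dep, q, float(c), float(s_), float(t),
                             float(2 * st.t.sf(abs(t), dfree))))
        for a, b in spec.residual_cov:
            cab = float(resid[a] @ resid[b]) / n
            Psi[pos[a], pos[b]] = Psi[pos[b], pos[a]] = cab

        IB = np.linalg.inv(np.eye(p) - B)
        Sigma = IB @ Psi @ IB.T
        sign_S, logdet_S = np.linalg.slogdet(S)
        sign_Sig, logdet_Sig = np.linalg.slogdet(Sigma)
        if sign_S <= 0 or sign_Sig <= 0:
            raise np.linalg.LinAlgError("non-positive-definite covariance in fit")
        fml = float(logdet_Sig - logdet_S + np.trace(S @ np.linalg.inv(Sigma)) - p)
        fml = max(fml, 0.0)
        paths = pd.DataFrame(rows, columns=["dep", "predictor", "coef", "se", "t", "p"])
        return GroupPaths(
            group=name, n=n, paths=paths, r_squared=r2,
            implied_cov=pd.DataFrame(Sigma, index=variables, columns=variables),
            sample_cov=pd.DataFrame(S, index=variables, columns=variables),
            fml=fml,
        )

    def fit(self) -> SEMFit:
        groups = [self._fit_group(str(name), df)
                  for name, df in self.data.groupby(self.group_col, sort=True)]
        if len(groups) < 1:
            raise ValueError("no groups to fit")
        return SEMFit(self.spec, groups)


def fit_path_sem(data: pd.DataFrame, spec: SEMSpec | None = None,
                 group_col: str = "light") -> SEMFit:
    """Fit the multigroup path model; see PathModel."""
    return PathModel(data, spec, group_col).fit()


def simulate_path_data(spec: SEMSpec, coefs: dict[tuple[str, str], float],
                       n: int, seed: int = 0,
                       resid_sd: dict[str, float] | None = None) -> pd.DataFrame:
    """Simulate data from a known recursive path model (for recovery checks).

    ``coefs`` maps (dep, predictor) to the path coefficient; exogenous
    variables and residuals are standard normal unless ``resid_sd`` overrides
    a residual SD.
    """
    rng = np.random.default_rng(seed)
    resid_sd = resid_sd or {}
    cols: dict[str, np.ndarray] = {}
    for v in spec.exog:
        cols[v] = rng.normal(0, 1, n)
    for dep, preds in spec.equations.items():
        e = rng.normal(0, resid_sd.get(dep, 1.0), n)
        val = e.copy()
        for q in preds:
            val += coefs.get((dep, q), 0.0) * cols[q]
        cols[dep] = val
    return pd.DataFrame(cols)
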