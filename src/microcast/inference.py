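"""Treatment-effect inference on forecast error with linear mixed models.

The models regress a response (forecast error of taxa abundances, of
community biomass, or a time-series diagnostic) on centered realized
richness, the light condition, and their interaction, with random intercepts
following the experimental design (taxon, bottle and incubator for taxa-level
responses; composition and incubator for aggregate responses). Fixed effects
are estimated by REML with Wald t tests and Wald confidence intervals; term
importance uses type III Wald F tests (sum-to-zero contrasts) when the
interaction is retained (p < 0.1) and type II tests after dropping it.

Model and Results objects follow the statsmodels idiom: build a
``TreatmentEffectModel`` from a dataframe and a spec, ``fit()`` it, and read
estimates, ANOVA tables and ``summary()`` off the returned ``LMMFit``.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.formula.api as smf


@dataclass(frozen=True)
class LMMSpec:
    """Specification of one random-intercept mixed model.

    ``fixed`` lists the fixed-effect terms (e.g. ["richness", "light",
    "richness:light"]); ``groups`` the random-intercept grouping factors;
    ``center`` a continuous column to center at its mean over experimental
    units (one value per ``unit``) before fitting.
    """

    response: str
    fixed: tuple[str, ...]
    groups: tuple[str, ...]
    center: str | None = "richness"
    unit: str = "bottle_id"

    def interaction_terms(self) -> list[str]:
        return [t for t in self.fixed if ":" in t]


@dataclass
class AnovaRow:
    term: str
    ss: float
    f_value: float
    df_num: int
    df_den: float
    p_value: float


@dataclass
class AnovaTable:
    rows: list[AnovaRow]
    type: str                 # "II" or "III"
    interaction_retained: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.term, r.ss, r.f_value, r.df_num, r.df_den, r.p_value) for r in self.rows],
            columns=["term", "SS", "F", "df_num", "df_den", "p"],
        )

    def p_for(self, term: str) -> float:
        for r in self.rows:
            if r.term == term:
                return r.p_value
        raise KeyError(term)


class LMMFit:
    """Results of a REML random-intercept fit (the Results object).

    Wraps the statsmodels MixedLM results with treatment-coded fixed-effect
    estimates, Wald t statistics and CIs (denominator df = n - rank(X)),
    variance components per grouping factor, and term-level Wald F tests.
    """

    def __init__(self, res, spec: LMMSpec, data: pd.DataFrame, singular: bool):
        self._res = res
        self.spec = spec
        self.data = data
        self.singular = singular
        self.n_obs = len(data)
        fe_names = list(res.fe_params.index)
        self.params = res.fe_params
        cov = res.cov_params()
        self.cov_fixed = cov.loc[fe_names, fe_names]
        # boundary (singular) fits can leave tiny negative diagonal artifacts
        diag = np.clip(np.diag(self.cov_fixed), 0.0, None)
        self.bse = pd.Series(np.sqrt(diag), index=fe_names)
        self.df_resid = self.n_obs - len(fe_names)
        self.tvalues = self.params / self.bse
        self.pvalues = pd.Series(
            2 * st.t.sf(np.abs(self.tvalues), self.df_resid), index=fe_names)
        q = st.t.ppf(0.975, self.df_resid)
        self.conf_int = pd.DataFrame(
            {"lower": self.params - q * self.bse, "upper": self.params + q * self.bse})
        self.vcomp = dict(zip(res.model.exog_vc.names, np.atleast_1d(res.vcomp)))
        self.scale = float(res.scale)
        self.llf = float(res.llf)

    @property
    def fittedvalues(self):
        return self._res.fittedvalues

    def wald_term_test(self, term_names: list[str] | None = None,
                       res=None) -> list[AnovaRow]:
        """Wald F test for each fixed-effect term (jointly over its columns)."""
        res = res or self._res
        design_info = res.model.data.design_info
        rows = []
        params = res.fe_params
        fe_names = list(params.index)
        V = res.cov_params().loc[fe_names, fe_names].to_numpy()
        beta = params.to_numpy()
        for term in design_info.term_names:
            if term == "Intercept":
                continue
            if term_names is not None and term not in term_names:
                continue
            sl = design_info.term_name_slices[term]
            idx = np.arange(len(fe_names))[sl]
            L = np.zeros((len(idx), len(fe_names)))
            for r, i in enumerate(idx):
                L[r, i] = 1.0
            lb = L @ beta
            lvl = L @ V @ L.T
            wald = float(lb @ np.linalg.solve(lvl, lb))
            q = len(idx)
            f = wald / q
            ddf = self.df_resid
            p = float(st.f.sf(f, q, ddf))
            rows.append(AnovaRow(term=term, ss=wald * self.scale, f_value=f,
                                 df_num=q, df_den=ddf, p_value=p))
        return rows

    def summary(self) -> str:
        lines = [
            f"Mixed model (REML): {self.spec.response} ~ {' + '.join(self.spec.fixed)}",
            f"random intercepts: {', '.join(self.spec.groups)}   n = {self.n_obs}"
            + ("   [singular fit]" if self.singular else ""),
            "",
            f"{'term':<32}{'estimate':>10}{'SE':>9}{'t':>8}{'p':>9}{'95% CI':>22}",
        ]
        for name in self.params.index:
            lo, hi = self.conf_int.loc[name]
            lines.append(
                f"{name:<32}{self.params[name]:>10.3f}{self.bse[name]:>9.3f}"
                f"{self.tvalues[name]:>8.2f}{self.pvalues[name]:>9.4f}"
                f"{f'[{lo:.3f}, {hi:.3f}]':>22}"
            )
        lines.append("")
        for g, v in self.vcomp.items():
            lines.append(f"var({g}) = {v:.4f}")
        lines.append(f"var(residual) = {self.scale:.4f}   logLik = {self.llf:.2f}")
        return "\n".join(lines)


def _categorical_columns(data: pd.DataFrame, fixed: tuple[str, ...]) -> set[str]:
    cols = set()
    for term in fixed:
        for f in term.split(":"):
            f = f.strip()
            if f in data.columns and not pd.api.types.is_numeric_dtype(data[f]):
                cols.add(f)
    return cols


def _build_formula(spec: LMMSpec, data: pd.DataFrame, sum_coded: bool) -> str:
    cats = _categorical_columns(data, spec.fixed)
    terms = []
    for term in spec.fixed:
        factors = []
        for f in term.split(":"):
            f = f.strip()
            if f in cats and sum_coded:
                factors.append(f"C({f}, Sum)")
            else:
                factors.append(f)
        terms.append(":".join(factors))
    rhs = " + ".join(terms) if terms else "1"
    return f"{spec.response} ~ {rhs}"


def center_column(data: pd.DataFrame, col: str, unit: str) -> tuple[pd.DataFrame, float]:
    """Center ``col`` at its mean over experimental units (one value each)."""
    data = data.copy()
    if unit in data.columns:
        grand = float(data.groupby(unit)[col].first().mean())
    else:
        grand = float(data[col].mean())
    data[col] = data[col] - grand
    return data, grand


class TreatmentEffectModel:
    """Random-intercept mixed model of a response on the treatment grid."""

    def __init__(self, data: pd.DataFrame, spec: LMMSpec, center: bool = True):
        if data[spec.response].isna().any():
            raise ValueError("missing responses; drop them before fitting")
        for g in spec.groups:
            if data[g].nunique() < 2:
                raise ValueError(f"grouping factor {g!r} needs >= 2 levels")
        self.spec = spec
        self.center_value: float | None = None
        if center and spec.center and spec.center in data.columns:
            data, self.center_value = center_column(data, spec.center, spec.unit)
        self.data = data.reset_index(drop=True)

    def _fit_formula(self, formula: str):
        vc = {g: f"0 + C({g})" for g in self.spec.groups}
        model = smf.mixedlm(formula, self.data,
                            groups=np.ones(len(self.data)),
                            re_formula="0", vc_formula=vc)
        singular = False
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = model.fit(reml=True)
            if not res.converged:
                # gradient methods stall near the variance-component boundary
                res = model.fit(reml=True, method="powell", maxiter=2000)
            for w in caught:
                if "singular" in str(w.message).lower():
                    singular = True
        if not res.converged or np.any(np.atleast_1d(res.vcomp) <= 1e-8):
            singular = True
        return res, singular

    def fit(self) -> LMMFit:
        res, singular = self._fit_formula(_build_formula(self.spec, self.data, False))
        if singular:
            warnings.warn("singular mixed-model fit: a variance component is (near) zero")
        fit = LMMFit(res, self.spec, self.data, singular)
        fit._model = self
        return fit

    def fit_sum_coded(self):
        """Refit with sum-to-zero contrasts (for type III tests)."""
        res, singular = self._fit_formula(_build_formula(self.spec, self.data, True))
        return LMMFit(res, self.spec, self.data, singular)


def fit_lmm(data: pd.DataFrame, spec: LMMSpec, center: bool = True) -> LMMFit:
    """REML fit of the random-intercept model described by ``spec``."""
    return TreatmentEffectModel(data, spec, center=center).fit()


def retain_interaction(p_value: float) -> bool:
    """Decision screen: keep the interaction iff p < 0.1."""
    return p_value < 0.1


def anova_decision(data: pd.DataFrame, spec: LMMSpec,
                   center: bool = True) -> tuple[LMMFit, AnovaTable]:
    """Fit with the interaction; keep it (type III) iff its p < 0.1, else
    refit without it and report type II tests for the main effects."""
    interactions = spec.interaction_terms()
    if len(interactions) < 1:
        raise ValueError("spec must contain an interaction term")
    model = TreatmentEffectModel(data, spec, center=center)
    full_fit = model.fit()
    sum_fit = model.fit_sum_coded()
    rows3 = full_fit.wald_term_test(res=sum_fit._res)
    # locate the interaction rows in the sum-coded design's term names
    def is_interaction(term: str) -> bool:
        return ":" in term
    int_ps = [r.p_value for r in rows3 if is_interaction(r.term)]
    if any(retain_interaction(p) for p in int_ps):
        return full_fit, AnovaTable(rows=rows3, type="III", interaction_retained=True)
    reduced = LMMSpec(
        response=spec.response,
        fixed=tuple(t for t in spec.fixed if ":" not in t),
        groups=spec.groups, center=spec.center, unit=spec.unit)
    red_model = TreatmentEffectModel(data, reduced, center=center)
    red_fit = red_model.fit()
    red_sum = red_model.fit_sum_coded()
    rows2 = red_fit.wald_term_test(res=red_sum._res)
    return red_fit, AnovaTable(rows=rows2, type="II", interaction_retained=False)


def _find_interaction_key(names, richness: str, light: str) -> str:
    """Locate the richness x light coefficient among patsy-style names."""
    for name in names:
        if ":" in name and richness in name and light in name:
            return name
    for name in names:
        if ":" in name:
            return name
    raise KeyError("no interaction coefficient found")


def slopes_and_percent_change(fit, richness: str = "richness",
                              light: str = "light") -> dict:
    """Per-light-condition richness slope and percent change in forecast error.

    With treatment coding (reference = constant light) the constant-light
    slope is the richness coefficient and the declining-light slope adds the
    interaction coefficient; on standardized series the baseline RMSE is 1,
    so percent change per added species is 100 x slope. Accepts an LMMFit or
    a plain mapping of coefficient estimates.
    """
    if isinstance(fit, Mapping):
        names = list(fit.keys())
        get = lambda k: float(fit[k])
    else:
        names = list(fit.params.index)
        get = lambda k: float(fit.params[k])
    if richness in names:
        rich_key = richness
    else:
        rich_key = next(n for n in names if richness in n and ":" not in n)
    int_key = _find_interaction_key(names, richness, light)
    b_r = get(rich_key)
    b_int = get(int_key)
    return {
        "slope_constant": b_r,
        "slope_declining": b_r + b_int,
        "percent_change_constant": 100.0 * b_r,
        "percent_change_declining": 100.0 * (b_r + b_int),
    }


def marginal_means_contrast(fit: LMMFit, at_richness, richness: str = "richness",
                            light: str = "light") -> pd.DataFrame:
    """Light-effect contrast (declining - constant) at given centered richness.

    Wald SEs from the fixed-effect covariance; warns when a richness value
    lies outside the observed (centered) range.
    """
    names = list(fit.params.index)
    light_key = next(n for n in names if light in n and ":" not in n and n != richness)
    int_key = _find_interaction_key(names, richness, light)
    obs = fit.data[richness]
    rows = []
    for r in np.atleast_1d(at_richness):
        if r < obs.min() - 1e-9 or r > obs.max() + 1e-9:
            warnings.warn(f"richness value {r} outside the observed range")
        c = pd.Series(0.0, index=names)
        c[light_key] = 1.0
        c[int_key] = float(r)
        est = float(c @ fit.params)
        se = float(np.sqrt(c @ fit.cov_fixed @ c))
        q = st.t.ppf(0.975, fit.df_resid)
        t = est / se
        rows.append((float(r), est, se, est - q * se, est + q * se,
                     2 * st.t.sf(abs(t), fit.df_resid)))
    return pd.DataFrame(rows, columns=["richness", "estimate", "se",
                                       "ci_lower", "ci_upper", "p"])


def aggregation_comparison(data: pd.DataFrame, response: str = "error",
                           richness: str = "richness", light: str = "light",
                           aggregation: str = "aggregation",
                           groups: tuple[str, ...] = ("bottle_id", "incubator"),
                           ) -> tuple[LMMFit, AnovaTable]:
    """Does the treatment effect depend on the aggregation level?

    Fits error ~ richness + light + aggregation + all pairwise interactions
    with random intercepts for bottle and incubator, then applies the
    p < 0.1 screen jointly to the interactions (any retained -> type III for
    all terms; none -> drop all interactions and report type II).
    """
    if data[aggregation].nunique() < 2:
        raise ValueError("need both aggregation levels in the data")
    spec = LMMSpec(
        response=response,
        fixed=(richness, light, aggregation,
               f"{richness}:{light}", f"{richness}:{aggregation}",
               f"{light}:{aggregation}"),
        groups=groups, center=richness)
    return anova_decision(data, spec)


# ---------------------------------------------------------------------------
# simulation from a fitted-model structure (parameter-recovery checks)

#: taxa-abundance model coefficients (intercept, richness, light, interaction)
#: used as defaults in recovery simulations
DEFAULT_BETA = (0.685, 0.056, -0.095, -0.102)


def simulate_lmm_dataset(beta=DEFAULT_BETA, sd_taxon: float = 0.15,
                         sd_bottle: float = 0.10, sd_incubator: float = 0.05,
                         sd_resid: float = 0.30, n_taxa_per_bottle: int = 8,
                         seed: int = 0) -> pd.DataFrame:
    """Simulate a taxa-level forecast-error dataset from the mixed model.

    Recreates the design structure: 15 compositions x 2 light regimes = 30
    bottles in 8 incubators, ~8 forecastable taxa per bottle drawn from 14
    labels, with response intercept + richness and light effects plus random
    intercepts for taxon, bottle and incubator and residual noise. Richness
    enters centered (as in the analysis models).
    """
    rng = np.random.default_rng(seed)
    b0, b_r, b_l, b_rl = beta
    taxa_labels = [f"T{i:02d}" for i in range(1, 15)]
    u_taxon = dict(zip(taxa_labels, rng.normal(0, sd_taxon, len(taxa_labels))))
    level_median = {1: 4.0, 2: 5.5, 3: 7.0}
    rows = []
    bottle_no = 0
    for regime_idx, regime in enumerate(("constant", "declining")):
        for comp_idx in range(15):
            bottle_no += 1
            level = comp_idx // 5 + 1
            richness = level_median[level] + rng.choice((-0.5, 0.0, 0.5))
            bottle = f"B{bottle_no:02d}"
            incubator = f"I{regime_idx * 4 + comp_idx % 4 + 1}"
            rows.append((bottle, f"L{level}C{comp_idx % 5 + 1}", regime,
                         incubator, richness))
    bottles = pd.DataFrame(rows, columns=["bottle_id", "composition", "light",
                                          "incubator", "richness"])
    grand = bottles["richness"].mean()
    u_bottle = dict(zip(bottles["bottle_id"],
                        rng.normal(0, sd_bottle, len(bottles))))
    incs = bottles["incubator"].unique()
    u_inc = dict(zip(incs, rng.normal(0, sd_incubator, len(incs))))
    out = []
    for _, b in bottles.iterrows():
        taxa = rng.choice(taxa_labels, size=n_taxa_per_bottle, replace=False)
        rc = b["richness"] - grand
        is_decl = 1.0 if b["light"] == "declining" else 0.0
        for t in taxa:
            mu = b0 + b_r * rc + b_l * is_decl + b_rl * rc * is_decl
            y = (mu + u_taxon[t] + u_bottle[b["bottle_id"]] + u_inc[b["incubator"]]
                 + rng.normal(0, sd_resid))
            out.append((b["bottle_id"], b["composition"], b["light"],
                        b["incubator"], b["richness"], t, y))
    return pd.DataFrame(out, columns=["bottle_id", "composition", "light",
                                      "incubator", "richness", "taxon", "error"])


TAXA_ERROR_SPEC = LMMSpec(
    response="error",
    fixed=("richness", "light", "richness:light"),
    groups=("taxon", "bottle_id", "incubator"),
    center="richness",
)

AGGREGATE_ERROR_SPEC = LMMSpec(
    response="error",
    fixed=("richness", "light", "richness:light"),
    groups=("composition", "incubator"),
    center="richness",
)
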