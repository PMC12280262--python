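"""End-to-end orchestration: design -> simulate -> preprocess -> forecast ->
diagnostics -> treatment-effect inference.

``run_experiment_tables`` produces the raw and transformed tables plus a
per-series results table (forecast error and diagnostics joined with the
design metadata); ``analyze_taxa_errors`` / ``analyze_aggregate_errors`` /
``fit_sem`` run the inference stage on that table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import design as dz
from . import forecast as fc
from . import inference as inf
from . import metrics as mx
from . import preprocess as pp
from . import sem as semm
from . import simulate as sim

AGGREGATES = ("community_biomass", "oxygen")


def default_design(seed: int = 0):
    pool = dz.SpeciesPool.default()
    comps = dz.assemble_compositions(pool, n_per_level=5, seed=seed)
    bottles = dz.build_bottle_grid(comps)
    return pool, bottles


def run_experiment_tables(seed: int, bottles=None, pool=None, params=None,
                          methods: tuple[str, ...] = ("simplex",),
                          window: str = "full",
                          min_positive_fraction: float = 0.6,
                          calendar: dz.SamplingCalendar | None = None):
    """Simulate a full experiment and score every forecastable series.

    Returns ``(raw, results)`` where ``results`` has one row per bottle x
    variable x method with forecast error on both scales, the three
    diagnostics, realized richness and design metadata. Taxa that went
    (near-)extinct — positive on fewer than ``min_positive_fraction`` of
    dates — are not forecast, mirroring the exclusion of extinct targets.
    """
    calendar = calendar or dz.SamplingCalendar.default()
    if bottles is None:
        pool, bottles = default_design(seed=0)
    pool = pool or dz.SpeciesPool.default()
    params = params or sim.SimParams.default_for_pool(pool)
    raw = sim.run_experiment(bottles, params, calendar, seed=seed, pool=pool)

    meta = {b.bottle_id: b for b in bottles}
    results = []
    for bottle_id, braw in raw.groupby("bottle_id", sort=True):
        config = meta[bottle_id]
        members = sorted(config.composition.members)
        richness = pp.realized_richness(braw, members=members, threshold=0.0)
        targets = []
        for name in members:
            svals = braw.loc[braw["variable"] == name, "value"]
            frac_pos = float(np.mean(np.nan_to_num(svals.to_numpy()) > 0))
            if frac_pos >= min_positive_fraction:
                targets.append(name)
        targets += [v for v in AGGREGATES]

        # transform every needed series once
        transforms = {}
        regridded = {}
        needed = set(targets) | {"DOC", "nitrogen"}
        for name in needed:
            grp = braw[braw["variable"] == name].sort_values("date_offset")
            if grp.empty:
                continue
            try:
                reg = pp.impute_and_regrid(grp["date_offset"], grp["value"],
                                           grp["missing"], calendar)
                ts = pp.detrend_standardize(reg, window=window)
            except (pp.DegenerateSeriesError, ValueError):
                continue
            regridded[name] = reg
            transforms[name] = ts

        predictor_block = {name: transforms[name].values
                           for name in transforms}
        for name in targets:
            if name not in transforms:
                continue
            ts = transforms[name]
            diag = mx.ts_metrics(ts.values, ts.residuals, regridded[name])
            for method in methods:
                predictors = None
                if method == "multiview":
                    predictors = {k: v for k, v in predictor_block.items()}
                res = fc.one_step_protocol(
                    ts.values, method, target=name, transformed=ts,
                    predictors=predictors, seed=seed)
                results.append({
                    "bottle_id": bottle_id,
                    "variable": name,
                    "kind": "aggregate" if name in AGGREGATES else "taxon",
                    "method": method,
                    "light": config.light_regime,
                    "incubator": config.incubator,
                    "composition": config.composition.id,
                    "richness_level": config.composition.richness_level,
                    "planned_richness": config.composition.planned_richness,
                    "richness": richness,
                    "error": res.rmse_std,
                    "error_orig": res.rmse_orig,
                    "cv": diag.cv,
                    "ac5": diag.ac5,
                    "pe": diag.pe,
                })
    return raw, pd.DataFrame(results)


def taxa_table(results: pd.DataFrame, method: str = "simplex") -> pd.DataFrame:
    df = results[(results["kind"] == "taxon") & (results["method"] == method)].copy()
    return df.rename(columns={"variable": "taxon"})


def aggregate_table(results: pd.DataFrame, variable: str = "community_biomass",
                    method: str = "simplex") -> pd.DataFrame:
    return results[(results["variable"] == variable)
                   & (results["method"] == method)].copy()


def analyze_taxa_errors(results: pd.DataFrame, method: str = "simplex"):
    """Richness x light mixed model on taxa forecast error with the ANOVA
    decision rule; returns (full_fit, anova_table, slopes dict)."""
    df = taxa_table(results, method)
    spec = inf.LMMSpec(response="error",
                       fixed=("richness", "light", "richness:light"),
                       groups=("taxon", "bottle_id", "incubator"),
                       center="richness")
    fit, table = inf.anova_decision(df, spec)
    full_fit = inf.fit_lmm(df, spec)
    slopes = inf.slopes_and_percent_change(full_fit)
    return fit, table, slopes, full_fit


def analyze_aggregate_errors(results: pd.DataFrame,
                             variable: str = "community_biomass",
                             method: str = "simplex"):
    df = aggregate_table(results, variable, method)
    spec = inf.LMMSpec(response="error",
                       fixed=("richness", "light", "richness:light"),
                       groups=("composition", "incubator"),
                       center="richness")
    return inf.anova_decision(df, spec)


def fit_sem(results: pd.DataFrame, method: str = "simplex") -> semm.SEMFit:
    df = taxa_table(results, method)
    df = df.copy()
    grand = df.groupby("bottle_id")["richness"].first().mean()
    df["richness"] = df["richness"] - grand
    return semm.fit_path_sem(df, group_col="light")


def aggregation_level_table(results: pd.DataFrame, variable: str = "community_biomass",
                            method: str = "simplex") -> pd.DataFrame:
    """Per-bottle mean taxa error and aggregate error, stacked for the
    aggregation-level comparison model."""
    taxa = taxa_table(results, method)
    mean_taxa = (taxa.groupby(["bottle_id", "light", "incubator", "richness"])
                 ["error"].mean().reset_index())
    mean_taxa["aggregation"] = "taxa_mean"
    agg = aggregate_table(results, variable, method)[
        ["bottle_id", "light", "incubator", "richness", "error"]].copy()
    agg["aggregation"] = variable
    return pd.concat([mean_taxa, agg], ignore_index=True)
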