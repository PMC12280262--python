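"""Synthetic microcosm communities: light-forced consumer-resource dynamics.

The simulator generates bottle time series with the statistical structure the
downstream analysis assumes: autocorrelated multi-trophic dynamics forced by a
light schedule, 5% batch dilution at every sampling, immigration pulses every
three weeks, an extinction threshold, multiplicative observation noise, and
instrument-specific missing data.

Model
-----
Between sampling events the latent state follows generalized Lotka-Volterra
dynamics,

    dN_i/dt = N_i * [ r_i(L(t), N) + sum_j A_ij N_j + eps_i ],

with r_i(L) = r_max_i * L/(L + K_L_i) * N_nut/(N_nut + K_N) for light-dependent
taxa (algae and mixotrophs), r_i = -m_i for heterotrophs, and eps_i a
per-interval environmental growth-rate perturbation. Bacteria grow on
dissolved organic carbon and are grazed by bacterivores, omnivores and
mixotrophs; the predator eats ciliates. Nutrients follow a chemostat-style
update at each dilution. Oxygen is an instantaneous balance of photosynthesis
and respiration around a saturation baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    BottleConfig,
    LightSchedule,
    SamplingCalendar,
    SpeciesPool,
    build_light_schedule,
)

AGGREGATE_VARIABLES = ("community_biomass", "oxygen", "DOC", "nitrogen")

#: instrument missing-data rates (fraction of records), per measurement channel
DEFAULT_MISSINGNESS = {
    "flowcam": 0.0081,        # algae counts
    "flow_cytometer": 0.0484, # bacteria counts
    "video": 0.0084,          # ciliate counts
    "oxygen_meter": 0.0167,
    "toc_tn": 0.0092,         # dissolved carbon and nitrogen
}

_CILIATE_GROUPS = {"bacterivore", "omnivore", "mixotroph", "predator"}
_PRODUCER_GROUPS = {"edible_algae", "inedible_algae"}


class SimulationError(RuntimeError):
    """Raised when the latent state becomes non-finite (parameter blow-up)."""


@dataclass
class SimParams:
    """All tunable simulator parameters.

    Species-keyed dicts cover the full 18-species pool; ``simulate_bottle``
    restricts them to the members of a bottle. ``interactions`` holds the
    per-capita effect of column species j on row species i (A_ij), including
    the pseudo-taxon ``"bacteria"``.
    """

    r_max: dict[str, float]
    mortality: dict[str, float]
    light_halfsat: dict[str, float]
    interactions: dict[tuple[str, str], float]
    biovolume: dict[str, float]
    light_dependent: dict[str, bool]
    reimmigrates: dict[str, bool]

    # bacteria / resources
    bacteria_growth: float = 2.5       # 1/day at saturating DOC
    bacteria_mortality: float = 0.8    # 1/day
    bacteria_capacity: float = 4.0e6   # cells/mL
    bacteria_supply: float = 0.0       # cells/mL/day basal input
    bacteria_init: float = 5.0e5       # cells/mL at inoculation
    bacteria_biovolume: float = 0.5    # um^3
    doc_medium: float = 10.0           # mg/L in fresh medium
    doc_supply: float = 0.2            # mg/L/day (wheat-seed release)
    doc_exudation: float = 1.5e-4      # mg/L per producer cell produced
    doc_halfsat: float = 2.0           # mg/L
    doc_uptake: float = 2.5e-7         # mg/L per bacterial cell per day
    nitrogen_medium: float = 5.0       # mg/L in fresh medium
    nitrogen_supply: float = 0.05      # mg/L/day recycling
    nitrogen_halfsat: float = 0.5      # mg/L
    nitrogen_quota: float = 5.0e-5     # mg/L per producer cell produced

    # protocol
    dilution_fraction: float = 0.05
    immigration_dose: float = 10.0     # individuals per bottle per event
    bottle_volume_ml: float = 1000.0
    immigration_every: int = 9         # samplings (3 weeks at Mon/Wed/Fri)
    extinction_threshold: float = 1e-3 # individuals/mL

    # noise
    obs_noise_cv: float = 0.12
    env_noise_sd: float = 0.13         # 1/day, per sampling interval
    #: insurance-effect buffering of environmental perturbations: when the
    #: light environment departs from its initial level, populations whose
    #: functional group holds partners experience damped, temporally
    #: persistent perturbations (compensatory dynamics filter fast
    #: fluctuations), while populations without functional partners face
    #: amplified erratic perturbations (novel dynamics).
    env_noise_change_gain: float = 7.0   # amplification of unbuffered noise under change
    env_noise_buffering: float = 0.6     # buffering per functional-group partner
    env_noise_persistence: float = 0.9   # AR(1) coefficient of buffered noise
    env_noise_redundancy_damping: float = 0.7  # amplitude damping of buffered populations
    env_noise_tracking: float = 0.85     # persistent share of stable-environment tracking
    missingness: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    #: counted sample volume (mL) per counting instrument; adds Poisson
    #: counting error (relatively larger at low density, as in real counts);
    #: None disables the counting stage
    count_volumes: dict[str, float] | None = field(
        default_factory=lambda: {"flowcam": 0.02, "video": 0.2, "flow_cytometer": 1e-4})

    # oxygen model (mg/L)
    oxygen_baseline: float = 8.0
    oxygen_photo_gain: float = 1.0
    oxygen_resp_loss: float = 0.15
    oxygen_noise_sd: float = 0.2

    # integration
    step: float = 0.05                 # days, fixed-step RK4

    # initial densities (per mL, split among group members)
    init_producer_group: float = 4.0e3
    init_ciliate_group: float = 40.0
    init_predator: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.dilution_fraction < 1.0:
            raise ValueError("dilution fraction must be in (0, 1)")
        if self.obs_noise_cv < 0:
            raise ValueError("observation noise CV must be >= 0")
        for k, v in self.missingness.items():
            if not 0.0 <= v < 1.0:
                raise ValueError(f"missingness rate for {k!r} must be in [0, 1)")

    @classmethod
    def default_for_pool(cls, pool: SpeciesPool, seed: int = 20240917) -> "SimParams":
        """Default parameterisation for the 18-species pool.

        Group-level baselines with multiplicative per-species jitter; the
        inedible-algae and mixotroph light half-saturation constants are
        spread within the group so every richer community holds both
        light-sensitive and light-tolerant producers (the insurance
        structure), while the species-poor communities draw a single,
        possibly sensitive, representative.
        """
        rng = np.random.default_rng(seed)

        def jit(scale: float = 0.25) -> float:
            return float(np.exp(rng.normal(0.0, scale)))

        r_max: dict[str, float] = {}
        mort: dict[str, float] = {}
        kl: dict[str, float] = {}
        A: dict[tuple[str, str], float] = {}
        biovol = {s.name: s.biovolume for s in pool.species}
        ldep = {s.name: s.light_dependent for s in pool.species}
        reimm = {s.name: s.reimmigrates for s in pool.species}

        edible = [s.name for s in pool.members("edible_algae")]
        inedible = [s.name for s in pool.members("inedible_algae")]
        bacterivores = [s.name for s in pool.members("bacterivore")]
        omnivores = [s.name for s in pool.members("omnivore")]
        mixotrophs = [s.name for s in pool.members("mixotroph")]
        predator = pool.members("predator")[0].name
        producers = edible + inedible
        ciliates = bacterivores + omnivores + mixotrophs + [predator]

        for name in edible:
            r_max[name] = 1.2 * jit(0.1)
            kl[name] = 5.0 * jit(0.2)
            mort[name] = 0.05
        # spread light tolerance across the inedible algae: half-saturation
        # from 2% (tolerant of dim light) to 14% (needs bright light)
        kl_spread = np.linspace(2.0, 14.0, len(inedible))
        for name, k in zip(inedible, kl_spread):
            r_max[name] = 0.9 * jit(0.1)
            kl[name] = float(k) * jit(0.1)
            mort[name] = 0.05
        for name in bacterivores:
            r_max[name] = 0.0
            mort[name] = 0.30 * jit(0.15)
        for name in omnivores:
            r_max[name] = 0.0
            mort[name] = 0.30 * jit(0.15)
        kl_mixo = np.linspace(2.5, 9.0, len(mixotrophs))
        for name, k in zip(mixotrophs, kl_mixo):
            r_max[name] = 0.45 * jit(0.1)
            kl[name] = float(k)
            mort[name] = 0.12
        r_max[predator] = 0.0
        mort[predator] = 0.45

        # producer competition for nutrients/light (self + cross)
        cap = {name: 8.0e3 * jit(0.2) for name in producers}
        for i in producers:
            for j in producers:
                comp = 1.0 if i == j else 0.5 * jit(0.2)
                A[(i, j)] = -comp * r_max[i] / cap[i]

        # bacterivory
        for c in bacterivores:
            A[(c, "bacteria")] = 3.0e-7 * jit(0.2)
            A[("bacteria", c)] = -4.0e-3 * jit(0.2)
        # diet spread among omnivores: algae-leaning to bacteria-leaning, so
        # richer communities hold consumers that tolerate an algal collapse
        diet_w = np.linspace(0.9, 0.3, len(omnivores))
        for o, w in zip(omnivores, diet_w):
            A[(o, "bacteria")] = 2.4e-7 * (1.0 - w) * jit(0.2)
            A[("bacteria", o)] = -1.2e-3 * (1.0 - w) * jit(0.2)
            for e in edible:
                A[(o, e)] = 1.0e-4 * w * jit(0.2)
                A[(e, o)] = -1.6e-2 * w * jit(0.2)
        for m in mixotrophs:
            A[(m, "bacteria")] = 1.0e-7 * jit(0.2)
            A[("bacteria", m)] = -1.5e-3 * jit(0.2)

        # predation on ciliates
        for c in bacterivores + omnivores + mixotrophs:
            A[(predator, c)] = 1.2e-3 * jit(0.2)
            A[(c, predator)] = -1.5e-2 * jit(0.2)

        # ciliate self-limitation (crowding)
        for c in bacterivores:
            A[(c, c)] = -1.2e-3 * jit(0.2)
        for o in omnivores:
            A[(o, o)] = -4.0e-3 * jit(0.2)
        for m in mixotrophs:
            A[(m, m)] = -1.5e-3 * jit(0.2)
        A[(predator, predator)] = -3.0e-2

        return cls(
            r_max=r_max,
            mortality=mort,
            light_halfsat=kl,
            interactions=A,
            biovolume=biovol,
            light_dependent=ldep,
            reimmigrates=reimm,
        )


def _instrument_for(variable: str, group_of: dict[str, str]) -> str:
    if variable == "bacteria":
        return "flow_cytometer"
    if variable == "oxygen":
        return "oxygen_meter"
    if variable in ("DOC", "nitrogen"):
        return "toc_tn"
    g = group_of.get(variable)
    if g in _PRODUCER_GROUPS:
        return "flowcam"
    if g in _CILIATE_GROUPS:
        return "video"
    raise KeyError(f"unknown taxon {variable!r}")


def simulate_bottle(config: BottleConfig, params: SimParams,
                    schedule: LightSchedule, calendar: SamplingCalendar,
                    seed: int, pool: SpeciesPool | None = None,
                    include_bacteria: bool = False,
                    return_latent: bool = False):
    """Simulate one bottle and return its tidy sampling table.

    At each sampling date the latent state is recorded (with multiplicative
    lognormal observation noise and instrument-specific missingness), then the
    bottle is diluted by ``dilution_fraction`` with nutrient refresh toward
    fresh-medium levels, taxa below the extinction threshold are zeroed, and
    every ``immigration_every``-th sampling each member taxon with a living
    stock culture receives the immigration dose.
    """
    members = sorted(config.composition.members)
    for name in members:
        if name not in params.r_max:
            raise KeyError(f"unknown taxon {name!r} in composition {config.composition.id}")
    pool = pool or SpeciesPool.default()
    group_of = {s.name: s.functional_group for s in pool.species}

    rng = np.random.default_rng(seed)
    S = len(members)
    idx = {name: i for i, name in enumerate(members)}

    # build restricted interaction matrix; column S is bacteria
    A = np.zeros((S, S + 1))
    for (i, j), a in params.interactions.items():
        if i in idx and (j in idx or j == "bacteria"):
            A[idx[i], idx[j] if j in idx else S] = a
    bact_loss = np.zeros(S)  # per-capita effect of member j on bacteria
    for (i, j), a in params.interactions.items():
        if i == "bacteria" and j in idx:
            bact_loss[idx[j]] = a

    r_max = np.array([params.r_max[m] for m in members])
    mort = np.array([params.mortality[m] for m in members])
    kl = np.array([params.light_halfsat.get(m, 1.0) for m in members])
    is_ldep = np.array([params.light_dependent.get(m, False) for m in members], dtype=bool)
    biovol = np.array([params.biovolume[m] for m in members])
    is_producer = np.array([group_of[m] in _PRODUCER_GROUPS for m in members], dtype=bool)
    is_hetero = ~is_ldep

    # initial conditions: substitutive design, inoculum split within groups
    n = np.zeros(S)
    groups = [group_of[m] for m in members]
    for g in set(groups):
        names_g = [m for m in members if group_of[m] == g]
        if g in _PRODUCER_GROUPS:
            each = params.init_producer_group / len(names_g)
        elif g == "predator":
            each = params.init_predator
        else:
            each = params.init_ciliate_group / len(names_g)
        for m in names_g:
            n[idx[m]] = each
    B = params.bacteria_init if S > 0 else 0.0
    C = params.doc_medium
    Nn = params.nitrogen_medium

    dose = params.immigration_dose / params.bottle_volume_ml
    can_immigrate = np.array([params.reimmigrates.get(m, True) for m in members], dtype=bool)

    dates = np.asarray(calendar.dates, dtype=float)
    n_dates = len(dates)
    latent = np.zeros((n_dates, S))
    latent_B = np.zeros(n_dates)
    latent_C = np.zeros(n_dates)
    latent_N = np.zeros(n_dates)
    latent_O2 = np.zeros(n_dates)

    dt = params.step

    def rhs(t, n, B, C, Nn, eps):
        L = schedule.level(t)
        phi_L = L / (L + kl)
        phi_N = Nn / (Nn + params.nitrogen_halfsat)
        growth = np.where(is_ldep, r_max * phi_L * phi_N, 0.0) - mort
        g = growth + A[:, :S] @ n + A[:, S] * B + eps
        dn = n * g
        phi_C = C / (C + params.doc_halfsat)
        gB = (params.bacteria_growth * phi_C - params.bacteria_mortality
              - B / params.bacteria_capacity + bact_loss @ n)
        dB = B * gB + params.bacteria_supply
        prod_growth = np.where(is_ldep, r_max * phi_L * phi_N, 0.0) * n
        dC = (params.doc_supply + params.doc_exudation * float(prod_growth.sum())
              - params.doc_uptake * B * phi_C)
        dN = params.nitrogen_supply - params.nitrogen_quota * float(prod_growth.sum())
        return dn, dB, dC, dN

    # functional-group redundancy per member (for noise buffering)
    group_count = np.array([sum(1 for m in members if group_of[m] == group_of[name])
                            for name in members], dtype=float)
    buffering = np.clip(params.env_noise_buffering * (group_count - 1.0), 0.0, 1.0)
    slow_noise = rng.normal(0.0, 1.0, size=S)  # AR(1) state, stationary sd 1
    phi = params.env_noise_persistence

    for k in range(n_dates):
        if k > 0:
            t0, t1 = dates[k - 1], dates[k]
            if params.env_noise_sd > 0:
                slow_noise = phi * slow_noise + math.sqrt(1 - phi * phi) * rng.normal(0.0, 1.0, size=S)
                white = rng.normal(0.0, 1.0, size=S)
                # light deficit activates the buffering mechanism
                deficit = 1.0 - schedule.level(t0) / schedule.high
                # persistence: unbuffered populations smoothly track the
                # (autocorrelated) micro-environment while conditions are
                # stable; buffered groups respond slowly under change
                u = (buffering * deficit
                     + params.env_noise_tracking * (1.0 - buffering) * (1.0 - deficit))
                amp = 1.0 - params.env_noise_redundancy_damping * buffering
                sd = params.env_noise_sd * amp * (
                    1.0 + params.env_noise_change_gain * deficit * (1.0 - buffering))
                eps = sd * (np.sqrt(1.0 - u) * white + np.sqrt(u) * slow_noise)
            else:
                eps = np.zeros(S)
            t = t0
            while t < t1 - 1e-9:
                h = min(dt, t1 - t)
                k1 = rhs(t, n, B, C, Nn, eps)
                k2 = rhs(t + h / 2, n + h / 2 * k1[0], B + h / 2 * k1[1],
                         C + h / 2 * k1[2], Nn + h / 2 * k1[3], eps)
                k3 = rhs(t + h / 2, n + h / 2 * k2[0], B + h / 2 * k2[1],
                         C + h / 2 * k2[2], Nn + h / 2 * k2[3], eps)
                k4 = rhs(t + h, n + h * k3[0], B + h * k3[1],
                         C + h * k3[2], Nn + h * k3[3], eps)
                n = n + h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
                B = B + h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
                C = C + h / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
                Nn = Nn + h / 6 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
                n = np.maximum(n, 0.0)
                B = max(B, 0.0)
                C = max(C, 0.0)
                Nn = max(Nn, 0.0)
                t += h
            if not (np.all(np.isfinite(n)) and math.isfinite(B)
                    and math.isfinite(C) and math.isfinite(Nn)):
                raise SimulationError(
                    f"non-finite state in bottle {config.bottle_id} at day {t1:.1f}: "
                    f"n={n}, B={B}, C={C}, N={Nn}"
                )

        # record pre-dilution state
        latent[k] = n
        latent_B[k] = B
        latent_C[k] = C
        latent_N[k] = Nn
        L = schedule.level(dates[k])
        photo = float(np.sum(np.where(is_ldep, L / (L + kl), 0.0) * n * biovol) * 1e-6)
        resp = float(np.sum(n[is_hetero] * biovol[is_hetero]) * 1e-6
                     + B * params.bacteria_biovolume * 1e-6)
        latent_O2[k] = (params.oxygen_baseline
                        + params.oxygen_photo_gain * photo
                        - params.oxygen_resp_loss * resp)

        # dilution with nutrient refresh, extinction threshold, immigration
        f = params.dilution_fraction
        n = (1.0 - f) * n
        B = (1.0 - f) * B
        C = (1.0 - f) * C + f * params.doc_medium
        Nn = (1.0 - f) * Nn + f * params.nitrogen_medium
        n[n < params.extinction_threshold] = 0.0
        if params.immigration_every > 0 and k > 0 and (k % params.immigration_every) == 0 and dose > 0:
            n = n + np.where(can_immigrate, dose, 0.0)

    # observation layer
    cv = params.obs_noise_cv
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0

    def observe(values: np.ndarray) -> np.ndarray:
        if sigma == 0.0:
            return values.copy()
        mult = rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=values.shape)
        return values * mult

    def count(values: np.ndarray, instrument: str) -> np.ndarray:
        """Poisson counting of a finite sample volume (density estimate)."""
        if params.count_volumes is None:
            return values
        v = params.count_volumes.get(instrument)
        if v is None or v <= 0:
            return values
        return rng.poisson(np.maximum(values, 0.0) * v) / v

    rows = []
    obs_taxa = observe(latent)
    for j, name in enumerate(members):
        inst = _instrument_for(name, group_of)
        obs_taxa[:, j] = count(obs_taxa[:, j], inst)
    obs_B = observe(latent_B)
    obs_B = count(obs_B, "flow_cytometer")
    obs_C = observe(latent_C)
    obs_N = observe(latent_N)
    obs_O2 = latent_O2 + (rng.normal(0.0, params.oxygen_noise_sd, size=n_dates)
                          if params.oxygen_noise_sd > 0 else 0.0)

    def miss_mask(instrument: str, size: int) -> np.ndarray:
        rate = params.missingness.get(instrument, 0.0)
        if rate <= 0:
            return np.zeros(size, dtype=bool)
        return rng.random(size) < rate

    taxa_missing = np.zeros((n_dates, S), dtype=bool)
    for j, name in enumerate(members):
        inst = _instrument_for(name, group_of)
        taxa_missing[:, j] = miss_mask(inst, n_dates)
    miss_B = miss_mask("flow_cytometer", n_dates)
    miss_O2 = miss_mask("oxygen_meter", n_dates)
    miss_CN = miss_mask("toc_tn", n_dates)
    miss_N2 = miss_mask("toc_tn", n_dates)

    # community biomass from observed constituents (missing if any constituent is)
    conv = 1e-6  # ug per um^3 at unit density
    biomass = obs_taxa @ (biovol * conv) + obs_B * (params.bacteria_biovolume * conv)
    miss_biomass = taxa_missing.any(axis=1) | miss_B

    for j, name in enumerate(members):
        for k in range(n_dates):
            m = bool(taxa_missing[k, j])
            rows.append((config.bottle_id, calendar.dates[k], name,
                         np.nan if m else obs_taxa[k, j], m))
    if include_bacteria:
        for k in range(n_dates):
            m = bool(miss_B[k])
            rows.append((config.bottle_id, calendar.dates[k], "bacteria",
                         np.nan if m else obs_B[k], m))
    for k in range(n_dates):
        m = bool(miss_biomass[k])
        rows.append((config.bottle_id, calendar.dates[k], "community_biomass",
                     np.nan if m else biomass[k], m))
    for k in range(n_dates):
        m = bool(miss_O2[k])
        rows.append((config.bottle_id, calendar.dates[k], "oxygen",
                     np.nan if m else obs_O2[k], m))
    for k in range(n_dates):
        m = bool(miss_CN[k])
        rows.append((config.bottle_id, calendar.dates[k], "DOC",
                     np.nan if m else obs_C[k], m))
    for k in range(n_dates):
        m = bool(miss_N2[k])
        rows.append((config.bottle_id, calendar.dates[k], "nitrogen",
                     np.nan if m else obs_N[k], m))

    table = pd.DataFrame(rows, columns=["bottle_id", "date_offset", "variable",
                                        "value", "missing"])
    if return_latent:
        lat = pd.DataFrame(latent, columns=members)
        lat.insert(0, "date_offset", calendar.dates)
        lat["bacteria"] = latent_B
        return table, lat
    return table


def aggregate_biomass(table: pd.DataFrame, biovolumes: dict[str, float],
                      conversion: float = 1e-6) -> pd.DataFrame:
    """Sum taxon rows of a sampling table into community-biomass rows.

    biomass = sum_taxa abundance * biovolume * conversion (ug per um^3 at
    unit density); a date's biomass is missing if any constituent taxon is
    missing at that date.
    """
    taxa = table[~table["variable"].isin(AGGREGATE_VARIABLES)]
    for name in taxa["variable"].unique():
        if name not in biovolumes:
            raise KeyError(f"no biovolume for taxon {name!r}")
    out_rows = []
    for (bottle, date), grp in taxa.groupby(["bottle_id", "date_offset"], sort=True):
        if grp["missing"].any():
            out_rows.append((bottle, date, "community_biomass", np.nan, True))
        else:
            total = float(sum(v * biovolumes[t] * conversion
                              for t, v in zip(grp["variable"], grp["value"])))
            out_rows.append((bottle, date, "community_biomass", total, False))
    return pd.DataFrame(out_rows, columns=["bottle_id", "date_offset", "variable",
                                           "value", "missing"])


def run_experiment(bottles: list[BottleConfig], params: SimParams,
                   calendar: SamplingCalendar, seed: int,
                   pool: SpeciesPool | None = None,
                   phase_lengths: tuple[float, float, float] = (91.0, 91.0, 91.0),
                   include_bacteria: bool = False) -> pd.DataFrame:
    """Simulate every bottle of a design grid into one tidy sampling table.

    Each bottle gets an independent child seed derived from ``seed``; the
    result carries light_regime / richness / incubator metadata columns.
    """
    pool = pool or SpeciesPool.default()
    schedules = {r: build_light_schedule(r, phase_lengths)
                 for r in {b.light_regime for b in bottles}}
    children = np.random.SeedSequence(seed).spawn(len(bottles))
    tables = []
    for config, child in zip(bottles, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        t = simulate_bottle(config, params, schedules[config.light_regime],
                            calendar, seed=sub_seed, pool=pool,
                            include_bacteria=include_bacteria)
        t["light_regime"] = config.light_regime
        t["richness_level"] = config.composition.richness_level
        t["planned_richness"] = config.composition.planned_richness
        t["composition"] = config.composition.id
        t["incubator"] = config.incubator
        tables.append(t)
    return pd.concat(tables, ignore_index=True)
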