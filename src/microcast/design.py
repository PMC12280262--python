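"""Experimental design: species pool, community compositions, light schedules,
sampling calendar, and the bottle grid.

The design encodes a 9-month microcosm experiment crossing three community
richness levels (7, 10, 14 species drawn from an 18-species pool spanning six
functional groups) with two light regimes (constantly high light versus a
gradual decline from 30% to 1% of maximum incubator intensity), sampled three
times per week (Mon/Wed/Fri) for 41 weeks, i.e. 123 sampling days spanning
284 days.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import yaml

FUNCTIONAL_GROUPS = (
    "edible_algae",
    "inedible_algae",
    "bacterivore",
    "omnivore",
    "mixotroph",
    "predator",
)

#: pool sizes per functional group (total 18 species)
GROUP_SIZES = {
    "edible_algae": 2,
    "inedible_algae": 5,
    "bacterivore": 4,
    "omnivore": 4,
    "mixotroph": 2,
    "predator": 1,
}

#: members per functional group at each richness level
LEVEL_GROUP_COUNTS = {
    1: {"edible_algae": 2, "inedible_algae": 1, "bacterivore": 1,
        "omnivore": 1, "mixotroph": 1, "predator": 1},
    2: {"edible_algae": 2, "inedible_algae": 2, "bacterivore": 2,
        "omnivore": 2, "mixotroph": 1, "predator": 1},
    3: {"edible_algae": 2, "inedible_algae": 3, "bacterivore": 3,
        "omnivore": 3, "mixotroph": 2, "predator": 1},
}

PLANNED_RICHNESS = {level: sum(c.values()) for level, c in LEVEL_GROUP_COUNTS.items()}

LIGHT_REGIMES = ("constant", "declining")

#: percent of maximum incubator light intensity
LIGHT_HIGH = 30.0
LIGHT_LOW = 1.0


class DesignError(ValueError):
    """Raised for invalid design inputs (unknown regime, infeasible counts...)."""


@dataclass(frozen=True)
class Species:
    """One member of the species pool.

    biovolume is the per-capita biovolume in um^3 used for biomass
    aggregation; light_dependent marks primary producers and mixotrophs whose
    growth rate saturates with light; reimmigrates=False marks species whose
    stock cultures were lost and that therefore cannot recolonise.
    """

    name: str
    functional_group: str
    biovolume: float
    light_dependent: bool = False
    reimmigrates: bool = True


@dataclass(frozen=True)
class SpeciesPool:
    species: tuple[Species, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise DesignError("species names must be unique")
        counts = {g: 0 for g in FUNCTIONAL_GROUPS}
        for s in self.species:
            if s.functional_group not in counts:
                raise DesignError(f"unknown functional group {s.functional_group!r}")
            counts[s.functional_group] += 1
        if counts != GROUP_SIZES:
            raise DesignError(
                f"functional group sizes {counts} do not match the pool layout {GROUP_SIZES}"
            )

    def members(self, group: str) -> list[Species]:
        return [s for s in self.species if s.functional_group == group]

    def __getitem__(self, name: str) -> Species:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.species]

    @classmethod
    def default(cls) -> "SpeciesPool":
        """The 18-species algae/ciliate pool used throughout.

        Biovolumes are order-of-magnitude values for the genera (algal cells
        10^2-10^3 um^3, ciliates 10^4-10^6 um^3). Two ciliates are flagged as
        unable to re-immigrate, mirroring stock-culture losses.
        """
        sp = [
            # edible algae
            Species("Chlamydomonas", "edible_algae", 250.0, light_dependent=True),
            Species("Cryptomonas", "edible_algae", 400.0, light_dependent=True),
            # inedible algae
            Species("Desmodesmus", "inedible_algae", 300.0, light_dependent=True),
            Species("Staurastrum", "inedible_algae", 2000.0, light_dependent=True),
            Species("Cosmarium", "inedible_algae", 3000.0, light_dependent=True),
            Species("Monoraphidium", "inedible_algae", 120.0, light_dependent=True),
            Species("Synechococcus", "inedible_algae", 30.0, light_dependent=True),
            # bacterivorous ciliates
            Species("Tetrahymena", "bacterivore", 2.0e4, False),
            Species("Colpidium", "bacterivore", 8.0e4, False),
            Species("Dexiostoma", "bacterivore", 4.0e4, False),
            Species("Loxocephalus", "bacterivore", 6.0e4, False),
            # omnivorous ciliates
            Species("Euplotes", "omnivore", 1.5e5, False),
            Species("Stylonychia", "omnivore", 2.5e5, False, reimmigrates=False),
            Species("Blepharisma", "omnivore", 4.0e5, False),
            Species("Frontonia", "omnivore", 6.0e5, False),
            # mixotrophic ciliates
            Species("Paramecium_bursaria", "mixotroph", 3.0e5, light_dependent=True),
            Species("Coleps", "mixotroph", 5.0e4, light_dependent=True),
            # predatory ciliate
            Species("Didinium", "predator", 8.0e5, False, reimmigrates=False),
        ]
        return cls(tuple(sp))


@dataclass(frozen=True)
class Composition:
    """A planned community: a set of pool species at one richness level."""

    id: str
    richness_level: int
    members: frozenset[str]

    @property
    def planned_richness(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class LightSchedule:
    """Light level as percent of maximum incubator intensity over time.

    The declining regime has three phases: high light, a linear-in-percent
    ramp from ``high`` to ``low``, and constant low light.
    """

    regime: str
    phase_lengths: tuple[float, float, float] = (91.0, 91.0, 91.0)
    high: float = LIGHT_HIGH
    low: float = LIGHT_LOW

    def __post_init__(self) -> None:
        if self.regime not in LIGHT_REGIMES:
            raise DesignError(f"unknown light regime {self.regime!r}")
        if any(p <= 0 for p in self.phase_lengths):
            raise DesignError("phase lengths must be positive")

    def level(self, t):
        """Light level (% of max) at day offset ``t`` (scalar or array)."""
        t = np.asarray(t, dtype=float)
        if self.regime == "constant":
            out = np.full_like(t, self.high)
        else:
            p1, p2, _ = self.phase_lengths
            frac = np.clip((t - p1) / p2, 0.0, 1.0)
            out = self.high + (self.low - self.high) * frac
        return float(out) if out.ndim == 0 else out

    def table(self, n_days: int) -> np.ndarray:
        """Per-day light levels for days 0..n_days-1."""
        return self.level(np.arange(n_days, dtype=float))


def build_light_schedule(regime: str,
                         phase_lengths: tuple[float, float, float] = (91.0, 91.0, 91.0),
                         ) -> LightSchedule:
    """Build the light schedule for one regime.

    ``constant`` stays at 30% of maximum intensity; ``declining`` holds 30%
    for the first phase, ramps linearly (in percent per day) down to 1% over
    the second phase, then stays at 1%.
    """
    return LightSchedule(regime=regime, phase_lengths=tuple(float(p) for p in phase_lengths))


@dataclass(frozen=True)
class SamplingCalendar:
    """Day offsets of the Mon/Wed/Fri samplings over 41 weeks (123 dates)."""

    dates: tuple[int, ...]

    @classmethod
    def default(cls, n_weeks: int = 41, weekdays: tuple[int, ...] = (0, 2, 4)) -> "SamplingCalendar":
        dates = tuple(7 * w + d for w in range(n_weeks) for d in weekdays)
        return cls(dates)

    @property
    def n_dates(self) -> int:
        return len(self.dates)

    @property
    def span(self) -> float:
        return float(self.dates[-1] - self.dates[0])

    @property
    def grid_step(self) -> float:
        """Uniform-grid step in days (284/122 = 2.33, printed as 2.3)."""
        return self.span / (self.n_dates - 1)

    def uniform_grid(self) -> np.ndarray:
        return np.linspace(self.dates[0], self.dates[-1], self.n_dates)


def _jaccard_similarity(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def _enumerate_member_sets(pool: SpeciesPool, level: int) -> list[frozenset[str]]:
    per_group = []
    for g in FUNCTIONAL_GROUPS:
        k = LEVEL_GROUP_COUNTS[level][g]
        names = [s.name for s in pool.members(g)]
        if k > len(names):
            raise DesignError(
                f"level {level} needs {k} members from group {g!r} but the pool has {len(names)}"
            )
        per_group.append([frozenset(c) for c in itertools.combinations(names, k)])
    out = []
    for combo in itertools.product(*per_group):
        out.append(frozenset().union(*combo))
    return out


def assemble_compositions(pool: SpeciesPool, n_per_level: int = 5,
                          seed: int = 0) -> list[Composition]:
    """Assemble ``n_per_level`` community compositions at each richness level.

    Within a level, compositions are chosen by a greedy maximin search on
    pairwise Jaccard dissimilarity under a usage-balance constraint: each new
    composition first minimises the total prior usage of its members (keeping
    per-species usage as even as the group-count rules allow), then maximises
    its minimum Jaccard distance to the compositions already chosen, with
    seeded random tie-breaking.
    """
    rng = np.random.default_rng(seed)
    usage: dict[str, int] = {name: 0 for name in pool.names}
    compositions: list[Composition] = []
    for level in sorted(LEVEL_GROUP_COUNTS):
        candidates = _enumerate_member_sets(pool, level)
        chosen: list[frozenset[str]] = []
        for i in range(n_per_level):
            noise = rng.random(len(candidates))
            best, best_key = None, None
            for cand, eps in zip(candidates, noise):
                if cand in chosen:
                    continue
                d = min((1.0 - _jaccard_similarity(cand, c) for c in chosen),
                        default=1.0)
                load = sum(usage[name] for name in cand)
                key = (-load, d, eps)
                if best_key is None or key > best_key:
                    best, best_key = cand, key
            assert best is not None
            chosen.append(best)
            for name in best:
                usage[name] += 1
            compositions.append(
                Composition(id=f"L{level}C{i + 1}", richness_level=level, members=best)
            )
    return compositions


@dataclass(frozen=True)
class BottleConfig:
    """One microcosm bottle: a composition under one light regime."""

    bottle_id: str
    composition: Composition
    light_regime: str
    incubator: str


def build_bottle_grid(compositions: list[Composition],
                      light_regimes: tuple[str, ...] = LIGHT_REGIMES,
                      n_incubators_per_regime: int = 4) -> list[BottleConfig]:
    """Cross every composition with every light regime (30 bottles).

    Each regime has its own set of incubators; bottles are assigned
    round-robin so each incubator holds an (almost) equal number of bottles.
    """
    bottles = []
    i = 0
    for regime_idx, regime in enumerate(light_regimes):
        for j, comp in enumerate(compositions):
            i += 1
            inc = regime_idx * n_incubators_per_regime + (j % n_incubators_per_regime) + 1
            bottles.append(
                BottleConfig(
                    bottle_id=f"B{i:02d}",
                    composition=comp,
                    light_regime=regime,
                    incubator=f"I{inc}",
                )
            )
    return bottles


# ---------------------------------------------------------------------------
# serialization

def design_to_dict(bottles: list[BottleConfig]) -> dict:
    return {
        "bottles": [
            {
                "bottle_id": b.bottle_id,
                "composition": b.composition.id,
                "richness_level": b.composition.richness_level,
                "members": sorted(b.composition.members),
                "light_regime": b.light_regime,
                "incubator": b.incubator,
            }
            for b in bottles
        ]
    }


def save_design(bottles: list[BottleConfig], path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design_to_dict(bottles), fh, sort_keys=False)


def load_design(path: str) -> list[BottleConfig]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    bottles = []
    for b in raw["bottles"]:
        comp = Composition(
            id=b["composition"],
            richness_level=int(b["richness_level"]),
            members=frozenset(b["members"]),
        )
        bottles.append(
            BottleConfig(
                bottle_id=b["bottle_id"],
                composition=comp,
                light_regime=b["light_regime"],
                incubator=b["incubator"],
            )
        )
    return bottles
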