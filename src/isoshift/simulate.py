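"""Synthetic isotope data with known ground truth.

Two generators: bivariate-normal consumer groups moment-matched to a
published summary table (mean, SD, n per species and period), and a forward
model that builds consumers from known diet proportions through the same
mixture structure the fitting code assumes. The built-in scenario tables
describe the Cumberland Sound (Nunavut) predator assemblage — beluga
whale, ringed seal, Greenland halibut and anadromous Arctic char — and its
prey end-members in two sampling windows, 1990–2002 and 2005–2012.

Within-group d13C–d15N correlation is never reported for these data, so the
scenario uses rho = 0 throughout; ``SyntheticSpec`` exposes rho for
sensitivity checks. Every generator takes an explicit seed; there is no
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import (
    BUILTIN_DTDFS,
    ConsumerGroup,
    DiscriminationFactor,
    IsotopeSample,
    SourceDistribution,
)

__all__ = [
    "SyntheticSpec",
    "Scenario",
    "PERIOD_EARLY",
    "PERIOD_LATE",
    "PREDATOR_TABLE",
    "SOURCE_TABLE",
    "PREDATOR_SOURCE_SETS",
    "FORAGE_FISH_SOURCE",
    "generate_group",
    "generate_consumers_from_diet",
    "assemblage_scenario",
]

PERIOD_EARLY = "1990–2002"
PERIOD_LATE = "2005–2012"

#: Published per-period consumer summaries: n, (d13C, d15N) mean, SD, taxon.
PREDATOR_TABLE: dict[tuple[str, str], tuple[int, tuple[float, float], tuple[float, float], str]] = {
    ("beluga", PERIOD_EARLY): (47, (-18.1, 17.2), (0.3, 1.1), "cetacean"),
    ("ringed seal", PERIOD_EARLY): (175, (-18.7, 15.2), (0.6, 0.9), "phocid"),
    ("Greenland halibut", PERIOD_EARLY): (14, (-19.6, 16.6), (0.7, 0.4), "fish"),
    ("Arctic char", PERIOD_EARLY): (72, (-20.0, 15.0), (0.5, 0.7), "fish"),
    ("beluga", PERIOD_LATE): (25, (-18.3, 15.9), (0.4, 0.8), "cetacean"),
    ("ringed seal", PERIOD_LATE): (53, (-19.1, 15.0), (0.5, 0.8), "phocid"),
    ("Greenland halibut", PERIOD_LATE): (21, (-19.4, 16.4), (0.4, 0.7), "fish"),
    ("Arctic char", PERIOD_LATE): (122, (-19.1, 15.0), (0.6, 0.7), "fish"),
}

#: Published prey end-members per period. The late-period forage-fish entry
#: is the pooled Arctic cod/capelin functional group as published (n = 22).
SOURCE_TABLE: dict[str, tuple[SourceDistribution, ...]] = {
    PERIOD_EARLY: (
        SourceDistribution("squid", (-20.3, 11.4), (0.9, 0.9), 7),
        SourceDistribution("shrimp", (-18.7, 13.3), (0.5, 1.0), 10),
        SourceDistribution("Arctic cod", (-19.2, 14.1), (0.5, 1.2), 8),
        SourceDistribution("Greenland halibut", (-19.6, 16.6), (0.7, 0.4), 14),
    ),
    PERIOD_LATE: (
        SourceDistribution("squid", (-19.8, 11.2), (0.6, 1.3), 5),
        SourceDistribution("shrimp", (-18.2, 13.9), (0.2, 0.4), 7),
        SourceDistribution("Arctic cod/capelin", (-20.0, 13.7), (0.4, 0.8), 22),
        SourceDistribution("Greenland halibut", (-19.4, 16.4), (0.4, 0.7), 21),
    ),
}

#: Which sources feed which predator's mixing model. Marine-mammal diets use
#: all four end-members; the two fish predators exclude Greenland halibut.
PREDATOR_SOURCE_SETS: dict[str, tuple[str, ...]] = {
    "beluga": ("squid", "shrimp", "forage fish", "Greenland halibut"),
    "ringed seal": ("squid", "shrimp", "forage fish", "Greenland halibut"),
    "Greenland halibut": ("squid", "shrimp", "forage fish"),
    "Arctic char": ("squid", "shrimp", "forage fish"),
}

#: The forage-fish functional group is a different named source in each
#: period (Arctic cod alone early; pooled cod/capelin late). Cross-period
#: comparisons pair these labels.
FORAGE_FISH_SOURCE: dict[str, str] = {
    PERIOD_EARLY: "Arctic cod",
    PERIOD_LATE: "Arctic cod/capelin",
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Moment specification for one bivariate-normal consumer group."""

    species: str
    period: str
    n: int
    mean: tuple[float, float]
    sd: tuple[float, float]
    rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if not all(s > 0 for s in self.sd):
            raise ValueError("sds must be strictly positive")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must be in (-1, 1)")


def generate_group(
    spec: SyntheticSpec, dtdf: DiscriminationFactor | None = None
) -> ConsumerGroup:
    """Draw n consumers from the bivariate normal the spec describes."""
    rng = np.random.default_rng(spec.seed)
    s1, s2 = spec.sd
    cov = np.array(
        [[s1**2, spec.rho * s1 * s2], [spec.rho * s1 * s2, s2**2]]
    )
    xy = rng.multivariate_normal(np.asarray(spec.mean, dtype=float), cov, size=spec.n)
    samples = tuple(
        IsotopeSample(spec.species, spec.period, float(x), float(y)) for x, y in xy
    )
    if dtdf is None:
        dtdf = DiscriminationFactor("none", (0.0, 0.0), (0.0, 0.0))
    return ConsumerGroup(spec.species, spec.period, samples, dtdf)


def generate_consumers_from_diet(
    p_star: np.ndarray,
    sources: tuple[SourceDistribution, ...],
    dtdf: DiscriminationFactor,
    residual_sd: tuple[float, float],
    n: int,
    seed: int,
    species: str = "synthetic consumer",
    period: str = "synthetic",
) -> ConsumerGroup:
    """Forward-simulate consumers with known true diet proportions.

    Each consumer i mixes an independent draw per source (source value plus
    an independent discrimination draw) weighted by p*, plus residual noise:

        x_i = sum_k p*_k (s_ik + d_ik) + e_i

    which is exactly the generative form the mixing likelihood integrates
    over, so fits on this output are a calibrated recovery test.
    """
    p = np.asarray(p_star, dtype=float)
    if p.ndim != 1 or len(p) != len(sources):
        raise ValueError("p_star length must match the number of sources")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("p_star must lie on the simplex")
    rng = np.random.default_rng(seed)
    mu = np.array([s.mean_arr for s in sources])  # (K, 2)
    om = np.array([s.sd_arr for s in sources])
    K = len(sources)
    s_draw = mu[None] + om[None] * rng.standard_normal((n, K, 2))
    d_draw = dtdf.mean_arr[None, None] + dtdf.sd_arr[None, None] * rng.standard_normal(
        (n, K, 2)
    )
    resid = np.asarray(residual_sd, dtype=float) * rng.standard_normal((n, 2))
    xy = np.einsum("k,nkj->nj", p, s_draw + d_draw) + resid
    samples = tuple(
        IsotopeSample(species, period, float(x), float(y)) for x, y in xy
    )
    return ConsumerGroup(species, period, samples, dtdf)


@dataclass(frozen=True)
class Scenario:
    """One period's simulated assemblage plus its prey table and wiring."""

    period: str
    groups: tuple[ConsumerGroup, ...]
    sources: tuple[SourceDistribution, ...]
    source_sets: dict[str, tuple[str, ...]]

    def group(self, species: str) -> ConsumerGroup:
        for g in self.groups:
            if g.species == species:
                return g
        raise KeyError(species)

    def sources_for(self, species: str) -> tuple[SourceDistribution, ...]:
        """The period-resolved source list for one predator's mixing model."""
        by_name = {s.name: s for s in self.sources}
        ff = FORAGE_FISH_SOURCE[self.period]
        out = []
        for label in self.source_sets[species]:
            out.append(by_name[ff if label == "forage fish" else label])
        return tuple(out)


def assemblage_scenario(period: str, seed: int = 0, rho: float = 0.0) -> Scenario:
    """Build one period of the Cumberland Sound scenario.

    Simulates all four predator groups as independent bivariate normals at
    the published n/mean/SD (correlation ``rho``, default 0) and returns
    them with the period's source table and per-predator source wiring.
    Group seeds are spawned deterministically from ``seed``.
    """
    if period not in (PERIOD_EARLY, PERIOD_LATE):
        raise ValueError(
            f"unknown period {period!r}; expected {PERIOD_EARLY!r} or {PERIOD_LATE!r}"
        )
    rows = sorted(
        (species, vals) for (species, per), vals in PREDATOR_TABLE.items() if per == period
    )
    seeds = np.random.SeedSequence(seed).generate_state(len(rows)) % (2**31)
    groups = []
    for i, (species, (n, mean, sd, taxon)) in enumerate(rows):
        spec = SyntheticSpec(species, period, n, mean, sd, rho=rho, seed=int(seeds[i]))
        groups.append(generate_group(spec, BUILTIN_DTDFS[taxon]))
    return Scenario(
        period=period,
        groups=tuple(groups),
        sources=SOURCE_TABLE[period],
        source_sets=dict(PREDATOR_SOURCE_SETS),
    )
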