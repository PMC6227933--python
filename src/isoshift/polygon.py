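"""Simulated mixing-polygon screening of consumers.

A consumer can only be explained by a mixing model if it lies inside the
convex hull of the discrimination-corrected source means — the mixing
polygon. Because sources and discrimination factors are uncertain, the
polygon itself is uncertain: each Monte-Carlo iteration draws one vertex
per source from

    N(mu_k + lambda, sqrt(omega_k^2 + tau^2))   (per isotope)

and records which consumers fall inside that iteration's hull (boundary
points count as inside, a deliberately conservative rule). A consumer's
inclusion probability is its inside-fraction across iterations; consumers
below a probability threshold are flagged as statistical outliers and
removed before model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._geometry import convex_hull, points_in_hull, _segment_distance
from .data import ConsumerGroup
from .mixing import MixingProblem

__all__ = [
    "PolygonScreenResult",
    "PolygonScreenError",
    "simulate_polygons",
    "filter_outliers",
    "DEFAULT_ITERATIONS",
    "DEFAULT_THRESHOLD",
]

#: 1500 iterations keep the Monte-Carlo SE of an inclusion probability
#: below ~0.006 near the 0.05 decision threshold.
DEFAULT_ITERATIONS = 1500
DEFAULT_THRESHOLD = 0.05
#: Half-width of the degenerate K=2 "polygon" (a segment) in permil.
_SEGMENT_EPS = 1e-8


class PolygonScreenError(Exception):
    pass


@dataclass(frozen=True)
class PolygonScreenResult:
    """Per-consumer inclusion probabilities for one screened group."""

    group: ConsumerGroup
    probabilities: np.ndarray
    iterations: int
    seed: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("inclusion probabilities must lie in [0, 1]")
        if len(p) != len(self.group):
            raise ValueError("one probability per consumer required")
        object.__setattr__(self, "probabilities", p)


def simulate_polygons(
    problem: MixingProblem,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
) -> PolygonScreenResult:
    """Monte-Carlo inclusion probability of each consumer in the mixing polygon."""
    if iterations < 100:
        raise ValueError("need at least 100 polygon iterations")
    X = problem.consumers.xy
    mu_c = np.array([s.mean_arr for s in problem.sources]) + problem.dtdf.mean_arr
    # unclamped: exact point sources give exact (deterministic) vertices
    sd_c = np.sqrt(
        np.array([s.sd_arr**2 for s in problem.sources]) + problem.dtdf.sd_arr**2
    )
    K = mu_c.shape[0]
    if K < 2:
        raise ValueError("polygon screening needs at least 2 sources")
    rng = np.random.default_rng(seed)
    inside = np.zeros(len(X), dtype=np.int64)
    for _ in range(iterations):
        verts = mu_c + sd_c * rng.standard_normal((K, 2))
        if K == 2:
            inside += _segment_distance(X, verts[0], verts[1]) <= _SEGMENT_EPS
        else:
            inside += points_in_hull(X, convex_hull(verts))
    return PolygonScreenResult(
        group=problem.consumers,
        probabilities=inside / iterations,
        iterations=iterations,
        seed=seed,
    )


def filter_outliers(
    result: PolygonScreenResult, threshold: float = DEFAULT_THRESHOLD
) -> tuple[ConsumerGroup, pd.DataFrame]:
    """Drop consumers whose inclusion probability falls below the threshold.

    Returns the retained group and a per-consumer report (species, period,
    d13c, d15n, probability, kept). Raises :class:`PolygonScreenError` if
    nothing survives — the model would be unfittable.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    group = result.group
    keep = result.probabilities >= threshold
    report = pd.DataFrame(
        {
            "species": [s.species for s in group.samples],
            "period": [s.period for s in group.samples],
            "d13c": [s.d13c for s in group.samples],
            "d15n": [s.d15n for s in group.samples],
            "probability": result.probabilities,
            "kept": keep,
        }
    )
    if not keep.any():
        raise PolygonScreenError(
            f"polygon screen removed every consumer in "
            f"({group.species!r}, {group.period!r})"
        )
    retained = replace(
        group,
        samples=tuple(s for s, k in zip(group.samples, keep) if k),
    )
    return retained, report
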