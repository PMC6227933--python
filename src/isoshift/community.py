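"""Community-wide trophic-structure metrics over a predator assemblage.

Six Layman-style metrics are computed on the species' mean positions in
(d13C, d15N) space:

    CR     d13C range among species means (basal carbon-source variability)
    NR     d15N range among species means (trophic-position variability)
    CD     mean Euclidean distance of species means to their centroid
           (trophic diversity)
    MNND   mean nearest-neighbour distance (species packing / redundancy)
    SDNND  SD (n-1) of nearest-neighbour distances (evenness of packing)
    TA     convex-hull area among the species means (total trophic extent;
           the mean-based variant, less sensitive to extreme individuals
           than the all-individuals hull)

The Bayesian version propagates uncertainty in each species' mean: per
posterior draw one mean vector per species is sampled from its conjugate
normal–inverse-Wishart posterior and the metrics are evaluated on those
draws. Predator values must be discrimination-corrected (see
``ConsumerGroup.dtdf_corrected``) before assembly so species sit on a
common prey-equivalent scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geometry import hull_area
from ._stats import equal_tailed_interval
from .data import ConsumerGroup
from .ellipse import DEFAULT_ELLIPSE_DRAWS, _niw_posterior
from .mixing import McmcSettings

__all__ = [
    "METRIC_NAMES",
    "AssemblageSnapshot",
    "CommunityMetricPosterior",
    "layman_metrics",
    "community_posterior",
]

METRIC_NAMES = (
    "d13c_range",
    "d15n_range",
    "mean_dist_centroid",
    "mean_nnd",
    "sd_nnd",
    "total_area",
)


@dataclass(frozen=True)
class AssemblageSnapshot:
    """The species groups of one period, on a common (corrected) scale."""

    period: str
    groups: tuple[ConsumerGroup, ...]

    def __post_init__(self) -> None:
        groups = tuple(self.groups)
        object.__setattr__(self, "groups", groups)
        if len(groups) < 3:
            raise ValueError("an assemblage needs at least 3 species groups")
        species = [g.species for g in groups]
        if len(set(species)) != len(species):
            raise ValueError(f"duplicate species in assemblage: {species}")
        for g in groups:
            if g.period != self.period:
                raise ValueError(
                    f"group {g.species!r} has period {g.period!r}, "
                    f"snapshot is {self.period!r}"
                )

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(g.species for g in self.groups)


def layman_metrics(points: np.ndarray) -> dict[str, float]:
    """The six metrics for S mean positions in delta-space.

    ``points`` is (S, 2) with S >= 3. S = 2 is tolerated for the range and
    nearest-neighbour metrics (TA = 0, with a warning). Duplicate points are
    fine (their nearest-neighbour distance is 0).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    S = len(pts)
    if S < 2:
        raise ValueError("need at least 2 points")
    if S == 2:
        warnings.warn("only 2 points: total_area is degenerate (0)", stacklevel=2)
    centroid = pts.mean(axis=0)
    cd = float(np.mean(np.linalg.norm(pts - centroid, axis=1)))
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    np.fill_diagonal(dist, np.inf)
    nnd = dist.min(axis=1)
    return {
        "d13c_range": float(np.ptp(pts[:, 0])),
        "d15n_range": float(np.ptp(pts[:, 1])),
        "mean_dist_centroid": cd,
        "mean_nnd": float(nnd.mean()),
        "sd_nnd": float(nnd.std(ddof=1)),
        "total_area": hull_area(pts) if S >= 3 else 0.0,
    }


@dataclass
class CommunityMetricPosterior:
    """Per-draw values of the six metrics for one period's assemblage."""

    period: str
    species: tuple[str, ...]
    draws: pd.DataFrame
    seed: int
    settings: McmcSettings | None = None

    def __post_init__(self) -> None:
        if tuple(self.draws.columns) != METRIC_NAMES:
            raise ValueError(f"draw columns must be {METRIC_NAMES}")
        if (self.draws.to_numpy() < 0).any():
            raise ValueError("all metric draws must be non-negative")

    def metric(self, name: str) -> np.ndarray:
        return self.draws[name].to_numpy()

    def summary(self, levels: tuple[float, ...] = (0.5, 0.75, 0.95)) -> pd.DataFrame:
        """Posterior mode (via median) and credible intervals per metric."""
        rows = []
        for name in METRIC_NAMES:
            d = self.metric(name)
            row = {"metric": name, "median": float(np.median(d))}
            for lv in levels:
                lo, hi = equal_tailed_interval(d, lv)
                row[f"lo{int(lv * 100)}"] = lo
                row[f"hi{int(lv * 100)}"] = hi
            rows.append(row)
        return pd.DataFrame(rows)


def community_posterior(
    snapshot: AssemblageSnapshot,
    settings: McmcSettings | None = None,
    n_draws: int = DEFAULT_ELLIPSE_DRAWS,
    seed: int = 0,
) -> CommunityMetricPosterior:
    """Posterior of the six metrics over species mean locations.

    Each retained draw samples one mean vector per species from that
    species' normal–inverse-Wishart posterior and evaluates
    :func:`layman_metrics` on the S means. Species sub-streams are spawned
    deterministically from ``seed``.
    """
    if settings is not None:
        n_draws, seed = settings.retained, settings.seed
    for g in snapshot.groups:
        if len(g) < 3:
            raise ValueError(
                f"group {g.species!r} has {len(g)} samples; need >= 3"
            )
    S = len(snapshot.groups)
    sub = np.random.SeedSequence(seed).spawn(S)
    means = np.empty((n_draws, S, 2))
    for i, g in enumerate(snapshot.groups):
        xy = g.xy
        xbar, kappa_n, nu_n, lambda_n = _niw_posterior(xy)
        rng = np.random.default_rng(sub[i])
        # mu | Sigma, data ~ N(xbar, Sigma/kappa_n) with Sigma ~ IW(nu_n, Lambda_n)
        from scipy import stats as _st

        cov = _st.invwishart.rvs(
            df=nu_n, scale=lambda_n, size=n_draws, random_state=rng
        ).reshape(n_draws, 2, 2)
        chol = np.linalg.cholesky(cov / kappa_n)
        z = rng.standard_normal((n_draws, 2))
        means[:, i, :] = xbar + np.einsum("nij,nj->ni", chol, z)
    rows = np.empty((n_draws, 6))
    for d in range(n_draws):
        m = layman_metrics(means[d])
        rows[d] = [m[k] for k in METRIC_NAMES]
    return CommunityMetricPosterior(
        period=snapshot.period,
        species=snapshot.species,
        draws=pd.DataFrame(rows, columns=METRIC_NAMES),
        seed=seed,
        settings=settings,
    )
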