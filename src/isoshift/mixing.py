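"""Bayesian stable-isotope mixing model for diet-proportion estimation.

The model treats each consumer's (d13C, d15N) pair as a draw from a normal
distribution whose moments are mass-balance mixtures of K prey sources.
For isotope j and diet proportions p on the K-simplex:

    mean_j = sum_k p_k (mu_jk + lambda_j)
    var_j  = sum_k p_k^2 (omega_jk^2 + tau_j^2) + sigma_j^2

where mu/omega are source means/SDs, lambda/tau the discrimination-factor
mean/SD for the consumer taxon, and sigma_j a per-isotope residual SD.
This is the classic SIAR-family formulation: source and discrimination
variability propagate with weight p_k^2, and an additive residual absorbs
consumer variation the sources cannot explain.

Priors are uninformative: Dirichlet(1, ..., 1) on p, and a vague
half-Cauchy (scale 2.5 permil, truncated at 20 permil) on each sigma_j.
Posterior sampling is a random-walk Metropolis on an additive log-ratio
transform of p and on log sigma, with step-size adaptation during burn-in
only, so retained draws come from a fixed-kernel chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import effective_sample_size, equal_tailed_interval
from .data import (
    ConsumerGroup,
    DiscriminationFactor,
    InsufficientDataError,
    IsotopeSample,
    SourceDistribution,
    source_from_samples,
)

__all__ = [
    "McmcSettings",
    "MixingProblem",
    "MixingPosterior",
    "DEFAULT_MIXING_SETTINGS",
    "combine_sources",
    "fit_mixing_model",
    "fit_mixing_ensemble",
    "fit_mixing_replicates",
    "posterior_summary",
]

#: Residual-SD prior: half-Cauchy scale (permil) and hard upper truncation.
_SIGMA_PRIOR_SCALE = 2.5
_SIGMA_MAX = 20.0
#: Point sources get their SD clamped to this inside likelihoods.
_SD_CLAMP = 1e-6


@dataclass(frozen=True)
class McmcSettings:
    """Chain length contract: retained = floor((iterations - burn_in)/thin)."""

    iterations: int
    burn_in: int
    thin: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.retained < 100:
            raise ValueError(
                f"settings retain only {self.retained} draws; need >= 100"
            )

    @property
    def retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


#: The headline run configuration: 500k iterations, 300k burn-in, thin 100,
#: retaining exactly 2000 posterior draws.
DEFAULT_MIXING_SETTINGS = McmcSettings(
    iterations=500_000, burn_in=300_000, thin=100, seed=0
)


@dataclass(frozen=True)
class MixingProblem:
    """One consumer group against an ordered list of prey sources.

    The same discrimination factor (the consumer taxon's) applies to every
    source. Any K >= 1 is representable; fitting K = 1 is a degenerate case
    gated behind a flag in :func:`fit_mixing_model`.
    """

    consumers: ConsumerGroup
    sources: tuple[SourceDistribution, ...]
    dtdf: DiscriminationFactor

    def __post_init__(self) -> None:
        sources = tuple(self.sources)
        object.__setattr__(self, "sources", sources)
        if len(sources) < 1:
            raise ValueError("need at least one source")
        names = [s.name for s in sources]
        if len(set(names)) != len(names):
            raise ValueError(f"source names must be unique, got {names}")
        if len(self.consumers) == 0:
            raise ValueError("consumer group is empty")

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def source_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sources)


@dataclass
class MixingPosterior:
    """Retained MCMC draws of diet proportions and residual SDs.

    ``draws`` is (retained, K) on the simplex; ``residual_sd_draws`` is
    (retained, 2) in permil. ``ess`` holds an effective-sample-size
    diagnostic per proportion; convergence concerns are recorded as strings
    in ``diagnostics`` rather than raised.
    """

    draws: np.ndarray
    residual_sd_draws: np.ndarray
    source_names: tuple[str, ...]
    settings: McmcSettings
    ess: np.ndarray
    diagnostics: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.draws.ndim != 2 or self.draws.shape[0] != self.settings.retained:
            raise ValueError("draws do not honor the retained-count contract")
        sums = self.draws.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-10) or np.any(self.draws < -1e-12):
            raise ValueError("diet-proportion draws must lie on the simplex")

    def proportion(self, source: str) -> np.ndarray:
        """Draws for one source by name."""
        return self.draws[:, self.source_names.index(source)]


def combine_sources(
    a: SourceDistribution | Sequence[IsotopeSample],
    b: SourceDistribution | Sequence[IsotopeSample],
    name: str,
) -> SourceDistribution:
    """Pool two prey groups into a single functional source.

    When raw samples are available for both groups the pooled moments are
    computed on the concatenated samples. Summary-only inputs are pooled by
    the exact two-group identities on (n, mean, sd), which agree with
    concatenation; mixed inputs summarize the raw side first.
    """
    raw_a = not isinstance(a, SourceDistribution)
    raw_b = not isinstance(b, SourceDistribution)
    if raw_a and raw_b:
        merged = list(a) + list(b)
        if not merged:
            raise InsufficientDataError("cannot pool two empty sample sets")
        return source_from_samples(merged, name)
    sa = source_from_samples(list(a), name + "/a") if raw_a else a
    sb = source_from_samples(list(b), name + "/b") if raw_b else b
    na, nb = sa.n, sb.n
    if na < 1 or nb < 1:
        raise InsufficientDataError(
            "summary pooling needs recorded sample sizes on both sources"
        )
    n = na + nb
    ma, mb = sa.mean_arr, sb.mean_arr
    mean = (na * ma + nb * mb) / n
    # exact pooled sum of squares: within-group + between-group parts
    ss = (
        (na - 1) * sa.sd_arr**2
        + (nb - 1) * sb.sd_arr**2
        + (na * nb / n) * (ma - mb) ** 2
    )
    sd = np.sqrt(ss / (n - 1))
    return SourceDistribution(name, tuple(mean), tuple(sd), n)


def _softmax_alr(z: np.ndarray) -> np.ndarray:
    """Map (C, K-1) free parameters to (C, K) simplex points (last pinned)."""
    full = np.concatenate([z, np.zeros((z.shape[0], 1))], axis=1)
    full -= full.max(axis=1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=1, keepdims=True)


def _run_chains(
    X: np.ndarray,
    mu_c: np.ndarray,
    v: np.ndarray,
    settings: McmcSettings,
    n_chains: int,
    rng: np.random.Generator,
    sigma_prior_scale: float = _SIGMA_PRIOR_SCALE,
) -> tuple[np.ndarray, np.ndarray]:
    """Run ``n_chains`` independent chains in lockstep (vectorized).

    ``X`` is one dataset (n, 2) shared by all chains, or one dataset per
    chain (C, n, 2). Returns (p_draws, sigma_draws) with shapes
    (C, retained, K) and (C, retained, 2). The likelihood uses the
    per-isotope sufficient statistics of the consumer data, so iteration
    cost is independent of n.
    """
    if X.ndim == 3 and X.shape[0] != n_chains:
        raise ValueError("per-chain data must supply one dataset per chain")
    n = X.shape[-2]
    K = mu_c.shape[0]
    C = n_chains
    R = settings.retained

    Sx = X.sum(axis=-2)
    Sxx = (X**2).sum(axis=-2)
    log2pi = np.log(2.0 * np.pi)
    s0sq = sigma_prior_scale**2

    def log_target(p: np.ndarray, sigma: np.ndarray) -> np.ndarray:
        m = p @ mu_c
        var = (p**2) @ v + sigma**2
        sse = Sxx - 2.0 * m * Sx + n * m**2
        ll = -0.5 * (n * (log2pi + np.log(var)) + sse / var).sum(axis=1)
        # Dirichlet(1) prior + ALR Jacobian
        lp = np.log(np.clip(p, 1e-300, None)).sum(axis=1) if K > 1 else 0.0
        # truncated half-Cauchy on sigma + log-sigma Jacobian
        ls = (np.log(sigma) - np.log1p(sigma**2 / s0sq)).sum(axis=1)
        ls = np.where((sigma < _SIGMA_MAX).all(axis=1), ls, -np.inf)
        return ll + lp + ls

    z = np.zeros((C, K - 1))
    data_sd = X.std(axis=-2, ddof=1) if n > 1 else np.ones(2)
    lsig = np.broadcast_to(
        np.log(np.maximum(data_sd, 0.1) * 0.5), (C, 2)
    ).copy()
    cur = log_target(_softmax_alr(z) if K > 1 else np.ones((C, 1)), np.exp(lsig))

    step_z = np.full(C, 0.5)
    step_s = np.full(C, 0.4)
    acc_z = np.zeros(C)
    acc_s = np.zeros(C)
    window = 100

    p_out = np.empty((C, R, K))
    s_out = np.empty((C, R, 2))
    r_idx = 0

    for it in range(1, settings.iterations + 1):
        if K > 1:
            z_prop = z + step_z[:, None] * rng.standard_normal((C, K - 1))
            p_prop = _softmax_alr(z_prop)
            new = log_target(p_prop, np.exp(lsig))
            accept = np.log(rng.random(C)) < new - cur
            z[accept] = z_prop[accept]
            cur[accept] = new[accept]
            acc_z += accept

        ls_prop = lsig + step_s[:, None] * rng.standard_normal((C, 2))
        p_cur = _softmax_alr(z) if K > 1 else np.ones((C, 1))
        new = log_target(p_cur, np.exp(ls_prop))
        accept = np.log(rng.random(C)) < new - cur
        lsig[accept] = ls_prop[accept]
        cur[accept] = new[accept]
        acc_s += accept

        if it <= settings.burn_in and it % window == 0:
            # adapt toward ~30% acceptance; frozen after burn-in
            step_z *= np.exp(0.5 * (acc_z / window - 0.3))
            step_s *= np.exp(0.5 * (acc_s / window - 0.3))
            np.clip(step_z, 1e-3, 10.0, out=step_z)
            np.clip(step_s, 1e-3, 10.0, out=step_s)
            acc_z[:] = 0.0
            acc_s[:] = 0.0

        if it > settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            p_out[:, r_idx] = _softmax_alr(z) if K > 1 else 1.0
            s_out[:, r_idx] = np.exp(lsig)
            r_idx += 1

    assert r_idx == R
    return p_out, s_out


def _prepare(problem: MixingProblem) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lam = problem.dtdf.mean_arr
    tau = problem.dtdf.sd_arr
    mu = np.array([s.mean_arr for s in problem.sources])
    om = np.array([np.maximum(s.sd_arr, _SD_CLAMP) for s in problem.sources])
    mu_c = mu + lam
    v = om**2 + tau**2
    return problem.consumers.xy, mu_c, v


def fit_mixing_model(
    problem: MixingProblem,
    settings: McmcSettings,
    *,
    allow_single_source: bool = False,
    sigma_prior_scale: float = _SIGMA_PRIOR_SCALE,
) -> MixingPosterior:
    """Sample the diet-proportion posterior for one consumer group.

    Returns exactly ``settings.retained`` draws. Internally sources are
    processed in name-sorted order and the columns un-permuted afterwards,
    so relabelling/reordering sources permutes posterior columns exactly.
    A low effective sample size (< 100 on any proportion) is recorded in
    ``diagnostics`` as a warning string, not raised.
    """
    if problem.n_sources < 2 and not allow_single_source:
        raise ValueError(
            "a mixing model needs at least 2 sources "
            "(pass allow_single_source=True for the degenerate K=1 case)"
        )
    if len(problem.consumers) < 3:
        raise InsufficientDataError(
            f"group ({problem.consumers.species!r}, "
            f"{problem.consumers.period!r}) has {len(problem.consumers)} "
            "samples; mixing fits need >= 3"
        )
    order = np.argsort(np.array(problem.source_names))
    inverse = np.argsort(order)

    X, mu_c, v = _prepare(problem)
    rng = np.random.default_rng(settings.seed)
    p_draws, s_draws = _run_chains(
        X, mu_c[order], v[order], settings, n_chains=1, rng=rng,
        sigma_prior_scale=sigma_prior_scale,
    )
    draws = p_draws[0][:, inverse]
    ess = np.array([effective_sample_size(draws[:, k]) for k in range(draws.shape[1])])
    diagnostics = [
        f"low effective sample size for p[{problem.source_names[k]}]: {ess[k]:.0f}"
        for k in range(len(ess))
        if ess[k] < 100
    ]
    for msg in diagnostics:
        warnings.warn(msg, stacklevel=2)
    return MixingPosterior(
        draws=draws,
        residual_sd_draws=s_draws[0],
        source_names=problem.source_names,
        settings=settings,
        ess=ess,
        diagnostics=diagnostics,
    )


def fit_mixing_ensemble(
    problem: MixingProblem,
    settings: McmcSettings,
    n_chains: int,
) -> list[MixingPosterior]:
    """Fit ``n_chains`` independent chains of the same problem in lockstep.

    Chains share one vectorized pass over iterations (much cheaper than
    sequential fits) but are statistically independent; chain c is seeded
    from ``settings.seed`` jointly. Use for multi-seed replicate summaries.
    """
    if problem.n_sources < 2:
        raise ValueError("a mixing model needs at least 2 sources")
    order = np.argsort(np.array(problem.source_names))
    inverse = np.argsort(order)
    X, mu_c, v = _prepare(problem)
    rng = np.random.default_rng(settings.seed)
    p_draws, s_draws = _run_chains(
        X, mu_c[order], v[order], settings, n_chains=n_chains, rng=rng
    )
    out = []
    for c in range(n_chains):
        draws = p_draws[c][:, inverse]
        ess = np.array(
            [effective_sample_size(draws[:, k]) for k in range(draws.shape[1])]
        )
        out.append(
            MixingPosterior(
                draws=draws,
                residual_sd_draws=s_draws[c],
                source_names=problem.source_names,
                settings=settings,
                ess=ess,
                diagnostics=[],
            )
        )
    return out


def fit_mixing_replicates(
    problems: Sequence[MixingProblem],
    settings: McmcSettings,
) -> list[MixingPosterior]:
    """Fit the same mixing problem over replicate consumer datasets.

    All problems must share the source list, discrimination factor and
    consumer count (replicate simulations of one group); one chain per
    dataset runs in a single vectorized pass, seeded jointly from
    ``settings.seed``.
    """
    base = problems[0]
    for p in problems[1:]:
        if p.source_names != base.source_names:
            raise ValueError("replicates must share the same sources")
        if len(p.consumers) != len(base.consumers):
            raise ValueError("replicates must share the consumer count")
    order = np.argsort(np.array(base.source_names))
    inverse = np.argsort(order)
    _, mu_c, v = _prepare(base)
    X = np.stack([p.consumers.xy for p in problems])
    rng = np.random.default_rng(settings.seed)
    p_draws, s_draws = _run_chains(
        X, mu_c[order], v[order], settings, n_chains=len(problems), rng=rng
    )
    out = []
    for c in range(len(problems)):
        draws = p_draws[c][:, inverse]
        ess = np.array(
            [effective_sample_size(draws[:, k]) for k in range(draws.shape[1])]
        )
        out.append(
            MixingPosterior(
                draws=draws,
                residual_sd_draws=s_draws[c],
                source_names=base.source_names,
                settings=settings,
                ess=ess,
                diagnostics=[],
            )
        )
    return out


def posterior_summary(
    post: MixingPosterior, level: float = 0.95, digits: int | None = None
) -> pd.DataFrame:
    """Per-source median and equal-tailed credible interval, in percent.

    ``digits=0`` reproduces whole-percent presentation (e.g. "63 (51-74)").
    """
    if post.draws.size == 0:
        raise RuntimeError("posterior has no draws")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rows = []
    for k, name in enumerate(post.source_names):
        d = post.draws[:, k] * 100.0
        lo, hi = equal_tailed_interval(d, level)
        med = float(np.median(d))
        if digits is not None:
            med, lo, hi = (round(x, digits) for x in (med, lo, hi))
            if digits == 0:
                med, lo, hi = int(med), int(lo), int(hi)
        rows.append({"source": name, "median_pct": med, "lo_pct": lo, "hi_pct": hi})
    return pd.DataFrame(rows)
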