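# isoshift

Bayesian stable-isotope analysis of temporal shifts in the trophic
structure of a predator assemblage. The package implements, as one tested
pipeline, the standard toolkit of quantitative trophic ecology for paired
δ¹³C/δ¹⁵N data:

- **diet-proportion mixing models** (SIAR-family likelihood, Dirichlet
  prior, dependency-free MCMC),
- **isotopic niche size** as the Bayesian standard ellipse area (SEA_B),
- **six community-wide (Layman) metrics** with full posterior uncertainty,
- **simulated mixing-polygon screening** of consumers the model cannot
  explain, and
- **paired-posterior probability-of-change statistics** between two
  sampling periods, plus ordinary trend regressions for environmental
  series.

It is written for ecologists asking whether and how a set of co-occurring
predators changed its diet and trophic organisation between two time
windows — the motivating system is the Cumberland Sound (Nunavut) marine
assemblage of beluga whale, ringed seal, Greenland halibut and anadromous
Arctic char, sampled before (1990–2002) and after (2005–2012) a rise in
capelin availability, and that two-period scenario ships with the package
as a moment-matched synthetic data generator.

## The models

**Mixing model.** For a consumer group with K prey sources, isotope
j ∈ {δ¹³C, δ¹⁵N} of individual i is modelled as

    x_ij ~ Normal( Σ_k p_k (μ_jk + λ_j),  Σ_k p_k² (ω_jk² + τ_j²) + σ_j² )

where (μ_jk, ω_jk) are the source mean and SD, (λ_j, τ_j) the
diet-to-tissue discrimination factor (DTDF) mean and SD for the consumer
taxon, p the diet-proportion vector on the simplex and σ_j a residual SD.
Priors are uninformative: p ~ Dirichlet(1, …, 1) and a vague half-Cauchy
on σ_j. Sampling is random-walk Metropolis on a log-ratio transform of p,
adaptive during burn-in only; the default settings (500 000 iterations,
300 000 burn-in, thin 100) retain exactly 2000 draws.

**Niche size.** The standard ellipse is the 1-SD contour of a bivariate
normal fitted to a group — it covers 1 − e^(−1/2) ≈ 39.4% of the data and
has area SEA = π√(det Σ). SEA_B places a vague conjugate
normal–inverse-Wishart prior on (μ, Σ) and reports the exact posterior of
the area (10 000 draws by default).

**Community metrics.** On the DTDF-corrected species mean positions:
δ¹³C range, δ¹⁵N range, mean distance to centroid, mean and SD of the
nearest-neighbour distance, and total area (convex hull of the species
means). Per posterior draw, one mean vector per species is sampled from
its normal–inverse-Wishart posterior and the metrics are evaluated on
those means.

**Change statistics.** P(quantity higher in period B than A) = fraction of
index-wise paired posterior draws with b > a, ties counting half.

## Worked example

Simulate the early-period assemblage, fit the ringed-seal mixing model
(4 sources, phocid DTDF Δ¹³C 1.3‰ / Δ¹⁵N 2.4‰), and ask whether
forage-fish consumption rose in the later period:

```python
from isoshift import (McmcSettings, MixingProblem, fit_mixing_model,
                      posterior_summary, sea_b, probability_greater,
                      assemblage_scenario)

sc = assemblage_scenario("1990–2002", seed=0)
seal = sc.group("ringed seal")
post = fit_mixing_model(
    MixingProblem(seal, sc.sources_for("ringed seal"), seal.dtdf),
    McmcSettings(iterations=100_000, burn_in=40_000, thin=30, seed=1),
)
print(posterior_summary(post, digits=0).to_string(index=False))
```

```
           source  median_pct  lo_pct  hi_pct
            squid          62      56      67
           shrimp           6       0      15
       Arctic cod           9       1      26
Greenland halibut          22      14      28
```

So this simulated seal population takes about 62% (95% credible interval
56–67%) of its diet from squid and under 10% from Arctic cod. Continuing,

```python
ellipse = sea_b(seal, n_draws=10_000, seed=2)          # niche size
late = assemblage_scenario("2005–2012", seed=0)
seal_late = late.group("ringed seal")
post_late = fit_mixing_model(
    MixingProblem(seal_late, late.sources_for("ringed seal"), seal_late.dtdf),
    McmcSettings(iterations=100_000, burn_in=40_000, thin=30, seed=3),
)
dp = probability_greater(post_late.proportion("Arctic cod/capelin"),
                         post.proportion("Arctic cod"))
print(f"median SEA_B = {ellipse.median_area:.1f} permil^2")
print(f"P(forage-fish contribution higher in 2005–2012) = {dp.probability:.3f}")
```

```
median SEA_B = 2.0 permil^2
P(forage-fish contribution higher in 2005–2012) = 1.000
```

i.e. a niche of about 2 ‰² and a near-certain between-period increase in
forage-fish consumption.

The same analysis runs as numbered stages (`analysis/01_simulate_data.py`
… `analysis/06_compare_periods.py`, writing tables under `results/`) or in
one shot from the shell:

```
isoshift run-all --out results/full --seed 0
```

## Layout

```
src/isoshift/     library: data model, mixing, polygon screen, ellipses,
                  community metrics, comparisons, synthetic data, pipeline, CLI
analysis/         numbered narrative drivers over the library
scripts/          acceptance recomputation
tests/            pytest suite (unit, property and end-to-end checks)
docs/methods.md   modelling assumptions, numerical choices, limitations
```
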