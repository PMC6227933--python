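# Methods

This note records the models the package implements, the assumptions and
numerical choices behind them, and what the synthetic-data scenario does
and does not establish.

## Data model and conventions

Isotope values are per-mil delta values (δ¹³C vs PDB carbonate, δ¹⁵N vs
atmospheric N₂), stored as given — lipid correction is assumed to have
happened upstream and no normalization arithmetic is applied. Period
labels are opaque strings; nothing parses years out of them. CSV I/O is
comma-delimited UTF-8 with "." decimals; the en-dash in labels like
"1990–2002" is preserved verbatim. Group SDs use the n−1 denominator
throughout.

Built-in diet-to-tissue discrimination factors (muscle): phocid
(Δ¹³C 1.3‰, Δ¹⁵N 2.4‰), cetacean (1.3‰, 1.2‰), fish (1.2‰, 2.1‰), each
with SD 0.2‰ on both isotopes. One DTDF applies to all sources of a given
consumer.

## Mixing model

Likelihood (per consumer i, isotope j, K sources):

    x_ij ~ N( Σ_k p_k (μ_jk + λ_j),  Σ_k p_k²(ω_jk² + τ_j²) + σ_j² )

This is the SIAR-family formulation: source and discrimination variances
propagate with weight p_k², and an additive per-isotope residual σ_j
absorbs consumer variation the sources cannot explain (including
consumers that sit outside the source mixing polygon). Priors:
p ~ Dirichlet(1,…,1); σ_j half-Cauchy with scale 2.5‰ truncated at 20‰
(weakly informative and scale-free at data magnitudes of ~1‰; at the
sample sizes used here the posterior is insensitive to this choice — the
test suite refits one problem with an independent JAGS implementation of
the same likelihood under a uniform σ prior and requires the posterior
medians to agree).

Sampling is random-walk Metropolis in two blocks: the additive log-ratio
transform of p (K−1 free parameters; the Dirichlet(1) prior plus the ALR
Jacobian contributes Σ log p_k) and log σ. The ALR was preferred over a
sum-constrained centered transform because it has no unidentified
direction under isotropic proposals. Step sizes adapt toward ~30%
acceptance every 100 iterations during burn-in only, so retained draws
come from a fixed-kernel chain. Retained-draw count is exactly
floor((iterations − burn_in)/thin); the default 500 000/300 000/100
retains 2000 draws. Zero source SDs are accepted but clamped to 10⁻⁶‰
inside likelihoods.

Internally sources are processed in name-sorted order and the posterior
columns un-permuted afterwards, which makes relabelling/reordering of
sources permute posterior columns exactly (bit-for-bit) under a fixed
seed. An effective-sample-size diagnostic (Geyer initial positive
sequence) is attached per proportion; ESS < 100 produces a recorded
warning, never an exception. K = 1 is a degenerate case (p ≡ 1) gated
behind an explicit flag; the likelihood cost per iteration is
n-independent (sufficient statistics), and replicate datasets or chains
run vectorized in lockstep.

Source pooling (e.g. merging two forage-fish species into one functional
group) uses exact two-group pooling identities on (n, mean, sd),
identical to concatenate-and-summarize. Note the n−1 denominator means
pooling two equal-mean groups shrinks the SD by O(1/n) relative to the
inputs; that is a property of the sample SD, not an approximation.

## Polygon screening

Each Monte-Carlo iteration draws one vertex per source from
N(μ_k + λ, √(ω_k² + τ²)) per isotope, forms the convex hull and tests
every consumer for membership (boundary counts as inside — removal is
deliberately conservative). Defaults: 1500 iterations (SE of an inclusion
probability < 0.006 near the 0.05 threshold) and removal threshold 0.05.
Vertex draws use the raw SDs (no clamp), so exact point sources give a
deterministic hull test. K = 2 degenerates to a segment, handled as a
width-10⁻⁸‰ band.

Inclusion probability is *not* monotone in the source SDs for interior
consumers: as vertex noise grows, the hull wobbles off a central point
(in the limit the inclusion probability of the centroid of three
i.i.d.-noise vertices falls to 1/4). Monotonicity does hold, and is
tested, for consumers outside the nominal polygon.

In the end-to-end pipeline the screen is reported for every group but a
group is kept unscreened (with a logged note) if filtering would leave
fewer than 3 consumers. This matters for moment-matched simulations of
groups like Greenland halibut, whose published mean lies outside the
corrected source polygon — there the residual term, not consumer removal,
is what the published analysis relied on.

## Standard ellipse area

SEA = π√(det Σ) (the 1-SD ellipse; ≈39.35% coverage). SEA_B uses the
exact conjugate normal–inverse-Wishart posterior with a vague proper
prior: prior mean pinned at the sample mean, κ₀ = 10⁻³, ν₀ = 3, scale
10⁻³·I. Because conjugacy gives the posterior in closed form, draws are
sampled independently rather than by a Markov chain; when chain settings
are supplied their retained-draw contract is honored, and the default is
10 000 draws. (The published chain arithmetic for this stage — 2 000 000
iterations, 100 000 burn-in, thin 10, "10 000 estimates" — is internally
inconsistent; the 10 000 retained-draw count is treated as authoritative
for all comparisons.) SEA rather than the small-sample-corrected SEAc is
reported, matching the use of posterior medians. A χ² quantile–quantile
diagnostic (ordered squared Mahalanobis distances vs χ²₂ quantiles, with
the maximum absolute deviation as scalar summary) supports the normality
assumption behind the ellipse.

## Community-wide metrics

Computed on species mean positions in δ-space after subtracting each
taxon's DTDF mean from every individual (common prey-equivalent scale):
δ¹³C range, δ¹⁵N range, mean distance to centroid, mean nearest-neighbour
distance, its SD (n−1), and total area as the convex hull of the species
means (less outlier-sensitive than the all-individuals hull, and always
bounded above by it). The community ranges are computed among per-draw
species means — deliberately distinct from the per-species individual
ranges reported by the descriptive summaries; both exist as separate
quantities. The Bayesian version draws one mean vector per species per
draw from the same normal–inverse-Wishart posterior used for SEA_B
(10 000 draws by default) and evaluates the metrics per draw. Hull area
uses Andrew's monotone chain plus the shoelace formula; collinear
configurations return area 0.

## Change statistics and trends

P(B > A) pairs draws index-wise (the longer vector is subsampled without
replacement, seeded, if lengths differ) and counts ties as one half,
making the statistic exactly antisymmetric; for continuous draws it
coincides with the strict count. Mixing posteriors are compared on
matched source labels (the forage-fish functional group carries a
different name in each period). Environmental trends use ordinary least
squares with the standard t-based slope p-value; proportions are
logit-transformed, with exact 0/1 clamped to 10⁻⁴ (warned).

## Synthetic data

The generator produces (a) bivariate-normal consumer groups
moment-matched to a published summary table — the built-in scenario
carries the two-period Cumberland Sound assemblage (per-group n of 47,
175, 14, 72 early and 25, 53, 21, 122 late, with the published means and
SDs) and its prey source tables — and (b) forward-simulated consumers
with known diet proportions p*, drawn from exactly the generative form
the likelihood integrates over (independent source and DTDF draws per
consumer and source, plus residual noise), so recovery tests are
calibrated. Within-group δ¹³C–δ¹⁵N correlation is never published for
these data; the scenario therefore uses ρ = 0, with ρ exposed for
sensitivity analyses. Every spec carries its own seed; there is no global
random state.

What passing tests on this scenario do **not** show about real data: real
consumer clouds may be correlated, skewed or contaminated; the published
analysis screened real individuals before fitting (the simulated clouds
are screened differently because their tails follow the normal, not the
data); and per-individual quantities (e.g. individual isotope ranges)
depend on features a moment-matched simulation cannot pin down. The
per-dataset spread of a simulated posterior-median contribution is 2–3
percentage points for the larger groups, which is why replicate averages
are used wherever a single headline number is quoted.

## Problem sizes and tolerances

The test suite runs scaled-down chains (80 000–120 000 iterations) that
always retain 2000 draws for mixing checks, 3 replicate datasets per
headline contribution, 12 replicates for ellipse medians, and 2000-draw
posteriors for community checks; the acceptance script uses the full
500 000/300 000/100 settings with 10 replicates per target. Posterior
medians of contributions are asserted within published 95% credible
bands; planted diet proportions must be recovered within ±0.07 at
n = 100; closed-form identities (SEA, OLS, pooling, quantiles) are
asserted against independent oracles at 10⁻⁹–10⁻¹⁰ absolute tolerance.

## Known limitations

No concentration dependence, isotope routing, hierarchical
individual-level effects or informative priors in the mixing model; no
ellipse-overlap statistics; no tissue-turnover modelling; environmental
series are fit but not acquired (no external data downloads). The
random-walk sampler is adequate for K ≤ 4 sources; larger K would warrant
a gradient-based sampler.
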