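# Methods

`weanling` reconstructs infant-feeding histories from incremental dentine
stable-isotope profiles of permanent first molars (M1). An M1's dentine
records diet from roughly 3 months to 9.5 years of age; serial sections
along the tooth therefore form a sub-annual dietary archive of early
childhood. The package chains four models: collagen quality control,
depth-to-time deconvolution, change-point detection of breastfeeding
cessation, and time-resolved dietary mixing. This note records the models,
their assumptions, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## Pipeline design: point-estimate hand-off

The stages are deliberately chained through point estimates: the temporal
stage passes only per-bin posterior *means* of δ¹⁵N and δ¹³C to the
change-point and mixing stages, and the mixing stage receives the
cessation *posterior median*. A joint model would propagate uncertainty
between stages but is much harder to make converge and to audit; with
fairly uniform sectioning, bin means are well determined and the chained
approach introduces little bias. The cost is that downstream credible
intervals do not include first-stage uncertainty; the coverage study
below measures the net effect empirically.

## Collagen quality control (`profile_io`)

Each increment is screened on the atomic C:N ratio
(%C/12.011)/(%N/14.007) and elemental floors. Defaults are the
conventional collagen-preservation window — C:N in [2.9, 3.6], %C ≥ 13,
%N ≥ 4.8 — and are configurable. Exclusion operates on whole individuals:
when more than `max_failed_fraction` (default 0.5) of a profile's
increments fail, the individual is removed, because a profile with
unreliable chemistry cannot support a life-history reconstruction even if
scattered increments pass.

## Depth-to-time model (`tooth_time`)

Tooth growth decelerates with age, so equal dentine slices cover unequal
age spans. A piecewise-linear growth model maps relative position along
the dentine to age; the default three-point curve (0 → 0.25 y,
0.45 → 3.0 y, 1 → 9.5 y) encodes faster crown-side growth and is
configurable per tooth. Increment age intervals are intersected with a
fixed half-year age grid to form an overlap matrix W whose rows sum
to 1. The grid runs from 0.25 y in exact 0.5-y bins until 9.5 y is
covered (the final bin ends at 9.75 y and is simply never observed).

The measurement model is

    y_i ~ Normal( Σ_j W[i,j] · x_j , σ ),   x_{j+1} − x_j ~ Normal(0, τ),

with half-normal priors on σ and τ (default scales 1 ‰) and a weak
Normal(ȳ, 10²) anchor on the first bin. Given (σ, τ) the model is
linear-Gaussian, so the per-bin values are never sampled by MCMC: the
two-dimensional marginal posterior over (log σ, log τ) is integrated on a
48 × 32 log-spaced grid (exact Gaussian evidence via the matrix inversion
and determinant lemmas), and per-bin draws are taken from the exact
Gaussian conditional at hyperparameter cells sampled by weight. Draws are
therefore exact and the split-R̂ gate (≤ 1.05, computed on pseudo-chains
for parity with the sampled stage) passes by construction; it remains as
a guard against degenerate weight collapse. Bins with no measurement
overlap are flagged `observed = False`, carry prior-driven wide
intervals, and are excluded from downstream input rather than silently
imputed.

## Cessation change-point model (`changepoint`)

The δ¹⁵N life history of a breastfed child declines from a ¹⁵N-enriched
nursing plateau (milk sits one trophic level above the maternal diet) to
a post-weaning baseline; the age at which the decline ends marks
cessation of breastfeeding. The binned δ¹⁵N means are fit with
continuous piecewise-linear Gaussian regressions of 2–4 segments, each
with and without a negative-slope prior on the first segment — six
candidates. Every candidate is a genuine change-point model: a 1-segment
line cannot place a change point, and under the parsimony rule below it
would win whenever its ELPD deficit stays within five standard errors,
which happens regularly even on clear decline-plateau profiles because
the deficit concentrates on the few declining bins and inflates the
paired standard error. The absence of a nursing signal is instead
diagnosed from the slope posterior (below).

Priors: change points jointly uniform-ordered over the observed span;
slopes Normal(0, 10²) ‰/yr, the first truncated negative when
constrained; intercept Normal(ȳ, 10²); noise sd half-Normal(0, 5). The
likelihood predicts each bin by the *exact average* of the piecewise mean
over the bin (not its midpoint value): the observations are bin means,
and midpoint evaluation biases the change point late by roughly +0.1 y
because averaging across the kink raises the kink bin.

Computation is again exact rather than sampled. Given the change points
and σ, the linear coefficients are Gaussian and integrate out in closed
form; a constrained first slope contributes the truncated-normal evidence
factor Φ(−μ₁/s₁)/½ computed from the untruncated posterior marginal. The
remaining posterior over (change points, σ) is integrated on an ordered
change-point grid (160/64/32 interior points for 2/3/4 segments) crossed
with a two-pass log-spaced σ grid of 25 points (the second pass zooms
onto the range carrying posterior mass). Change-point posteriors are
routinely multimodal — a weak-break mode coexists with the main one —
which traps ensemble samplers (split-R̂ stuck near 1.1–1.7 in our trials)
but is immaterial to quadrature. Posterior draws are exact: a grid cell
by weight, then coefficients from their Gaussian (or truncated-Gaussian)
conditional.

**Model ranking.** Candidates are scored by PSIS-LOO ELPD (ArviZ).
Observations whose Pareto k̂ exceeds 0.7 are recomputed exactly on the
fit's quadrature grid — the grid analogue of refit-based "reloo": the
one-observation-out predictive density is closed-form per cell (Woodbury
identity on the marginal covariance, rank-one downdates for the
truncation factor). The ELPD difference of every candidate to the best
model is divided by the paired standard error of the difference;
candidates with ratio > 5 are excluded, and among the survivors the spec
with the fewest parameters wins (ties: fewer segments, then the
unconstrained variant). This two-stage rule deliberately favours the
simplest model consistent with the data, so a clean decline-then-plateau
is read as two segments.

**Cessation interval.** If the posterior probability that the first slope
is negative falls below 0.9 (or a direct 1-segment fit is supplied), the
individual is reported as `no_descending_trend` — the pattern expected
when maternal-diet shifts mask the nursing signal. Otherwise the
cessation age is the change point terminating the initial descending run:
the first change point after which the posterior-mean slope stops
decreasing and is at least −0.1 ‰/yr; for a 2-segment selection this is
the single change point. Equal-tailed 68% and 95% credible intervals are
reported, and individuals are classified against a reference cessation
age (default 2.0 y) as `above`/`below` (both intervals clear of the
threshold) or `straddling`.

## Dietary mixing (`mixing`)

A concentration-dependent Bayesian mixing model in the FRUITS tradition
estimates per-bin protein-source contributions f (a simplex over K
sources) from the binned δ¹³C/δ¹⁵N means. For isotope e,

    δ_e ~ Normal( Σ_k w_k (μ_k,e + Δ_k,e),
                  √( Σ_k w_k² (s_k,e² + τ_k,e²) + σ_e² ) ),
    w_k = f_k C_k / Σ_j f_j C_j,

where μ ± s are source signatures, Δ ± τ diet-to-collagen offsets
(defaults +4.8 ± 0.5 ‰ for δ¹³C, +5.5 ± 0.5 ‰ for δ¹⁵N), and C_k
relative protein concentrations. Signatures and offsets enter the mean
linearly given (f, C), so their uncertainty is marginalised *exactly*
into the likelihood variance; concentrations, which enter nonlinearly,
are sampled as latent truncated normals, and σ_e is a residual term
(half-normal, scale 0.3 ‰). The contribution prior is a flat Dirichlet
per bin (logit/softmax parameterisation with the exact Jacobian).

Human-milk structure ties the model to the cessation estimate: milk is
fixed at 1 for bins ending at or before the complementary-feeding onset
(default 0.5 y, the 4–6-month consensus), is exactly 0 for bins starting
at or after the cessation age, and declines monotonically in between —a
hard non-increasing constraint implemented by chained shrinkage
(f_milk,b = f_milk,b−1 · u_b with u_b ∈ (0,1)), so the constraint holds
in every draw by construction. Setting `milk_monotone=False` frees the
per-bin milk share as a soft alternative.

This stage is the one genuinely sampled model (the simplex blocks are
high-dimensional and non-Gaussian): an affine-invariant ensemble with
differential-evolution moves (emcee), 4·ndim walkers (minimum 64),
10 000 steps with the first half discarded, thinned to ~25 000 retained
draws. Convergence is gated on split-R̂ ≤ 1.05 of the reported per-bin
fractions; a failing fit is retried once with a doubled chain before the
error propagates. Only the protein fraction is modelled — no
energy-routing across macronutrients.

The bundled `roman_italy_demo` source table (C3 plants, C4 cereals,
terrestrial animal products, marine fish, human milk) is a synthetic
illustration for demonstrations and tests, not a measured baseline; real
analyses must supply their own source CSV.

## Synthetic cohorts (`synthetic`)

The generator emulates the canonical M1 weaning signal: δ¹⁵N on a nursing
plateau (baseline + enrichment) until weaning onset, declining linearly
to the baseline at the cessation age, flat afterwards; δ¹³C follows the
same schedule at 0.4× amplitude, keeping carbon the weaker signal as in
real profiles. Defaults: onset 0.5 y, enrichment 2.5 ‰, baseline
δ¹⁵N 9.0 ‰ / δ¹³C −20.0 ‰, noise sd 0.15 ‰, 14 equal dentine slices of a
16-mm tooth aged through the default growth curve. Measurements are exact
latent averages over each increment's age span plus Gaussian noise;
collagen chemistry is drawn inside the QC window unless the degrade flag
marks a fraction (default 0.6) of increments as failing, emulating a
poorly preserved burial. Cohorts draw per-individual cessation ages
Normal(μ_site, sd_site) truncated to [1, 6] y; the two-site contrast
study uses μ = 1.8 vs 3.0 y with a within-site sd of 0.35 y.

What the generator does *not* emulate — maternal-diet shifts,
illness-driven δ¹⁵N excursions, tooth wear, inter-individual growth-curve
variation, non-Gaussian measurement error — bounds what green tests mean:
they demonstrate correct recovery when the decline-plateau model is true,
not robustness to physiological stress signals or growth-model
misspecification in archaeological material.

## Validation studies and problem sizes

The studies in `weanling.experiments` (run by `analysis/04`, the
acceptance tests and `scripts/acceptance.py`) use: 50 replicate
individuals for change-point coverage; 50 replicates split across 1-/2-/
3-segment truths (noise 0.1 ‰) for selection recovery; two fixture series
of 8 and 10 bins for the LOO-vs-refit oracle; 10 seeds of a static
3-source recovery plus 10 five-bin weaning cohorts (milk + two foods) for
mixing; and 5 replicates of the two-site experiment (n = 10 per site).
These sizes keep the full battery in the tens of minutes on one core
while leaving the binomial noise on reported rates at a few percent.

## Known limitations

- Two-step hand-off: downstream intervals understate total uncertainty;
  the coverage study quantifies the net effect (≈ 86% at nominal 95%
  under the standard conditions).
- Change-point draws are quantized at the grid resolution (≈ 0.06 y for
  2-segment selections), which is well below reporting precision.
- The default growth curve is a stylised M1 schedule; analyses of real
  teeth should substitute a histologically informed curve.
- `no_descending_trend` is operationalised as P(slope₁ < 0) < 0.9; the
  underlying phenomenon has no canonical cutoff.
- The mixing model resolves sources only as far as the supplied baseline
  separates them; with two isotopes, strongly collinear sources are
  identified mainly through their priors.
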