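# Methods

This note documents the models, conventions and numerical choices behind
nestrhythm, and what the synthetic validation does and does not establish.

## Segmentation

A recording is a strictly ordered, non-overlapping sequence of annotated
calls. The silent gap between consecutive calls (next onset − current
offset) assigns each junction to one of four bands:

| gap (s)        | junction                     |
|----------------|------------------------------|
| ≤ 0.2          | within a combination         |
| (0.2, 2]       | between combinations, one bout |
| (2, 20]        | between bouts, one series    |
| > 20           | between series               |

Band closure is half-open on the lower side: a gap exactly equal to a
threshold stays in the tighter unit. The inclusive upper bound at 0.2 s
follows the "0.2 s or less" convention for combinations; the other two
follow the strict "more than" lower bounds of their bands. This makes the
classification exhaustive — every non-negative gap falls in exactly one
band — and the tree unique (one bottom-up pass, each gap classified once).
Overlapping calls are rejected rather than merged: gap-based grouping is
undefined for overlaps. Abutting calls (gap = 0) are valid and share a
combination.

The gap used for segmentation (offset-to-onset) is deliberately distinct
from the inter-onset interval t_k (onset-to-onset) used for rhythm
statistics; both conventions and all thresholds are configurable.

## Ratio statistic and rhythmic-category bins

Within each parent unit, t_k is the onset-to-onset interval between
consecutive children, and r_k = t_k / (t_k + t_{k+1}) for consecutive
interval pairs under the same parent. Ratios never straddle a parent
boundary, so a within-bout interval is never paired with a between-bout
interval.

Each rhythmic category (1:1, 1:2, 1:3, 2:1) has a closed on-integer bin
around its nominal ratio (0.5, 1/3, 1/4, 2/3) and a two-segment off-integer
bin flanking it; the two off segments are aggregated into a single "off"
label whose width is the sum of the segment widths (e.g. 1:1 off
= (0.444 − 0.4) + (0.6 − 0.555) = 0.089), since the inference compares
"off vs on" as two factor levels. The default boundaries are the 3-decimal
values conventional in the comparative-rhythm literature; they are decimal
truncations of small fractions (0.444 = 4/9, 0.308 = 4/13, …) and an exact
-fraction scheme is available (`RatioBinScheme.exact_fractions()`), under
which the r ↔ 1−r mirror symmetry (1:2 ↔ 2:1, 1:1 ↔ itself) is exact;
under the truncated defaults it holds to the stated 3-decimal resolution
except at the truncated 1:1 edges.

Boundary points shared by an on bin and its own off bin belong to the on
bin; points shared by two adjacent off regions (0.4, 0.6, 0.286) are
resolved by a fixed category order (1:1, 1:2, 1:3, 2:1 — first match
wins). Both rules are measure-zero for continuous data but make
classification a deterministic total function into the labels ∪
{unbinned}.

Density summaries use a Gaussian kernel on (0, 1) with reflection at both
boundaries (so the estimate integrates to one on the unit interval) and a
Silverman-type bandwidth floored at 0.005. Densities are for inspection
and plotting only; no inference consumes them.

## Count model (rhythmic-category test)

For each level (and separately within each context subset), the response
is the zero-filled r_k count y_ij of recording i in bin j. The model is a
zero-inflated Poisson with a recording random intercept:

    y_ij | u_i ~ ZIP(λ_ij, π),
    log λ_ij = β_{bin(j)} + log w_j + u_i,   u_i ~ N(0, σ_u²),
    logit π = γ₀,
    P(y = 0) = π + (1 − π) e^{−λ},  P(y = k ≥ 1) = (1 − π) e^{−λ} λ^k / k!.

The bin width w_j enters as an offset, so β are log ratio *densities*
(counts per unit ratio-width) and are comparable between the unequal-width
on and off bins. Fixed effects use cell-means coding: each β is directly
the log rate of its bin, and "off vs on" contrasts are simple β
differences. Zero-filling matters: absent recording × bin cells are real
zeros that the zero-inflation component is there to absorb.

Estimation maximises the exact marginal likelihood, integrating u_i out by
Gauss–Hermite quadrature (default 25 nodes; the log-likelihood is stable
to < 1e−4 between 20 and 40 nodes at the σ_u values arising here),
optimised by L-BFGS-B on (β, γ₀, log σ_u) with wide bounds, standard
errors from a numerical Hessian. γ₀ and log σ_u can be pinned (π = 0 and
σ_u = 0 reduce the model exactly to a plain Poisson regression, which is
verified against the closed-form MLE and against statsmodels'
ZeroInflatedPoisson; the full mixed model is cross-checked against R's
glmmTMB in the test suite). Factor levels with zero total counts have
rates degenerating to 0 (β at the box bound); contrasts involving them are
flagged non-estimable rather than reported with meaningless SEs.

Significance of the bin factor is a full-vs-null likelihood-ratio test:
the null keeps the offset, the random intercept and the zero inflation but
drops the bin factor; χ² = 2 (ℓ_full − ℓ_null), floored at zero, with df
equal to the number of extra fixed parameters (1 for a two-bin factor, 3
for the four-bin bout-level factor). Both fits must carry the same data
fingerprint. Post hoc pairwise contrasts use the estimated fixed-effect
covariance with a Tukey-style studentized-range adjustment within the
factor family (configurable to none/Bonferroni); the normal reference is
used throughout (no Satterthwaite df).

## Tempo model

log t_k (all three levels pooled) is modelled with a linear mixed model on
the level × context cell grid with an individual random intercept, fitted
by REML via statsmodels MixedLM. The headline quantities are the six cell
means, the three within-level context contrasts (non_natural − natural;
positive = slower under non-natural contexts), and all 15 pairwise cell
contrasts. The full-vs-null LRT refits both models by maximum likelihood
using an internal closed-form profile likelihood for the random-intercept
model (Woodbury identity for the compound-symmetric covariance, GLS-
profiled fixed effects), which remains stable when the individual variance
estimate sits on the zero boundary — a configuration where generic
Hessian-based fitters can fail. When only one individual is present, or
the response is degenerate (zero residual variance, e.g. noise-free
synthetic data), the fit falls back to OLS cell means with a warning.

The between-level tempo relation is summarised as the smallest-integer
triple scaled so its first term is 2 (so means of 0.259, 1.11 and 8.74 s
read 2:9:67); scaling to a first term of 1 would hide the near-half-integer
relation of the first two levels.

## Synthetic generator

The generator inverts the segmentation rules: a nested point process with

* call onsets within a combination spaced `tempo_combination`
  (default 0.259 s),
* combination onsets within a bout spaced `tempo_bout` (default 1.11 s),
* bout onsets within a series spaced `tempo_series` (default 8.74 s),
* series separated by a silent gap of `inter_series_gap`
  (default 30 s > the 20 s threshold),

each interval multiplied by 1 + ε with ε ~ N(0, cv²) truncated at ±3 cv
(default cv = 0.05). Jitter is renewal-style — each interval drawn
independently, so timing errors accumulate along a sequence — which is the
conservative choice for isochrony detection; a metronome mode (jitter
about a fixed grid) is available. Defaults emulate the study conditions:
14 recordings from 7 individuals (round-robin), one quarter of recordings
in the natural-predator context (one natural print among four predator
models), 3 series × 3 bouts × 3 combinations × 4 calls per recording, and
a non-natural bout-tempo log effect of 0.167.

A design point worth stating: the onset spacings, which carry the tempos,
are drawn once and never rejected. The silent-gap bands are satisfied by
the *durations* — nuisance quantities drawn from 0.04–0.12 s but shortened
(down to a 0.01 s floor) or extended when a band binds, with bounded
redrawing of combination internals only. An earlier accept/reject scheme
on the spacings themselves truncated the low tail of the natural-context
combination spacing (whose nominal 0.25 s gap to the next combination sits
near the 0.2 s threshold) and biased the realised bout tempo upward by
~2%, corrupting context-contrast recovery; rejection sampling on the
quantity of interest is not harmless. A configuration whose bands cannot
be satisfied at all (e.g. `tempo_bout` shorter than a combination's span
plus the threshold) raises a generation error naming the violated band
after 100 attempts.

Context effects: non-natural recordings multiply the bout-level spacing by
exp(0.167) and may degrade combination-level isochrony via three modes —
`extra_jitter` (larger cv), `alternating` (long–short interval pairs x,
2x, concentrating r_k at 1/3 and 2/3), and `arrhythmic` (i.i.d.
exponential intervals at the same mean rate). The arrhythmic mode is the
canonical "no rhythm" reference: the adjacent-interval ratio of i.i.d.
exponential intervals is exactly Uniform(0, 1), giving equal on/off
densities, and is the mode used to demonstrate the natural/non-natural
dissociation. Symmetric extra jitter alone cannot do this — any i.i.d.
symmetric perturbation keeps the ratio density peaked at 0.5, so with
realistic sample sizes the 1:1 test stays significant.

Every dataset carries its generating tree, tempos and context effect as
ground truth; re-segmenting the emitted annotations must reproduce the
tree node-for-node, and identical (config, seed) give identical output.

## What the synthetic validation shows — and does not

Passing tests establish that segmentation, interval/ratio bookkeeping,
classification, and the estimators behave correctly under the generating
model: known tempos and effects are recovered without bias, the isochrony
test has high power under nested isochrony with 5% timing jitter at the
study's scale (14 recordings), and its false-positive rate under a
rhythm-free (uniform-ratio) null stays near the nominal 5%. They do not
establish anything about real recordings: real call sequences have
variable unit counts, annotation jitter from manual selection, possible
drift and autocorrelation in tempo, and within- vs between-recording
variance structure that the generator (within-recording jitter only, by
default) does not emulate. The generator also draws call durations for
band feasibility, not from measured duration distributions.

## Numerical conventions and edge cases

* Times are double-precision seconds, never rounded internally; CSV output
  round-trips exactly.
* A parent with m children yields m − 1 intervals and max(m − 2, 0)
  ratios; single-call recordings produce one series/bout/combination and
  no intervals.
* LRT χ² values are floored at 0; p-values use the χ² reference with the
  package's own df (extra fixed parameters). Reported df follows the
  model actually fitted.
* Tukey adjustment uses the studentized-range distribution in its
  infinite-df (normal) limit; with a two-level factor it coincides with
  the unadjusted two-sided z-test.
* The report JSON is deterministic for identical inputs and seed
  (timestamps are not embedded; provenance records input hashes, the
  thresholds, bin scheme and package version).

## Problem sizes used in validation

The acceptance-style checks run at the scale the analysis targets:
segmentation oracle equivalence on 1000 random gap sequences spanning all
bands including exact boundary values; generator round-trips over 20
seeds; detection power over 20 seeded 14-recording datasets; specificity
over 200 rhythm-free replicates at ~94 ratios per recording (the observed
combination-level density of ratios per recording); count-model recovery
over 100 replicates of 50 groups; tempo-model recovery over 20 seeds.
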