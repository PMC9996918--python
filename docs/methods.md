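# Methods

## Scope and model overview

`metabodisc` analyses a samples × metabolites table of positive peak areas
from two populations (labels `L`, resilient, and `H`, non-resilient).  Three
stages: compositional preprocessing, discriminant modelling (PLS-DA), and a
per-metabolite Bayesian contrast.  A synthetic generator supplies
ground-truth test beds.  All stages are deterministic given their seeds; the
pipeline fans a single global seed out to the stages by fixed offsets.

## Preprocessing

**Missingness filter.**  A metabolite is removed when its missing fraction
exceeds the threshold (default 0.20) in *either* population.  Rationale: a
metabolite largely unobserved in one population cannot support a two-group
contrast, and keeping it would force the imputation to fabricate most of one
group.  The filter requires both populations to be present.

**Half-minimum imputation.**  Each missing entry becomes 0.5 × the minimum
observed intensity over *all* metabolites and samples of the acquisition
method the metabolite belongs to.  The method-wide minimum is used (rather
than a per-metabolite minimum) because the smallest peak a method ever
quantified is its effective detection floor; missingness in these tables is
overwhelmingly left-censoring at that floor.

**ALR transform.**  Natural logarithms throughout; any other base would only
rescale columns and be absorbed by the autoscaling.  The reference is the
metabolite with the smallest coefficient of variation of raw post-imputation
intensities across all samples (ties break to the earlier column, for
determinism).  p metabolites yield p−1 coordinates; ALR rows are exactly
invariant to per-sample multiplicative scaling — the compositional contract
the tests assert.

**Procrustes isometry check.**  The ALR is not an isometry; how much the
chosen reference distorts the sample geometry is measured by superimposing
the principal coordinates of the ALR configuration onto those of the CLR
(centered log-ratio) configuration of the same table — the standard
isometric reference geometry — under translation, rotation and uniform
scaling.  The statistic is sqrt(1 − m²), with m² the minimised standardised
Procrustes sum of squares (computed via `scipy.spatial.procrustes`).  It is
reported, with a log warning below 0.95, never enforced: there is no
principled hard threshold, and a low value is a property of the data, not an
error.

**Autoscaling.**  Columns are centered and divided by the sample SD (n−1).
Pre-scaling means/SDs are stored so the transform round-trips exactly and
downstream contrasts are in per-metabolite SD units.

## PLS-DA

The response is a two-column one-hot class-indicator matrix, column-centered
(for two balanced classes this is rank one; NIPALS handles the residual
response after each deflation).  Components are extracted by NIPALS PLS2
with X- and Y-deflation, unit-norm weight vectors, convergence tolerance
1e−10 on the score vector, and a 500-iteration cap per component.  If the
response is exhausted early (perfect fit) the model simply carries fewer
components.  New data are projected with the rotation W(PᵀW)⁻¹; because
PᵀW is upper triangular, truncating the rotation to the leading a columns
is equivalent to refitting with a components, which the cross-validation
exploits (one fit per fold serves every candidate component count).

**Classification.**  Mahalanobis distance to the class centroids of training
scores, with the pooled within-class score covariance (divisor n − 2)
ridge-regularised by 1e−8·I for invertibility.

**VIP.**  VIP_j = sqrt(p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a) with
SS_a = ‖q_a‖²‖t_a‖², the response variance captured by component a.  Mean
squared VIP is 1 by construction; the suite cross-checks the values against
scikit-learn's NIPALS and against frozen output of Bioconductor mixOmics on
a fixed fixture.

**Cross-validated tuning.**  Stratified fourfold assignment (class
proportions preserved per fold) redrawn each repeat; with 13 samples per
class, unstratified folds can produce single-class training splits, which
are guarded against by redrawing.  Per repeat, class-wise error counts are
pooled over the four folds; BER is the unweighted mean of the two class
rates; the chosen component count minimises the mean BER over repeats with
ties resolved toward fewer components.  The candidate grid is
1..min(10, n−2, p).  Defaults: 100 tuning repeats, 10,000 validation
repeats, scaled down in tests and examples via arguments, never silently.

**Iterative selection.**  Each iteration: tune the component count, fit on
all current variables, compute VIP from that full-data fit, drop variables
with VIP < 1.  Stop when nothing is dropped, when fewer than two variables
would remain, or when the tuned BER worsens relative to the best iteration
so far; return the iteration with the minimal BER (ties toward fewer
variables) together with the full trace.  VIP from the full-data fit (not
CV-averaged VIP) keeps the loop deterministic and cheap.

**Validation.**  Out-of-fold predictions aggregated over repeats into a 2×2
table of class-wise percentages (rows sum to 100); accuracy and precision
treat the resilient class `L` as positive.  The permutation analogue draws a
*fresh* uniform label permutation per repeat before one round of fourfold
CV.  This matters: the conditional CV error of a single fixed random
labeling wanders around chance by ±0.1 on a 26-sample set, because held-out
points anti-correlate with their own-class training centroid on a fixed
finite sample; only the fresh-permutation design has expectation 50%.

## Bayesian two-group contrast

Model, per metabolite: y_ij = µ_i + e_ij, e ~ N(0, σ²), flat improper
priors on µ_H, µ_L and on σ² over (0, ∞).  Full conditionals:
µ_i | σ² ~ N(ȳ_i, σ²/n_i) and σ² | µ ~ Inv-Gamma(n/2 − 1, SSE(µ)/2).
Under these priors the marginal posterior of D = µ_H − µ_L is available in
closed form — a location-scale t with **n₁+n₂−4** degrees of freedom,
location ȳ_H − ȳ_L, scale sqrt(SSE/(n−4)·(1/n₁+1/n₂)).  (A uniform prior
on σ² costs two degrees of freedom relative to the Jeffreys 1/σ² posterior,
whose t has n−2 df; at n = 26 the interval widths differ by ~2%.)  The
tests use this closed form as the sampler's independent oracle.

The conditionals depend on the data only through per-group means and the
within-group sum of squares, so the sampler is vectorised over all
metabolites and chains simultaneously from one seeded generator — a whole
300-metabolite table at reduced length runs in well under a second, and
determinism given the seed is preserved.  Defaults follow the study-scale
settings: 4 chains × 50,000 iterations, lag 10, burn-in 1,000 → 4,900 kept
draws per chain, 19,600 pooled.  Chains start at the pooled within-group
variance; no convergence diagnostics beyond the closed-form agreement
checks, which bound the total error directly.

**Summaries.**  Posterior mean; P0 = max(frac(D>0), frac(D<0)) ∈ [0.5, 1];
PEP = (1 − P0)/0.5; HPD95 as the narrowest window containing ⌈0.95·N⌉ of
the sorted pooled draws (deterministic scan).

**Cumulative-PEP selection.**  PEPs sorted ascending; the cumulative PEP at
rank i is the mean of the i smallest PEPs, i.e. the estimated FDR were the
list cut at rank i; metabolites with cumulative PEP ≤ α (default 0.05) are
flagged.  Tied PEPs share the cumulative PEP of the largest tied rank;
input order is restored on return.

**Known limitation — calibration against exact nulls.**  PEP here is a
*sign-error* probability under a continuous flat prior, not a local
false-discovery rate from a null/signal mixture.  For a metabolite whose
true difference is exactly zero, P0 is uniform on (0.5, 1), so its PEP is
uniform on (0, 1); order statistics then let roughly 2α·m null metabolites
through the prefix-mean rule on an m-metabolite null set.  Consequently the
rule's nominal 5% is honest *within the model's own prior* (expected
sign-error rate among flagged contrasts) but does **not** control the
frequentist false-discovery proportion when many metabolites are truly
null — `scripts/acceptance.py` quantifies exactly this on mixed null/signal
simulations, and the pure-null behaviour is asserted (at its computed
value, not at zero) in the test suite.  Users who need point-null FDR
control should treat the flagged list as a ranking and apply a mixture-based
or Benjamini–Hochberg procedure to it.

## Synthetic data generator

Emulates the study conditions: two balanced groups of 13, 200 metabolites
(four acquisition methods, round-robin assignment), log-normal intensities
with per-metabolite log-means ~ N(15, 1) and log-SDs Uniform(0.5, 1.5) ×
0.6 — giving the heterogeneous dispersions typical of untargeted peak
areas — 10 informative metabolites with a 2-SD group separation additive on
the log scale (random sign, split symmetrically around the metabolite
mean), and 10% left-censoring applied per method at the intensity quantile,
deterministically, so the censoring oracle is exact.  Pre-censoring values
ride along for oracle tests.  Effects additive on the log scale match the
downstream log-ratio analysis; the FDR and coverage studies use 26 × 300
tables with 60 signals at 1.5 SD and 200 single-column replicates at 1 SD
respectively, sized so Monte-Carlo error stays well inside the asserted
tolerances while the whole suite runs in about half a minute.

What the generator does *not* emulate: correlated metabolite blocks
(pathway structure), batch/injection-order drift, heavy-tailed or
multiplicative noise, compositional closure beyond positivity, and
missingness mechanisms other than left-censoring.  Passing tests therefore
demonstrate algorithmic correctness and calibration under an idealised
independent log-normal world, not robustness to real-data pathologies.

Note on the calibration studies: the FDR simulation feeds autoscaled log
intensities directly to the Bayesian stage, without the ALR step.  An ALR
against a data-chosen reference would mix the reference metabolite's noise
(or signal) into every column and thereby redefine which metabolites are
truly null; skipping it keeps the ground truth exact.  The full-pipeline
path (with ALR) is exercised by the PLS-DA and end-to-end tests.

## Numerical and design choices

- Contrast direction is H − L (non-resilient minus resilient) everywhere.
- NIPALS: tol 1e−10, max 500 iterations per component, degenerate-response
  guard at ‖Y‖ < 1e−12.
- Mahalanobis ridge 1e−8; pooled covariance divisor n − 2.
- CV reference selection on raw post-imputation intensities across all
  samples, not per population; CV ties → first column.
- Procrustes partner is the CLR configuration; both configurations are
  truncated to their common principal-coordinate rank.
- Gibbs thinning keeps iterations (burn_in, n_iter] with
  (it − burn_in) mod thin = 0, so kept-per-chain = (n_iter − burn_in)/thin
  exactly at the defaults.
- Half-minimum imputation errors out (naming the method) if a method has no
  observed value; autoscaling errors out (naming the column) on constant
  columns; ALR errors out with sample/metabolite coordinates on nonpositive
  values.
- No sample-exclusion rule is implemented: the pipeline analyses whatever
  samples it is given.
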