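# Methods

## Benchmark model

The package assumes a two-sample spike-in design: digests of 2–4
species mixed volumetrically at a common stock concentration, so the
expected log2 fold change (A/B) of every protein of species *s* is
log2(f_A,s / f_B,s) with f the volumetric fractions. Fractions may be
entered as ratios (65:30:5) and are normalized internally. Designs
with unequal stock concentrations are supported through an explicit
per-species concentration override (mass fractions are re-derived from
volume × concentration); this is an extension beyond the
equal-concentration design and is the user's responsibility to get
right. On-column amounts are concentration × injection volume split by
mass fraction. A species present in A but absent from B has an
infinite expected fold change and is rejected.

## Filters

An entry is *identified* when its data completeness strictly exceeds
50% in both conditions — with triplicates, a value in ≥ 2 of 3
replicates in both samples. An identified entry is *quantified* when
its CV is strictly below 20% in both conditions. CVs use raw
(non-log) intensities and the n−1 standard deviation; both are
conventional choices. Zero intensities are parsed as missing by
default because a zero is not a valid measurement and would distort
CVs; this is configurable at read time. Summary CVs (mean, median)
pool the per-entry CVs of both conditions; because the pooling
convention is a genuine choice, per-condition means and medians are
emitted alongside.

## Differential test

Quantified entries are compared with a moderated two-group t-test on
log2 intensities. Per entry, the pooled within-group variance s² with
df = n_A + n_B − 2 degrees of freedom (reduced by missingness) is
shrunk toward a prior variance s0² with d0 prior degrees of freedom:

    s²_post = (d0·s0² + df·s²)/(d0 + df),   df_total = df + d0.

(d0, s0²) are estimated by moment-matching of log s² against the
scaled-F marginal using the digamma/trigamma identities, with a
Newton-iteration trigamma inverse. When the empirical variance of the
log-variances does not exceed the sampling component, d0 is infinite
and s0² is the arithmetic mean of the observed variances (matching
limma's `fitFDist` in the same branch; the moderated p-values then use
a standard normal reference). The *robust* variant that down-weights
variance outliers during hyperparameter estimation is deliberately not
implemented: for 3-vs-3 designs without variance outliers the two
agree closely, and the test suite cross-checks hyperparameters, t and
p against Bioconductor limma to ~1e-9 on a fixture. Entries with fewer
than 10 positive residual variances fall back to the ordinary pooled
t-test with a warning.

P-values are two-sided; BH adjustment runs across all tested entries
jointly (not per species). Calls use p_adj < 0.01 and |log2FC| > 0.5
with no upper magnitude limit. Identified-but-not-quantified entries
receive no test result.

## Ground-truth scoring

Expected classes follow the sign of the expected log2FC. The confusion
matrix uses the convention that a wrong-direction call on a changed
species counts as FP (not FN), which keeps TP+FP+TN+FN an exact
partition of the tested, ground-truthed entries; magnitude overshoots
in the correct direction remain TP. deFDR = FP/(FP+TP). Sensitivity is
reported both as TP/(TP+FN) (the standard true-positive rate) and as
TP/(FP+TP) (`sensitivity_paper_literal`), because the latter formula
circulates in print; the two are kept side by side for comparability.
Entries with ambiguous species (mixed protein groups) or no species
match stay in identification counts but are excluded from every
ground-truth statistic, with their count reported — how shared-peptide
groups should be scored is genuinely open, and exclusion is the
conservative choice.

The asymmetry factor uses a Gaussian KDE with Silverman bandwidth on a
512-point grid spanning the data range ± 3 bandwidths; the center line
is the density mode, the left/right positions are the outermost
crossings of 10% of the peak height (linear interpolation between grid
points), and AF = right/left half-width. Species expected to go down
are mirrored first (configurable), so AF < 1 uniformly reads as
compression. Fewer than 30 values or a zero-width sample yield an
undefined AF with a warning. Bandwidth rule, grid size, center-line
definition and interpolation are all unspecified in the field's usage
of this statistic; the defaults here are fixed and configurable, and a
histogram-based direct measurement serves as the independent oracle in
the tests (they agree within a few percent at large n; at n ≈ 300 the
KDE estimate carries ±0.1–0.2 of sampling noise, which matters when an
AF sits near the 0.5 threshold).

Accuracy and Dispersion are pooled over entries, with per-species
contributions reported (whether the original convention pooled or
averaged per species is not determinable; pooled is the default here).
Trueness sums |median − expected| over design species and becomes "not
evaluable" if a design species has no quantified entry.

## Verdict

Default criteria: deFDR ≤ 1% and every defined per-species AF within
[0.5, 2]. A configurable precision criterion on the mean CV of
quantified entries (`mean_cv_max`, conventionally 5%) can be enabled;
it is off by default because it measures instrument precision rather
than the correctness of the differential analysis, and a benchmark
with a 10% replicate CV can still be quantitatively faithful — the
mean CV is always computed and reported either way. Any criterion
whose statistic is undefined makes the verdict "inaccurate (not
evaluable)" with the criterion listed. Report ranking uses TP counts
but excludes inaccurate workflows from the ranking proper.

## Synthetic generator

The generator emulates a DIA-NN-style protein-group matrix for the
three-species design. Defaults: 1000 human / 500 yeast / 300 E. coli
entries (mirroring the dominance of the human background in the
65:65 design), true log2FCs 0/+1/−2, 3 replicates per condition, 10%
target CV, 5% missingness, 20 contaminant rows, base intensities
log10-uniform over 1e4–1e8. Replicate values are mean-preserving
log-normal draws with σ = √ln(1 + (CV/100)²), so the expected CV
equals the target analytically. Missingness is independent by default;
an intensity-dependent (logistic in log-intensity) mechanism is
available but off, since the completeness filter is agnostic to the
mechanism.

Error injections:

* **Ratio distortion** (`compression_factor` c): real compression is
  heterogeneous — interference affects entries unevenly — and a
  uniform rescaling of all fold changes would shift medians while
  leaving the density symmetric, which no density-shape statistic
  could see. The generator therefore draws a per-entry multiplier from
  a rising-quadratic density on [4c−3, 1] (mean exactly c, mode at 1):
  most entries are mildly affected with a skewed tail toward strong
  attenuation. Below c = 0.75 the tail crosses zero, i.e. a small
  fraction of entries shows inverted ratios, as severe interference
  produces in practice — this is also what couples strong compression
  to elevated deFDR. Expansion (c > 1) mirrors the construction.
* **Normalization shift** (`shift_b`): every A/B log2 ratio is offset
  by +shift_b (condition B scaled down), applied after everything
  else. Per-entry CVs are provably unchanged.
* **Outlier subpopulation** (`outlier_fraction`, `outlier_shift`): a
  random fraction of entries gets a constant log2 offset, the
  matrix-level signature of a fragment-level system error.

What the generator does **not** emulate: correlated noise across
entries, intensity-dependent CVs, chromatographic or spectral
artifacts, shared-peptide protein-group ambiguity, and realistic
contaminant behavior (contaminant rows are just background-like rows
with a `CON__` prefix). Passing the recovery tests therefore shows the
*analysis chain* is correct, not that any real workflow is accurate.

## Normalization check

The dilution check loads the two samples at different on-column
amounts (canonically 1 µg vs 0.7 µg) and measures the median log2
ratio of a background (unchanged) species between the load groups.
Correct normalization gives ≈ 0; unnormalized data gives
≈ log2(load ratio) ≈ 0.515. How this validation should be quantified
is not standardized; the median-shift statistic with a default
tolerance of 0.2 log2 units is this package's operationalization, and
both the observed and the expected-if-unnormalized shifts are
reported. Fewer than 50 usable entries marks the result
low-confidence. The check only detects failure; `median_center` is
provided as the minimal correction for a global shift, not as a
normalization method.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on synthetic
data at the default generator sizes (≈ 1800 entries, 6 runs), with
5000-entry draws for variance-prior recovery, 2000 entries for the
null calibration of the moderated test, and 4×10⁵ draws for the
asymmetry-factor oracle comparison. Every random draw is seeded; CLI
reruns on the same inputs are bit-reproducible (plots excluded).

## Known limitations

* Only two-condition designs; no covariates, no precursor→protein
  roll-up (matrices arrive summarized).
* The AF of a multimodal fold-change density uses the global mode and
  outermost 10% crossings; strongly bimodal distributions can produce
  AFs that are hard to interpret.
* deFDR is undefined (reported as such) when no entry is called
  Up/Down.
* The eBayes prior estimation drops zero residual variances instead of
  offsetting them (limma offsets); with many exact-tie intensities
  this could bias d0 upward, which does not occur with continuous
  intensity data.
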