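# Methods

`ppbscreen` implements the quantitative analysis of a multiplexed
affinity-pulldown screen for protoporphyrin-IX-probe (PPB) interacting
proteins: an 11-plex isobaric-tag (TMT) experiment in which four cell lines —
two human (HepG2, U251) and two mouse (NIH3T3, MEL) — are measured in
duplicate alongside three blank bead-only negative controls, all in one MS
run. This note records the model, the defaults, the numerical choices, and
what the synthetic benchmark does and does not demonstrate.

## Quantification model

The pipeline starts from peptide-spectrum matches (PSMs), each carrying one
reporter-ion intensity per channel; identification, search-engine FDR and
parsimony grouping happen upstream and arrive as table columns.

1. **Impurity correction.** Each isobaric reagent's reporter ions are spread
   over neighbouring channels by isotopic impurities (e.g. a reagent emitting
   91.8% / 7.9% / 0.3% of its signal into its own, +1 and +2 channels). With
   `M[i][j]` the fraction of label *j* observed in channel *i*, the observed
   PSM vector is `M @ true`; we solve the linear system (`invert` mode,
   negatives clamped to zero and flagged) or solve under non-negativity
   (`nnls`). Matrices passing validation (diagonal > 0.5, column sums ≤ 1)
   are strictly column-diagonally dominant and therefore always invertible.
2. **Low-intensity exclusion.** PSMs with across-channel minimum below 1000
   or median below 5000 (inclusive thresholds) are removed; these values are
   the screen's operating defaults and are configurable.
3. **Loading normalization** (below), applied to post-filter raw intensities.
4. **Mean-centering.** Each PSM is divided by its across-channel mean,
   giving a relative profile averaging exactly 1.
5. **Protein summarization.** Protein relative intensity per channel is the
   unweighted mean of its PSMs' relative profiles. Only peptides shared
   between the human and mouse proteomes are used, so that species-specific
   peptides — absent from the wrong-species channels by construction — cannot
   bias cross-species protein ratios. Proteins without any shared-peptide
   PSM are omitted.
6. **Absolute scaling.** Relative profiles are multiplied by the grand mean
   of the protein's three most abundant PSMs (top-min(3, n)); a PSM's
   abundance is its across-channel mean raw intensity by default
   (configurable: mean | sum | max, per-protein or global scope). The
   per-protein reading was chosen because a global scale would make absolute
   values of low-abundance proteins depend on unrelated proteins.

## Species-specific-peptide loading normalization

Pulldowns violate the equal-loading assumption of ordinary normalization:
channels legitimately capture different amounts of material. Pooling two
species into one plex provides internal standards: a mouse-specific peptide
in a human cell line carries only bead-background signal, just as it does in
a blank. For a human-line channel *c*, the loading factor is

    f_c = median_i x_i[c] / median_i x_i[ref]

over mouse-specific PSMs *i*, where `ref` is the first blank channel; the
symmetric factor (human-specific peptides) serves mouse-line channels. All
intensities in channel *c* are divided by `f_c`.

Design choices: the original definition covers only sample channels, but the
downstream t-test needs blanks on the same scale, so non-reference blank
channels are normalized with the pooled union of both species-specific PSM
sets (background in every blank); the reference blank is fixed at 1. The
even-set median is the midpoint of the central pair. Channels supported by
fewer than 10 PSMs (configurable) are flagged rather than rejected.

Because numerator and denominator use the same PSM set, noise-free recovery
is exact, and the correction is a fixed point: recomputing factors on
corrected data returns 1. The factor's precision scales as the median's
standard error (≈ 1.25 σ/√n per channel); with the default simulation's
several thousand cross-species PSMs the error is well under 1%.

## Candidate calling

On log2 relative intensities after normalization, each cell line's two
replicates are compared to the three blanks by a one-tailed pooled-variance
Student t-test (alternative: line > blanks; df = n1+n2−2 = 3). Pooled
variance was preferred to Welch because per-group variance estimates from
two replicates make Welch's df estimate unstable. The four per-line
p-values are combined by Fisher's method, `X² = −2 Σ ln p` against
chi-square with 2L df (p floored at 1e-300 to keep the log finite), and
combined p-values are converted to q-values by Benjamini–Hochberg step-up.

The orthogonal effect-size gate measures fold change in units of
measurement noise. The log2 ratio between replicate channels is computed
for every protein and line, pooled, and fitted with a Gaussian: `mle` uses
the sample mean and the maximum-likelihood SD; `mad` (robust to the true
binders sitting in the pool) uses the median and 1.4826·MAD. The z-score is
`(max_l log2FC_l − μ0)/σ0`; the maximum-over-lines rule lets a protein
binding strongly in a single line pass (line-specific binders are real in
this design), with `mean` and `all` exposed as alternatives. μ0 is
estimated rather than assumed zero. A protein is a candidate iff
q < 0.01 **and** z > 3 (both configurable).

### Calibration caveat: shared blanks

The four per-line tests reuse the same three blank channels, so their
p-values are positively correlated (r ≈ 0.37 in simulation). Fisher's
method assumes independence; the combined p is therefore anticonservative
in the tail (under a pure null, ≈ 4% of combined p fall below 0.01 instead
of 1%). This is a property of the experimental design, not of the
implementation. The empirical false-discovery proportion of the *joint*
rule nonetheless stays well below the nominal 1%, because the z-gate at
3σ0 sits ≈ 4 null SDs above the spread of a null protein's maximal fold
change and removes essentially every null protein that slips through the
FDR gate. Per-line p-values themselves are uniform under the null, and
Fisher combination of genuinely independent uniforms is exactly calibrated
(both are property-tested).

## Synthetic experiments

The generator emulates the screen's statistical structure with known ground
truth. Per PSM and channel, log2 intensity is

    base + effect(protein, line) + log2(bias_channel) + N(0, noise_sd)

for observable signal, where species-specific peptides are observable only
in same-species sample channels and otherwise carry an independent
`background` level; blanks never receive binder effects. Intensities are
exponentiated, optionally mixed through an impurity matrix, and censored to
zero below a threshold (censoring keeps the row so the exclusion filter is
exercised end to end).

Defaults are the reference study conditions: 1000 proteins, an even
human/mouse split, 5% binders per cell line drawn independently per line,
log2 effect 3, noise SD 0.15 on log2 intensities, per-channel loading
biases uniform in [0.5, 2], seed 17. Structure defaults are the package's
own choices of a realistic mid-depth experiment: 3–6 peptides per protein,
1–3 PSMs per peptide, and (within proteins that have shared peptides —
all of them by default) each peptide shared with probability 0.5, the first
forced shared so every protein is quantifiable. `base_intensity` (16, 1)
and `blank_background` (13.5, 0.75) on the log2 scale put full signal near
2^16 and bead background near 2^13.5, so typical PSMs clear the 1000/5000
intensity filter across the bias range while background stays ~6-fold below
signal. Gaussian-on-log2 noise makes the t-test's normality assumption
exactly satisfiable, which is deliberate: benchmark failures then indicate
pipeline defects, not model mismatch.

What the generator does *not* emulate: peptide-level identification error,
interference/ratio compression from co-isolated precursors, missing
channels, heteroscedastic intensity-dependent noise, or correlated binding
across cell lines. Passing benchmarks therefore demonstrate correctness of
the computation under the stated model, not performance on real spectra.

## Benchmark results and problem sizes

The calibration study (`scripts/acceptance.py`, also run by the acceptance
tests) simulates 200 independent screens at the defaults and measures the
false-discovery proportion among called candidates: mean FDP + 2 Monte-Carlo
SE ≈ 0.002–0.003, comfortably below the nominal 1%. Each screen is ~9000
PSMs × 11 channels; the 200-run study completes in well under a minute on
one CPU.

Measured sensitivity for binders under the same conditions averages ≈ 0.85.
The misses are almost exclusively single-line binders: with independent 5%
binder draws per line, ~85% of binder proteins bind in exactly one line,
whose df = 3 t-test bounds the evidence one line can contribute to the
Fisher statistic, leaving such proteins near the BH decision boundary at
q = 0.01. Sensitivity rises with deeper PSM coverage (smaller per-protein
noise) and with cross-line binder correlation; both are configurable in
`SimConfig`, but the reported number is at the defaults above.

## Numerical conventions

- Median of an even set: midpoint of the central pair.
- Ties in BH: stable sort on input order (determinism).
- Degenerate t-tests: zero pooled variance gives p = 0.5 at equal means,
  p = 1e-300 (flagged) otherwise.
- PCA (QC): SVD of channel-centered log2 relative profiles; each
  component's sign is fixed so its largest-magnitude loading is positive.
- Hierarchical clustering (QC): average linkage on Euclidean distances of
  log2 profiles; both are conventional choices, exposed as parameters, and
  the QC outputs are sanity views, not reproductions of any published
  figure.
- All randomness flows from one `numpy` generator per simulation, seeded
  from `SimConfig.seed`; identical configs give byte-identical outputs.

## Limitations

- Fisher combination over tests sharing blank channels is anticonservative
  (see above); the joint rule compensates, but the combined p should not be
  interpreted as a calibrated single-test p-value.
- The null SD pools proteins with heterogeneous PSM counts, so σ0 is an
  average noise scale; per-protein variance moderation is out of scope.
- Parsimony protein grouping is accepted as input (a greedy helper is
  provided); no protein database ships with the package.
- Blank-channel normalization via the pooled cross-species set is an
  interpretation where the original procedure is silent.
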