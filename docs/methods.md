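# Methods

This note documents the statistical model behind `hvtime`, the defaults and
why they are what they are, what the synthetic-data generator does and does
not emulate, and the design choices made where several defensible options
existed.

## Background-mode normalization

**Model.** On a single-channel bead array, most probes measure only
background; their intensities form a Gaussian centred near zero, while the
minority of expressed genes populate a long right tail. Each array is
therefore normalized against its own background Gaussian: mean `μ_bg` and
SD `σ_bg` are estimated from the low-intensity mode, and every value is
re-expressed as `z = (x − μ_bg)/σ_bg`. A gene is "expressed" in an array
when `z ≥ z_threshold` (default **3.0**, i.e. three background SDs; on the
log₁₀ scale, 0.477). Expression values are log₁₀-transformed after flooring
at `floor_z = 1` (log 0): the floor only touches values already below the
expression threshold, so no downstream statistic on expressed genes is
affected. The expressed mask is recorded from pre-floor z-scores, before
alignment, and never changes afterwards.

**Mode estimation.** The mode is located on a Freedman–Diaconis histogram
smoothed with a 3-bin moving average (ties resolved toward the smaller
value), then refined by a mean-shift iteration: the mean of values within
±2 robust SDs of the current centre, iterated to a fixed point. The
refinement matters quantitatively — the histogram mode alone scatters by a
few bin widths on the flat top of a Gaussian, while the windowed mean is
tight and, because expressed genes sit beyond three background SDs, remains
blind to the right tail. The ±2-SD window width balances boundary-noise
amplification of the fixed point (which grows as the window shrinks)
against contamination risk from weakly expressed genes (which grows as it
widens). The SD is then the root-mean-square deviation of the left flank
mirrored about the mode — the left half of the background is uncontaminated
by expression, and mirroring doubles it into a symmetric sample.

**Cross-array alignment.** Arrays are adjusted to each other on the log₁₀
scale by regressing each array onto a gene-wise median pseudo-array
(computed over genes expressed in *all* arrays, at least 30 of them) with
iteratively reweighted least squares under a Huber ρ (tuning constant
**1.345**, the standard 95%-efficiency choice; convergence 1e−8 on
coefficients, ≤100 iterations). The adjusted value is
`(value − intercept)/slope`. A pseudo-array reference avoids privileging
any one sample; because Huber regression is affine-equivariant, a robust
refit of an adjusted array on the reference returns slope 1 and intercept 0
exactly, which is the package's internal consistency check (an ordinary
least-squares refit returns the identity only on outlier-free data).
Adjusted values are re-floored at log 0 so unexpressed placeholders cannot
drift below the floor.

## Hypervariable-gene detection

**Reference group.** The technical variance of the platform is estimated
from expressed genes whose replicate scatter is indistinguishable from
noise. Starting from all expressed genes, the per-gene residual variance
under the replicate-group-mean model (`df = n_arrays − n_groups`) is pooled
df-weighted; genes with upper-tail F-test `p < alpha_ref` (default
**0.05**) against the pool are removed, and the pool is re-estimated to a
fixed point. Trimming the upper tail of a variance distribution biases the
trimmed pool low (≈ −14% at df 5), which would inflate every downstream F
statistic and visibly distort null p-values; the pool is therefore
corrected analytically for the truncation: each member's df is weighted by
`κ = P(χ²_{df+2} < c)/P(χ²_{df} < c)`, the expected retained fraction of a
χ² mean below the trim threshold `c`. With the correction the pool is
unbiased to a few per mil and null p-values are uniform
(`bias_correction=False` disables it).

**Test statistic.** A gene's time-course variability is contrasted with
technical noise by the one-way ANOVA ratio

    F = MS_between / s²_ref,  df = (G − 1, Σ member dfs)

where `MS_between` is the between-replicate-group mean square over the
gene's (treatment, time) groups. This is the canonical statistic for "does
this gene's level move across time points by more than replicate noise
explains"; the total-variance variant (`statistic="total"`, df = n − 1) is
available for designs without meaningful replicate structure, at a
measurable cost in power (on the default synthetic conditions, sensitivity
0.80 vs 0.885 at matched calibration).

**Threshold.** Genes are flagged when `p < 1/N`, a Bonferroni-style rule
with N the number of genes expressed above background. The inequality is
strict; N counts expressed genes before any HV filtering. A gene counts as
expressed when its pre-floor z reaches the threshold in at least
`expressed_min_arrays` arrays — default **2**, i.e. expression must
replicate. With a single-array rule, roughly 1.3% of pure-background probes
fluctuate past three SDs somewhere in a ten-array design and enter N as
floored spike patterns whose log-scale "variance" dwarfs the technical
noise of genuinely expressed genes; requiring two arrays suppresses this
probe class (expected rate ~10⁻⁴) without touching real expressed genes.

**Leave-one-out replicate-error filter.** Flagged genes are screened for
single-replicate artifacts: the residual variance is recomputed excluding
the sample with the largest positive residual and, separately, the one with
the largest negative residual; a significant collapse on either exclusion
drops the gene (`alpha_loo`, default **0.05**) and reports the excluded
sample as suspect. Because the excluded sample is *selected* as the most
extreme, the variance ratio is not F-distributed under the null — using the
naive F reference would drop clean genes at several times the nominal rate.
The filter instead calibrates `max(F₋max, F₋min)` against its Monte-Carlo
null distribution under the identical replicate design (20,000
standard-normal draws, a fixed internal seed — the table is part of the
method, cached per design). The familywise level is then exactly
`alpha_loo`: measured clean-gene drop rate ≈ 0.052, artifact flag rate
≈ 0.93 at a 10-noise-SD spike. Within a replicate pair the two members
produce identical collapses, so the suspect is identified up to the pair.

## Clustering

HV genes are mean-centered by row and agglomerated bottom-up under
`d = 1 − s` with the uncentered correlation
`s = Σxᵢyᵢ/√(Σxᵢ²·Σyᵢ²)` (centering is applied even though the metric is
uncentered — both steps are part of the procedure). Linkage is **average**
(complete and single available); merge heights are then monotone and lie in
[0, 2]. The agglomerator is implemented in-package with a deterministic
tie-break (smallest node-index pair in lexicographic order) so merge
sequences are reproducible; the test suite verifies its merge sequence
against scipy's independent implementation. Newick export splits each merge
distance equally between the two children, giving an ultrametric tree with
every leaf at depth half the root height. Heat-map row order places the
larger subtree first at each merge, ties by smallest leaf identifier.

## Comparison and enrichment

Two arms' HV sets partition by exact set algebra into common / a-specific /
b-specific; `|common| + |only_x| = |X|` is asserted on every pipeline run.
Over-representation of an annotation term is the exact hypergeometric upper
tail `P(X ≥ k)` for an overlap of k between an n-gene list and a K-member
term in an N-gene background (terms are intersected with the background
first; the list must be a subset of it). No multiple-testing correction is
applied by default; Benjamini–Hochberg is available as a flag. The
enrichment score of a user-supplied term group is the arithmetic mean of
−log₁₀ p (zero p-values are floored at 1e−300 with a warning); automatic
fuzzy term grouping is deliberately out of scope.

## Assays

Viability fold change is `mean(A₂₄)/mean(A₀)` per dilution; relative
viability normalizes to the untreated control. The IC50 is interpolated
linearly in log₁₀ concentration (= −log₁₀ dilution factor) at the 0.5
crossing — a deliberate choice of the simplest determinate rule over a
4-parameter logistic fit, which would demand more dose points than a
screening plate provides; with several crossings the lowest concentration
is returned with a warning. ΔΔCt quantification assumes 100% amplification
efficiency: `fold = 2^(−ΔΔCt)`.

## Synthetic data: what it emulates, and what it does not

`generate_timecourse` produces raw matrices by *inverting* the
normalization model, so the analysis chain can be checked against known
parameters. Defaults mirror a two-arm treatment study sharing an untreated
0 h baseline: 24,526 probes, treatments sampled at 0.5, 1, 2, 3 h, 2
replicate arrays per group.

| parameter | default | meaning |
|---|---|---|
| `background_fraction` | 0.6 | probes that are pure background |
| `background_sd` | 50 | background Gaussian SD, fluorescence units |
| `baseline_log_mean/sd/min` | 1.2 / 0.35 / 0.6 | expressed baselines, log₁₀(z), truncated |
| `hv_fraction` | 0.05 | trend genes among expressed |
| `hv_effect_size` | 5 | trend amplitude, units of `noise_sd` |
| `noise_sd` | 0.05 | replicate noise SD, log₁₀ scale |
| `artifact_fraction` | 0.01 | stable genes with one spiked replicate |
| `artifact_spike` | 10 | spike height, units of `noise_sd` |
| `slope_range`, `offset_range` | 0.92–1.08, ±0.08 | per-array affine distortion, log₁₀ scale |

Trend shapes are a 50/50 mix of linear ramps and saturating exponentials,
both rising monotonically from baseline; in two-arm designs each trend gene
responds to arm a, arm b, or both. One global seed splits into independent
streams for gene roles, array distortions and noise, so enlarging the panel
does not perturb the distortions. Identical configs give bitwise-identical
output.

The generator does **not** emulate: a continuum of weakly expressed genes
straddling the 3-SD threshold (baselines are truncated at z = 4, so the
expressed/background classes are separable); intensity-dependent
(heteroskedastic) noise; probe-level bead replicates, scanner artifacts or
dye chemistry; correlated gene modules beyond the shared trend shapes.
Passing tests therefore demonstrate correctness of the inference machinery
under the model's own assumptions, not robustness to everything real arrays
do.

## Problem sizes used in tests and the acceptance script

Null calibration uses 200 datasets of 2,000 expressed genes (the
theoretical expectation under P < 1/N is ≈ 1 flagged gene per dataset);
p-value uniformity is tested by KS on 10 p-values subsampled per dataset,
because p-values within one dataset share the pooled reference denominator
and a whole-dataset KS has no iid null. HV recovery pools five datasets of
2,000 genes (2 replicates × 5 groups, effect size 5). Background and
alignment recovery run at the full 24,526-probe panel, where the mode
estimator's sampling error is well inside the 5% band (a 2,000-probe panel
leaves only ~1,200 background draws, and no mode-type estimator reaches 5%
precision there). Oracle checks enumerate every hypergeometric
configuration with N ≤ 12 and compare 50 random 6×4 clustering instances.

## Known limitations

- The background fit assumes a unimodal, locally symmetric background; it
  will mis-estimate arrays whose background is skewed or bimodal.
- The reference-group bias correction treats the trim threshold as fixed at
  its fixed-point value; the residual bias (≲0.5%) is negligible for
  detection but visible in very large meta-analyses.
- The leave-one-out null table assumes exchangeable Gaussian replicates
  within groups; heavy-tailed replicate noise would make it conservative
  for artifacts and liberal for clean genes.
- P < 1/N controls the expected number of null false positives at ~1 by
  construction; it is not an FDR procedure, and no alternative error-rate
  control is provided by design.
- IC50 interpolation is bounded by the tested dilution range and reports
  no confidence interval.
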