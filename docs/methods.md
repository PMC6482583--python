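# Methods

## Classification model

Samples carry two biomarkers: circulating formate F_i (mM) and a glucose
signal G_i (integrated MS peak area, arbitrary units).  Reference labels
are the five study subtypes (H, BC, LC, OD−, OD+), merged for
classification into healthy `h`, cancer `c` = {BC, LC} and obesity
`o` = {OD−, OD+}.

Two classifiers are implemented.  The **F-classifier** imputes `c` when
F_i < F_T and `h` otherwise.  The **(G,F)-classifier** is a decision tree
with fixed topology — obesity first, then cancer:

* `o` if G_i > G_T;
* `c` if G_i < G_T and F_i < F_T;
* `h` otherwise.

All branch conditions are strict, with `h` as the catch-all.  A sample
sitting exactly on a threshold is therefore never assigned to a positive
branch; in particular G_i = G_T yields `h` even when F_i < F_T.  This
equality convention matters because candidate thresholds are the observed
values themselves, so exact equality is common.  The alternative reading
(equality counts as positive) is not distinguishable from the case
definitions the method is stated with; we adopt the strict reading and
flag it here.

## Threshold selection

Thresholds are selected on a training set by exhaustive search.  The
candidate grid for each biomarker is the sorted set of distinct observed
values, plus one sentinel below the minimum and one above the maximum so
the all-positive and all-negative assignments are reachable (sentinels:
half the minimum and twice the maximum for positive data).  Midpoints are
not used: between two observed values no classification changes.

The objective is the **relative mutual information** between the imputed
classification S\* and the reference S over the evaluated samples U:

    I(S*, S | U) = Σ_ab p_ab ln( p_ab / (q_a r_b) )      [nats]
    i(S*, S | U) = I(S*, S | U) / ( −Σ_a q_a ln q_a )

with p_ab the joint class fractions and q, r the marginals; 0·ln 0 := 0
for empty cells, and marginals are computed from integer counts so that
degenerate tables (e.g. a constant imputation) give exactly 0.  i = 1 for
a perfect match, 0 for independence.  The plug-in estimator is used
deliberately; no bias correction or shrinkage.

The F-classifier maximises i over the formate grid on the training set's
h/c samples; the (G,F)-classifier over the full glucose × formate grid on
all three classes.  The search is exact: with cohort sizes of a few
hundred, the O(|G-grid|·|F-grid|·n) cost is negligible and the grid joint
counts factor into three einsum-able pieces per reference class, so the
whole grid is evaluated vectorised.

**Tie-break.** Among grid points attaining the maximum, the smallest F_T is
chosen, then the smallest G_T — a deterministic, value-based rule, so
results are invariant to the row order of the training table.  The tie set
is formed with an absolute tolerance of 1e-12 on the [0, 1] RMI scale:
mathematically equal optima (for example, partitions that differ only by a
label permutation) can differ by an ulp depending on summation order, and
without the tolerance row-order invariance itself would fail.  Genuine RMI
gaps between distinct optima on realistic grids are many orders of
magnitude larger.

**Significance.** A permutation test shuffles the reference labels
uniformly (n_perm times, seeded) and reports the add-one p-value
p = (1 + #{i_perm ≥ i_obs}) / (1 + n_perm), never exactly 0.  Shuffling S
or S\* is equivalent for this statistic; S is shuffled.

## Validation

**Prevalence-corrected rates.** For the cancer class on a validation set V:

    TPR_C = |V∩C∩C*| / |V∩C|
    FPR_C = (|V∩H∩C*| + x·|V∩O∩C*|) / (|V∩H| + x·|V∩O|),  x = p_O·|V∩H|/|V∩O|

The weight x dilutes the oversampled obesity group to p_O obesity samples
per healthy control; at p_O = 0 the expression reduces exactly to the
unweighted healthy-only FPR.  x is a function of each validation set's
composition and is recomputed per realisation, never cached.  The
implementation generalises to several confounder diseases D_1..D_k with
prevalences p_1..p_k, each weighted x_j = p_j·|V∩H|/|V∩D_j| — the direct
extension of the two-class formula — and to obesity as the positive class
with cancer as the confounder.

**ROC.** With T = V = U, sweeping F_T gives one (FPR, TPR) point per
candidate (a curve); sweeping (G_T, F_T) gives one point per grid pair (a
region — with two biomarkers the operating points fill a surface in the
(FPR, TPR) plane).  Sentinel thresholds guarantee the (0,0) and (1,1)
endpoints.  AUC is never used for model selection, only descriptively in a
null-curve test.

**Monte-Carlo cross-validation.** Per realisation, each sample joins the
training set independently with probability 0.75 (split sizes fluctuate by
design — the Bernoulli reading of the split, not fixed 75/25 counts);
thresholds are re-optimised on T and rates computed on V at the configured
p_O.  Estimates are reported as median with the 5th–95th percentile range
over realisations.  Realisations with a degenerate training set (missing a
required class) or an undefined metric (no cancer in V for TPR; no healthy
in V, or p_O > 0 with no obesity in V, for FPR) are skipped and counted —
skipping is the only policy that never fabricates a rate; the per-metric
valid counts are part of every estimate.  A single master seed spawns one
independent substream per realisation (`numpy` SeedSequence), so results
are reproducible and independent of execution order.  The default is
100,000 realisations; tests and the acceptance script use 2,000–10,000,
which stabilises medians to well under a percentage point on these cohort
sizes.

## Differential statistics

The volcano screen computes, per metabolite, the fold change of group
means (case/control, raw scale; medians available by option) and the
p-value of a two-tailed Welch t-test.  Rows are flagged at fixed tiers
p < 1e-3 and p < 1e-6; no multiple-testing correction enters the flags,
matching the fixed-tier reporting style, though Benjamini–Hochberg
q-values are emitted as a reference column.  Whether fold changes should
use means or medians, raw or log scale, is genuinely open; raw-scale means
are the default and the switch is exposed.  Metabolites with fewer than
two usable values in a group, or zero variance in both groups, keep their
row with an undefined p-value and an explicit flag.

Pearson correlation between two metabolite vectors is tested by permuting
one vector, two-sided on |r|, with the same add-one rule.

**Formate quantification.** Internal-standard GC-MS quantification:
concentration = effective_standard × (A_formate − A_blank,formate) /
(A_d2 − A_blank,d2), where the effective in-sample d2-formate
concentration is standard_conc × spike_volume / sample_volume (25 μM for
the default 50 μM, 20 μL into 40 μL scheme; all three are parameters since
dilution schemes vary).  The assay is treated as validated over 0–100 μM;
results outside warn.  Raw-spectrum processing (peak integration,
derivatisation chemistry, matrix effects) is out of scope — inputs are
integrated peak areas.

## Synthetic cohort generator

The generator emulates the study design, not any measured dataset (the
original per-patient measurements are not deposited):

* **Marginals** are lognormal — concentrations are positive and
  right-skewed.  Defaults: healthy formate median 0.080 mM (log-sd 0.35),
  cancer 0.035 mM (log-sd 0.40); non-obese glucose median 9.0×10⁷
  (log-sd 0.25), OD− 1.8×10⁸, OD+ 2.1×10⁸.  These were chosen once so the
  geometric midpoints sit at the two published thresholds (0.054 mM
  formate, 1.3×10⁸ peak-area glucose) and the qualitative group orderings
  hold; they are calibration choices, not measured group statistics, which
  were never published.
* **Obesity formate** is a 50/50 mixture of the healthy-like and
  cancer-like components, realising the observation that obesity formate
  spans from healthy-like down to cancer-like values — precisely the
  structure that makes obesity a confounder for the F-classifier.
* **Group sizes** default to H=50, BC=68, LC=56, OD−=46, OD+=35 (the
  published cohort table; the accompanying text differs slightly for LC
  and OD− — sizes are parameters, so the discrepancy is parameterised
  away, not resolved).
* **The co-metabolite** (sarcosine-like channel) is coupled to formate by
  a Gaussian copula on the log scale.  The latent is log-formate
  standardized by the *analytic cohort-level* mean/sd implied by the
  cohort recipe (mixture over groups and components), so the cohort-wide log-scale
  correlation equals the target ρ (default 0.6) by construction and
  group-mean tracking is included, scaled by ρ.  Standardizing within
  groups instead would overshoot the raw-scale correlation by adding the
  between-group shifts on top of ρ.  The raw-scale Pearson r is slightly
  below the log-scale value (≈0.57 at the defaults).

What the generator does **not** emulate: the broader LC-MS metabolite
panel, batch/block structure, matrix effects, measurement error models,
age/BMI covariates, or any within-subtype heterogeneity beyond the
obesity formate mixture.  Passing tests therefore demonstrate that the
pipeline's statistics and algorithms behave correctly on data with the
assumed structure — not that the published clinical performance figures
generalise, which would require the original measurements.

## Numerical and degenerate-input conventions

* Natural logarithms throughout; MI ≥ 0 and i ∈ [0, 1] up to 1e-12.
* Empty joint cells contribute 0 (0·ln 0 := 0).
* Threshold grids with a single observed value degenerate to three
  candidates (two sentinels + the value).
* Missing extra-metabolite values are permitted (absent), missing formate
  or glucose are hard row-level errors — the classifiers cannot run
  without them.
* CSV reading uses round-trip float parsing so write/read cycles are
  bit-identical on numeric columns.
* Percentile summaries use linear interpolation; all-identical realisation
  values collapse to (v, v, v).

## Known limitations

* The tree topology is fixed (obesity, then cancer) and limited to two
  biomarkers; no learned structure.
* The plug-in MI estimator is biased upward on small samples; since only
  the arg max over thresholds on a fixed sample is needed, this does not
  affect threshold choice, but reported i values on small cohorts should
  not be compared across sample sizes.
* Cross-validation percentile ranges are sampling ranges over splits of
  one cohort, not population confidence intervals.
* The equality-falls-to-healthy convention can make the nominally
  "perfect" separation unattainable on cohorts where a class boundary
  coincides with shared observed values.
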