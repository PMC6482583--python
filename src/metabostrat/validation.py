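"""Classifier validation: prevalence-corrected rates, ROC, cross-validation.

Case-control cohorts over-represent the confounder disease relative to the
population, so a raw false positive rate computed on the cohort is not the
one a screening programme would see.  With H, C, O the healthy, cancer and
obesity samples of a validation set V, and C* the samples imputed cancer,
the corrected cancer-screening rates are

    TPR_C = |V n C n C*| / |V n C|
    FPR_C = (|V n H n C*| + x |V n O n C*|) / (|V n H| + x |V n O|),
    x     = p_O |V n H| / |V n O|,

where p_O is the population obesity prevalence.  The weight x dilutes the
oversampled obesity group down to p_O obesity samples per healthy control;
at p_O = 0 the formula reduces exactly to the unweighted healthy-only FPR.
x depends on the composition of each validation set and is recomputed per
realisation, never cached.  The same construction extends to several
confounder diseases D_1..D_k with prevalences p_1..p_k, each contributing a
weight x_j = p_j |V n H| / |V n D_j| (see
:func:`prevalence_corrected_fpr`), and to obesity as the positive class
with cancer as the confounder.

Cross-validation is Monte-Carlo: each sample joins the training set
independently with probability 0.75 (so split sizes fluctuate), thresholds
are re-optimised on each training set, and rates are computed on the held
out samples.  Results are summarised as median with the 5th and 95th
percentiles over realisations.  Realisations whose training set is
degenerate (missing a required class) or whose validation set leaves a
metric undefined (no cancer sample, no healthy sample, or no obesity sample
while p_O > 0) are skipped and counted rather than imputed — skipping is
the only policy that never fabricates a rate.  A single master seed spawns
one independent random substream per realisation, so results do not depend
on execution order.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .classifier import (
    _candidate_grid,
    _encode_merged,
    _gf_grid_counts,
    _optimize_f_arrays,
    _optimize_gf_arrays,
)
from .data_model import ClassAssignment, CohortTable
from .errors import (
    CohortValidationError,
    DegenerateTrainingError,
    EstimationError,
    UndefinedMetricError,
)

__all__ = [
    "SplitConfig",
    "PerformanceEstimate",
    "CrossValidationResult",
    "tpr_cancer",
    "fpr_cancer",
    "tpr_obesity",
    "fpr_obesity",
    "prevalence_corrected_fpr",
    "roc_curve_F",
    "roc_region_GF",
    "cross_validate",
]


@dataclasses.dataclass(frozen=True)
class SplitConfig:
    """Monte-Carlo cross-validation configuration.

    ``train_probability`` is the per-sample Bernoulli probability of joining
    the training set; ``p_o`` the obesity prevalence used in the corrected
    FPR.  Defaults follow the study constants (0.75 split, 100,000
    realisations); tests and exploratory runs typically use 1,000-10,000
    realisations.
    """

    train_probability: float = 0.75
    n_realisations: int = 100_000
    seed: int = 0
    p_o: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.train_probability < 1:
            raise CohortValidationError("train_probability must be in (0, 1)")
        if self.n_realisations < 1:
            raise CohortValidationError("n_realisations must be >= 1")
        if not 0 <= self.p_o < 1:
            raise CohortValidationError("p_o must be in [0, 1)")


@dataclasses.dataclass(frozen=True)
class PerformanceEstimate:
    """A rate summarised as median with its 5th-95th percentile range over
    the valid resampling realisations."""

    metric: str
    median: float
    lo: float
    hi: float
    n_valid: int

    def __post_init__(self) -> None:
        if not (self.lo <= self.median <= self.hi):
            raise CohortValidationError("percentile summary must satisfy lo <= median <= hi")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class CrossValidationResult:
    tpr: PerformanceEstimate
    fpr: PerformanceEstimate
    config: SplitConfig
    classifier_kind: str
    skipped: dict[str, int]
    #: per-realisation rates (NaN where the metric was undefined)
    tpr_values: np.ndarray = dataclasses.field(repr=False, default=None)
    fpr_values: np.ndarray = dataclasses.field(repr=False, default=None)


def _labels(x) -> np.ndarray:
    if isinstance(x, ClassAssignment):
        return x.as_array()
    return np.asarray(x, dtype=object).ravel()


def tpr_cancer(reference, imputed) -> float:
    """Fraction of validation cancer samples imputed cancer."""
    ref, imp = _labels(reference), _labels(imputed)
    cancer = ref == "c"
    if not cancer.any():
        raise UndefinedMetricError("TPR_C undefined: no cancer samples in the validation set")
    return float(np.mean(imp[cancer] == "c"))


def tpr_obesity(reference, imputed) -> float:
    """Fraction of validation obesity samples imputed obesity."""
    ref, imp = _labels(reference), _labels(imputed)
    obese = ref == "o"
    if not obese.any():
        raise UndefinedMetricError("TPR_O undefined: no obesity samples in the validation set")
    return float(np.mean(imp[obese] == "o"))


def prevalence_corrected_fpr(
    reference, imputed, positive: str, prevalences: Mapping[str, float] | None = None
) -> float:
    """False positive rate for ``positive``, reweighting confounder classes.

    Healthy controls enter with weight 1; every other class ``d`` named in
    ``prevalences`` enters with weight x_d = p_d |V n H| / |V n D_d|, so
    that it contributes p_d confounder samples per healthy control.  Classes
    with prevalence 0 drop out exactly.
    """
    ref, imp = _labels(reference), _labels(imputed)
    healthy = ref == "h"
    n_h = int(healthy.sum())
    if n_h == 0:
        raise UndefinedMetricError("FPR undefined: no healthy samples in the validation set")
    numerator = float((imp[healthy] == positive).sum())
    denominator = float(n_h)
    for cls, p in (prevalences or {}).items():
        if cls in ("h", positive):
            raise CohortValidationError(
                f"prevalence weight for class {cls!r} conflicts with the positive/healthy roles"
            )
        if p == 0:
            continue
        members = ref == cls
        n_d = int(members.sum())
        if n_d == 0:
            raise UndefinedMetricError(
                f"FPR undefined: prevalence {p} given for class {cls!r} "
                "but no such samples in the validation set"
            )
        x = p * n_h / n_d
        numerator += x * float((imp[members] == positive).sum())
        denominator += x * n_d
    return numerator / denominator


def fpr_cancer(reference, imputed, p_o: float = 0.0) -> float:
    """Prevalence-corrected FPR for the cancer class (obesity confounder)."""
    return prevalence_corrected_fpr(reference, imputed, "c", {"o": p_o})


def fpr_obesity(reference, imputed, p_c: float = 0.0) -> float:
    """Prevalence-corrected FPR for the obesity class (cancer confounder)."""
    return prevalence_corrected_fpr(reference, imputed, "o", {"c": p_c})


# -- ROC --------------------------------------------------------------------


def roc_curve_F(
    cohort: CohortTable, include_obesity: bool = False, p_o: float = 0.0
):
    """ROC points of the F-classifier, one per candidate formate threshold.

    With ``include_obesity`` false the cohort is restricted to its healthy
    and cancer samples and p_o is ignored; otherwise obesity samples stay in
    the evaluated set and the corrected FPR applies.  Training and
    evaluation both use the full evaluated set (T = V = U).  Returns a
    DataFrame with columns ``f_t``, ``fpr``, ``tpr`` sorted by (fpr, tpr);
    the sentinel thresholds guarantee the (0, 0) and (1, 1) endpoints.
    """
    sub = cohort if include_obesity else cohort.restrict({"h", "c"})
    if len(sub) == 0:
        raise CohortValidationError("no samples to evaluate")
    ref = sub.merged
    formate = sub.formate
    rows = []
    for f_t in _candidate_grid(formate):
        imp = np.where(formate < f_t, "c", "h").astype(object)
        rows.append(
            (
                float(f_t),
                fpr_cancer(ref, imp, p_o if include_obesity else 0.0),
                tpr_cancer(ref, imp),
            )
        )
    frame = pd.DataFrame(rows, columns=["f_t", "fpr", "tpr"])
    return frame.sort_values(["fpr", "tpr"], kind="stable").reset_index(drop=True)


def roc_region_GF(cohort: CohortTable, p_o: float = 0.0):
    """ROC point set of the (G,F)-classifier for the cancer class.

    One point per (G_T, F_T) pair on the full candidate grid, evaluated on
    the whole cohort (T = V = U) with the corrected FPR.  The result is a
    region, not a curve: two biomarkers sweep a surface in the (FPR, TPR)
    plane.  Returns a DataFrame with columns ``g_t``, ``f_t``, ``fpr``,
    ``tpr``.
    """
    classes = set(cohort.merged)
    if not {"h", "c", "o"} <= classes:
        raise CohortValidationError(
            f"(G,F) ROC region needs h, c and o samples, got {sorted(classes)}"
        )
    merged = cohort.merged
    codes, n_classes = _encode_merged(merged)
    g_cand = _candidate_grid(cohort.glucose)
    f_cand = _candidate_grid(cohort.formate)
    counts = _gf_grid_counts(
        cohort.glucose, cohort.formate, codes, n_classes, g_cand, f_cand
    )
    # counts[class, imputed(o,c,h), i_g, i_f]
    n_h = float((merged == "h").sum())
    n_c = float((merged == "c").sum())
    n_o = float((merged == "o").sum())
    tpr = counts[1, 1] / n_c
    x = p_o * n_h / n_o if p_o > 0 else 0.0
    fpr = (counts[0, 1] + x * counts[2, 1]) / (n_h + x * n_o)
    gg, ff = np.meshgrid(g_cand, f_cand, indexing="ij")
    return pd.DataFrame(
        {
            "g_t": gg.ravel(),
            "f_t": ff.ravel(),
            "fpr": fpr.ravel(),
            "tpr": tpr.ravel(),
        }
    )


# -- Monte-Carlo cross-validation -------------------------------------------


def _summarise(metric: str, values: np.ndarray) -> PerformanceEstimate:
    lo, med, hi = np.percentile(values, [5, 50, 95])
    return PerformanceEstimate(
        metric=metric, median=float(med), lo=float(lo), hi=float(hi), n_valid=len(values)
    )


def cross_validate(
    cohort: CohortTable, classifier_kind: str, cfg: SplitConfig
) -> CrossValidationResult:
    """Repeated random-split cross-validation of a classifier.

    Per realisation: every sample is assigned to the training set with
    probability ``cfg.train_probability``; the classifier's thresholds are
    re-optimised on the training samples (restricted to healthy + cancer for
    the F-classifier); TPR_C and the prevalence-corrected FPR_C are computed
    on the held-out samples.  Undefined realisations are skipped and their
    reasons tallied in ``skipped``.
    """
    if classifier_kind not in ("F", "GF"):
        raise CohortValidationError(f"unknown classifier kind {classifier_kind!r}")
    n = len(cohort)
    if n < 2:
        raise CohortValidationError("cohort too small to split")
    glucose = cohort.glucose
    formate = cohort.formate
    merged = cohort.merged

    master = np.random.SeedSequence(cfg.seed)
    children = master.spawn(cfg.n_realisations)

    tpr_values = np.full(cfg.n_realisations, np.nan)
    fpr_values = np.full(cfg.n_realisations, np.nan)
    skipped: Counter[str] = Counter()

    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        in_train = rng.random(n) < cfg.train_probability
        val = ~in_train
        if not val.any():
            skipped["empty_validation_set"] += 1
            continue
        try:
            if classifier_kind == "F":
                f_0, _ = _optimize_f_arrays(formate[in_train], merged[in_train])
                imp = np.where(formate[val] < f_0, "c", "h").astype(object)
            else:
                g_0, f_0, _ = _optimize_gf_arrays(
                    glucose[in_train], formate[in_train], merged[in_train]
                )
                imp = np.full(int(val.sum()), "h", dtype=object)
                gv, fv = glucose[val], formate[val]
                imp[gv > g_0] = "o"
                imp[(gv < g_0) & (fv < f_0)] = "c"
        except DegenerateTrainingError:
            skipped["degenerate_training_set"] += 1
            continue
        ref = merged[val]
        try:
            tpr_values[k] = tpr_cancer(ref, imp)
        except UndefinedMetricError:
            skipped["no_cancer_in_validation"] += 1
        try:
            fpr_values[k] = fpr_cancer(ref, imp, cfg.p_o)
        except UndefinedMetricError:
            skipped["fpr_undefined_in_validation"] += 1

    tpr_valid = tpr_values[~np.isnan(tpr_values)]
    fpr_valid = fpr_values[~np.isnan(fpr_values)]
    if len(tpr_valid) == 0 or len(fpr_valid) == 0:
        raise EstimationError(
            f"no valid realisations (skip reasons: {dict(skipped)})"
        )
    return CrossValidationResult(
        tpr=_summarise("TPR_C", tpr_valid),
        fpr=_summarise("FPR_C", fpr_valid),
        config=cfg,
        classifier_kind=classifier_kind,
        skipped=dict(skipped),
        tpr_values=tpr_values,
        fpr_values=fpr_values,
    )
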