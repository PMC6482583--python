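"""Threshold classifiers and their selection by relative mutual information.

Two classifiers are implemented:

* the **F-classifier**: a sample is imputed cancer (``c``) when its formate
  level lies strictly below a threshold F_T, healthy (``h``) otherwise;
* the **(G,F)-classifier**: a fixed two-level decision tree that first
  imputes obesity (``o``) when glucose lies strictly above a threshold G_T,
  then splits the remainder into cancer (glucose < G_T and formate < F_T)
  and healthy (everything else).

Branch conditions are strict inequalities with an "otherwise" catch-all, so
a sample sitting exactly on a threshold is never assigned to the positive
branch: F_i = F_T gives ``h``, and G_i = G_T gives ``h`` even when
F_i < F_T (neither the obesity nor the cancer branch fires).  This matters
in practice because candidate thresholds are taken from the observed values
themselves, making exact equality common rather than a measure-zero event.

Thresholds are selected by exhaustive search over the observed biomarker
values (augmented with one sentinel below the minimum and one above the
maximum so the all-positive and all-negative assignments are reachable),
maximising the relative mutual information between imputed and reference
labels.  Ties in the arg max are broken toward the smallest F_T, then the
smallest G_T — a deterministic, value-based rule, so the result is invariant
to the row order of the training table.  Cohorts here are a few hundred
samples, so the O(|G grid| x |F grid| x n) search is exact and fast; no
pruning is attempted.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence

import numpy as np

from .data_model import ClassAssignment, CohortTable
from .errors import CohortValidationError, DegenerateTrainingError

__all__ = [
    "ThresholdPair",
    "FitResult",
    "impute_F",
    "impute_GF",
    "classify_cohort",
    "candidate_thresholds",
    "optimize_F",
    "optimize_GF",
]


@dataclasses.dataclass(frozen=True)
class ThresholdPair:
    """Decision thresholds: glucose G_T (peak area; None for the F-only
    classifier) and formate F_T (mM)."""

    f_t: float
    g_t: float | None = None

    def __post_init__(self) -> None:
        if not (self.f_t > 0 and math.isfinite(self.f_t)):
            raise CohortValidationError(f"F_T must be positive and finite, got {self.f_t}")
        if self.g_t is not None and not (self.g_t > 0 and math.isfinite(self.g_t)):
            raise CohortValidationError(
                f"G_T must be positive and finite when present, got {self.g_t}"
            )


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Outcome of a threshold optimisation.

    ``rmi`` is the relative mutual information achieved at the optimum on
    the training samples used; ``class_counts`` records the training-set
    composition by merged class.
    """

    thresholds: ThresholdPair
    rmi: float
    n_train: int
    class_counts: dict[str, int]


def _validate_levels(values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise CohortValidationError(f"{name} levels must be finite and nonnegative")
    return values


def impute_F(formate, f_t: float):
    """Impute ``c`` where formate < F_T (strict), ``h`` otherwise.

    Accepts a scalar or an array of formate levels (mM).
    """
    if not (f_t > 0 and math.isfinite(f_t)):
        raise CohortValidationError(f"F_T must be positive and finite, got {f_t}")
    scalar = np.isscalar(formate)
    values = _validate_levels(np.atleast_1d(formate), "formate")
    labels = np.where(values < f_t, "c", "h").astype(object)
    return labels[0] if scalar else labels


def impute_GF(glucose, formate, thresholds: ThresholdPair):
    """Impute ``o`` where glucose > G_T; ``c`` where glucose < G_T and
    formate < F_T; ``h`` otherwise.  Accepts scalars or arrays."""
    if thresholds.g_t is None:
        raise CohortValidationError("the (G,F)-classifier needs a glucose threshold")
    scalar = np.isscalar(glucose) and np.isscalar(formate)
    g = _validate_levels(np.atleast_1d(glucose), "glucose")
    f = _validate_levels(np.atleast_1d(formate), "formate")
    labels = np.full(np.broadcast(g, f).shape, "h", dtype=object)
    labels[g > thresholds.g_t] = "o"
    labels[(g < thresholds.g_t) & (f < thresholds.f_t)] = "c"
    return labels[0] if scalar else labels


def classify_cohort(
    cohort: CohortTable, thresholds: ThresholdPair, kind: str = "GF"
) -> ClassAssignment:
    """Apply a classifier to every sample of a cohort."""
    if kind == "F":
        labels = impute_F(cohort.formate, thresholds.f_t)
        provenance = f"F-classifier F_T={thresholds.f_t!r}"
    elif kind == "GF":
        labels = impute_GF(cohort.glucose, cohort.formate, thresholds)
        provenance = f"(G,F)-classifier G_T={thresholds.g_t!r} F_T={thresholds.f_t!r}"
    else:
        raise CohortValidationError(f"unknown classifier kind {kind!r}")
    return ClassAssignment(
        sample_ids=tuple(cohort.sample_ids),
        labels=tuple(labels),
        provenance=provenance,
    )


def _candidate_grid(values: np.ndarray) -> np.ndarray:
    """Sorted distinct values plus a sentinel below the minimum and above the
    maximum.  The low sentinel yields the all-negative assignment, the high
    sentinel the all-positive one (for strict `<`) or all-negative (for the
    glucose `>` branch)."""
    distinct = np.unique(np.asarray(values, dtype=float))
    lo = distinct[0] / 2.0 if distinct[0] > 0 else distinct[0] - 1.0
    hi = distinct[-1] * 2.0 if distinct[-1] > 0 else 1.0
    return np.concatenate(([lo], distinct, [hi]))


def candidate_thresholds(cohort: CohortTable, biomarker: str) -> np.ndarray:
    """Threshold candidates for a biomarker: its sorted distinct observed
    values, augmented with one sentinel below and one above."""
    if len(cohort) == 0:
        raise CohortValidationError("cannot build a threshold grid from an empty cohort")
    if biomarker == "formate":
        values = cohort.formate
    elif biomarker == "glucose":
        values = cohort.glucose
    else:
        raise CohortValidationError(f"unknown biomarker {biomarker!r}")
    return _candidate_grid(values)


# -- grid machinery ---------------------------------------------------------
#
# For the decision tree, the joint (reference class x imputed class) counts
# over the whole (G_T, F_T) grid factor into three einsum-able pieces:
# per reference class a,
#     n(a -> o)[j]    = #{i in a : G_i > G_T[j]}
#     n(a -> c)[j,k]  = #{i in a : G_i < G_T[j] and F_i < F_T[k]}
#     n(a -> h)       = |a| - n(a -> o) - n(a -> c)
# Note the o-branch uses > and the c-branch uses <, so samples with
# G_i = G_T[j] land in h, matching the strict-inequality semantics above.


def _gf_grid_counts(
    glucose: np.ndarray,
    formate: np.ndarray,
    codes: np.ndarray,
    n_classes: int,
    g_cand: np.ndarray,
    f_cand: np.ndarray,
) -> np.ndarray:
    """Joint counts over the full threshold grid.

    Returns an array of shape (n_classes, 3, nG, nF) where axis 1 indexes
    the imputed label in the fixed order (o, c, h).
    """
    n_g, n_f = len(g_cand), len(f_cand)
    above = glucose[:, None] > g_cand[None, :]
    below_g = glucose[:, None] < g_cand[None, :]
    below_f = formate[:, None] < f_cand[None, :]
    counts = np.empty((n_classes, 3, n_g, n_f))
    for a in range(n_classes):
        sel = codes == a
        n_a = int(sel.sum())
        n_o = above[sel].sum(axis=0).astype(float)
        n_c = np.einsum(
            "ij,ik->jk",
            below_g[sel].astype(float),
            below_f[sel].astype(float),
        )
        counts[a, 0] = n_o[:, None]
        counts[a, 1] = n_c
        counts[a, 2] = n_a - counts[a, 0] - n_c
    return counts


def _rmi_grid(counts: np.ndarray, n: int) -> np.ndarray:
    """Relative mutual information at every grid point, from joint counts of
    shape (n_ref_classes, 3, nG, nF)."""
    p = counts / n
    q = p.sum(axis=(1, 2, 3)) / (counts.shape[2] * counts.shape[3])  # per-class fraction
    r = p.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_term = np.log(p) - np.log(q)[:, None, None, None] - np.log(r)[None]
        mi = np.where(p > 0, p * log_term, 0.0).sum(axis=(0, 1))
    present = q > 0
    h_ref = float(-(q[present] * np.log(q[present])).sum())
    return mi / h_ref


#: Two grid points whose relative MI differs by less than this are treated
#: as tied.  Summation order (and hence row order) can perturb mathematically
#: equal values by an ulp; genuine differences on any realistic grid are
#: orders of magnitude larger than 1e-12 on the [0, 1] scale.
_TIE_ATOL = 1e-12


def _argmax_smallest_f_then_g(
    i_grid: np.ndarray, g_cand: np.ndarray, f_cand: np.ndarray
) -> tuple[int, int]:
    """Index of the grid maximum; ties resolved toward the smallest F_T,
    then the smallest G_T (value-based, hence row-order invariant)."""
    best = i_grid.max()
    g_idx, f_idx = np.nonzero(i_grid >= best - _TIE_ATOL)
    k = np.lexsort((g_cand[g_idx], f_cand[f_idx]))[0]
    return int(g_idx[k]), int(f_idx[k])


_CLASS_ORDER = {"h": 0, "c": 1, "o": 2}


def _encode_merged(merged: np.ndarray) -> tuple[np.ndarray, int]:
    codes = np.array([_CLASS_ORDER[m] for m in merged], dtype=np.intp)
    return codes, 3


def _optimize_f_arrays(formate: np.ndarray, merged: np.ndarray) -> tuple[float, float]:
    """F_0 and achieved relative MI on raw arrays (h/c samples only)."""
    keep = np.isin(merged, ("h", "c"))
    formate, merged = formate[keep], merged[keep]
    classes = set(merged)
    if not {"h", "c"} <= classes:
        raise DegenerateTrainingError(
            f"F-classifier training needs both h and c samples, got {sorted(classes)}"
        )
    codes, n_classes = _encode_merged(merged)
    f_cand = _candidate_grid(formate)
    # single glucose sentinel above every value: the o branch never fires and
    # the tree degenerates to the pure formate rule
    g_cand = np.array([np.inf])
    glucose = np.zeros_like(formate)
    counts = _gf_grid_counts(glucose, formate, codes, n_classes, g_cand, f_cand)
    i_grid = _rmi_grid(counts, len(formate))
    _, f_idx = _argmax_smallest_f_then_g(i_grid, g_cand, f_cand)
    return float(f_cand[f_idx]), float(i_grid[0, f_idx])


def _optimize_gf_arrays(
    glucose: np.ndarray, formate: np.ndarray, merged: np.ndarray
) -> tuple[float, float, float]:
    """(G_0, F_0) and achieved relative MI on raw arrays (all three classes)."""
    classes = set(merged)
    if not {"h", "c", "o"} <= classes:
        raise DegenerateTrainingError(
            f"(G,F)-classifier training needs h, c and o samples, got {sorted(classes)}"
        )
    codes, n_classes = _encode_merged(merged)
    g_cand = _candidate_grid(glucose)
    f_cand = _candidate_grid(formate)
    counts = _gf_grid_counts(glucose, formate, codes, n_classes, g_cand, f_cand)
    i_grid = _rmi_grid(counts, len(formate))
    g_idx, f_idx = _argmax_smallest_f_then_g(i_grid, g_cand, f_cand)
    return float(g_cand[g_idx]), float(f_cand[f_idx]), float(i_grid[g_idx, f_idx])


def optimize_F(train: CohortTable) -> FitResult:
    """Best formate threshold F_0 on a training cohort.

    Restricts the cohort to its healthy and cancer samples, evaluates every
    candidate F_T and returns the one maximising the relative mutual
    information of the imputed vs reference labels (smallest F_T on ties).
    """
    sub = train.restrict({"h", "c"})
    if len(sub) == 0:
        raise DegenerateTrainingError("training cohort has no h or c samples")
    f_0, rmi = _optimize_f_arrays(sub.formate, sub.merged)
    return FitResult(
        thresholds=ThresholdPair(f_t=f_0),
        rmi=rmi,
        n_train=len(sub),
        class_counts=sub.class_counts(),
    )


def optimize_GF(train: CohortTable) -> FitResult:
    """Best (G_0, F_0) pair on a training cohort containing all three
    merged classes, by exhaustive search over the glucose x formate grid."""
    if len(train) == 0:
        raise DegenerateTrainingError("training cohort is empty")
    g_0, f_0, rmi = _optimize_gf_arrays(train.glucose, train.formate, train.merged)
    return FitResult(
        thresholds=ThresholdPair(f_t=f_0, g_t=g_0),
        rmi=rmi,
        n_train=len(train),
        class_counts=train.class_counts(),
    )
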