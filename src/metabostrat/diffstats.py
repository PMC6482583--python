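"""Differential screening, correlation testing and formate quantification.

``welch_volcano`` produces the per-metabolite statistics behind a volcano
plot: fold change of group means (case over control, raw scale) against the
p-value of a two-tailed Welch t-test (unequal variances).  Rows are flagged
at two fixed significance tiers, p < 1e-3 (``*``) and p < 1e-6 (``**``); no
multiple-testing correction enters the flags, though a Benjamini-Hochberg
q-value column is emitted for reference.  The fold-change estimator is the
arithmetic group mean by default, with medians available via ``estimator``.

``correlation_perm`` reports a plug-in Pearson correlation with a two-sided
permutation p-value on |r| (add-one rule, seeded).

``quantify_formate`` implements internal-standard quantification from GC-MS
peak areas: the analyte concentration is the analyte/standard peak-area
ratio, after blank (background) subtraction, scaled by the effective
in-sample concentration of the isotope-labelled standard.  With the default
spike scheme (50 uM d2-formate, 20 uL spiked into 40 uL sample) that
effective concentration is 25 uM.  The assay is treated as validated over
0-100 uM; values outside emit :class:`QuantificationRangeWarning`.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CohortTable
from .errors import (
    CohortValidationError,
    QuantificationError,
    QuantificationRangeWarning,
)

__all__ = ["welch_volcano", "correlation_perm", "quantify_formate"]

SIGNIFICANCE_TIERS = (1e-3, 1e-6)
VALIDATED_RANGE_UM = (0.0, 100.0)


def _metabolite_columns(cohort: CohortTable) -> dict[str, np.ndarray]:
    cols = {"formate": cohort.formate, "glucose": cohort.glucose}
    for name in cohort.extra_names:
        cols[name] = cohort.extra(name)
    return cols


def welch_volcano(
    cohort: CohortTable,
    case_subtype: str,
    control_subtype: str,
    estimator: str = "mean",
) -> pd.DataFrame:
    """Per-metabolite fold change and Welch p-value, case vs control.

    Returns one row per metabolite with columns ``metabolite``,
    ``fold_change``, ``p_value``, ``q_value`` (Benjamini-Hochberg, reference
    only), ``tier`` (``**``, ``*`` or empty), ``n_case``, ``n_control`` and
    ``flag``.  Metabolites with fewer than two usable values in either
    group, or with zero variance in both, keep their row with an undefined
    p-value and a non-empty ``flag`` — they are never silently dropped.
    """
    if estimator not in ("mean", "median"):
        raise CohortValidationError(f"unknown estimator {estimator!r}")
    subtypes = cohort.subtypes
    case_mask = subtypes == case_subtype
    control_mask = subtypes == control_subtype
    if not case_mask.any() or not control_mask.any():
        raise CohortValidationError(
            f"no samples for case {case_subtype!r} and/or control {control_subtype!r}"
        )
    center = np.mean if estimator == "mean" else np.median

    rows = []
    for name, values in _metabolite_columns(cohort).items():
        case = values[case_mask]
        control = values[control_mask]
        case = case[np.isfinite(case)]
        control = control[np.isfinite(control)]
        flag = ""
        fold = math.nan
        p = math.nan
        if len(case) >= 1 and len(control) >= 1:
            c0 = float(center(control))
            fold = float(center(case)) / c0 if c0 > 0 else math.nan
        if len(case) < 2 or len(control) < 2:
            flag = "insufficient_n"
        else:
            if np.var(case) == 0 and np.var(control) == 0:
                flag = "zero_variance"
            else:
                p = float(
                    stats.ttest_ind(case, control, equal_var=False).pvalue
                )
        tier = ""
        if not math.isnan(p):
            if p < SIGNIFICANCE_TIERS[1]:
                tier = "**"
            elif p < SIGNIFICANCE_TIERS[0]:
                tier = "*"
        rows.append(
            {
                "metabolite": name,
                "fold_change": fold,
                "p_value": p,
                "tier": tier,
                "n_case": len(case),
                "n_control": len(control),
                "flag": flag,
            }
        )
    frame = pd.DataFrame(rows)
    q = np.full(len(frame), math.nan)
    defined = frame["p_value"].notna().to_numpy()
    if defined.any():
        q[defined] = stats.false_discovery_control(
            frame.loc[defined, "p_value"].to_numpy()
        )
    frame.insert(3, "q_value", q)
    return frame


def correlation_perm(
    x,
    y,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Pearson correlation with a two-sided permutation p-value.

    ``y`` is shuffled ``n_perm`` times; the p-value is the add-one fraction
    of permutations with |r_perm| >= |r_observed|.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y) or len(x) < 3:
        raise CohortValidationError("paired vectors of length >= 3 required")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise CohortValidationError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise CohortValidationError("correlation undefined for a zero-variance input")
    if n_perm < 1:
        raise CohortValidationError("n_perm must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    r_obs = float(xc @ yc) / denom
    exceed = 0
    for _ in range(n_perm):
        r_perm = float(xc @ rng.permutation(yc)) / denom
        if abs(r_perm) >= abs(r_obs):
            exceed += 1
    return r_obs, (1 + exceed) / (1 + n_perm)


def quantify_formate(
    area_formate: float,
    area_d2: float,
    blank_area_formate: float = 0.0,
    blank_area_d2: float = 0.0,
    standard_conc_uM: float = 50.0,
    standard_volume_uL: float = 20.0,
    sample_volume_uL: float = 40.0,
) -> float:
    """Formate concentration (uM) from analyte and internal-standard areas.

    concentration = effective_standard * (area_formate - blank_formate)
                                        / (area_d2 - blank_d2)

    where ``effective_standard`` is the in-sample concentration of the
    spiked d2-formate, ``standard_conc_uM * standard_volume_uL /
    sample_volume_uL`` (25 uM with the defaults).  Negative corrected
    analyte areas clip to 0.  A nonpositive corrected internal-standard
    area is unquantifiable and raises :class:`QuantificationError`; results
    outside the validated 0-100 uM range carry a
    :class:`QuantificationRangeWarning`.
    """
    for name, v in (
        ("area_formate", area_formate),
        ("area_d2", area_d2),
        ("blank_area_formate", blank_area_formate),
        ("blank_area_d2", blank_area_d2),
    ):
        if not (math.isfinite(v) and v >= 0):
            raise CohortValidationError(f"{name} must be finite and >= 0, got {v!r}")
    if not (standard_conc_uM > 0 and standard_volume_uL > 0 and sample_volume_uL > 0):
        raise CohortValidationError("standard concentration and volumes must be > 0")
    corrected_d2 = area_d2 - blank_area_d2
    if corrected_d2 <= 0:
        raise QuantificationError(
            "corrected internal-standard area is nonpositive; cannot quantify"
        )
    corrected_formate = max(area_formate - blank_area_formate, 0.0)
    effective_standard = standard_conc_uM * standard_volume_uL / sample_volume_uL
    concentration = effective_standard * corrected_formate / corrected_d2
    lo, hi = VALIDATED_RANGE_UM
    if not lo <= concentration <= hi:
        warnings.warn(
            f"formate concentration {concentration:.3g} uM is outside the "
            f"validated {lo:g}-{hi:g} uM range",
            QuantificationRangeWarning,
            stacklevel=2,
        )
    return concentration
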