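"""Mutual information between an imputed and a reference classification.

The classifiers in this package are selected by *relative mutual
information*.  For a reference labelling S and an imputed labelling S* over
a sample set U, the (plug-in) mutual information is

    I(S*, S | U) = sum_ab  p_ab ln( p_ab / (q_a r_b) )        [nats]

where p_ab is the fraction of samples with reference class a and imputed
class b, and q_a, r_b are the corresponding marginal fractions.  The
relative mutual information normalises by the reference-label entropy,

    i(S*, S | U) = I(S*, S | U) / ( -sum_a q_a ln q_a ),

so that i = 1 for a perfect match (S* = S) and i = 0 for statistically
independent labellings.  Cells with p_ab = 0 contribute 0 (the standard
0 ln 0 := 0 limit).  All logarithms are natural.

Significance is assessed with a permutation test that shuffles the reference
labels uniformly at random and uses the add-one rule
p = (1 + #{i_perm >= i_obs}) / (1 + n_perm), so the reported p-value is
never exactly zero.  Shuffling S or S* is equivalent for this statistic;
this implementation shuffles S.  No bias-corrected or shrinkage estimator is
used: the plug-in estimator is the quantity of interest here.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import CohortValidationError, UndefinedNormalizationError

__all__ = [
    "JointClassCounts",
    "joint_counts",
    "entropy",
    "mutual_information",
    "relative_mutual_information",
    "permutation_pvalue",
]


def _as_labels(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=object).ravel()
    if arr.size == 0:
        raise CohortValidationError(f"{name}: empty label vector")
    return arr


def _encode_pair(s_star, s) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    s = _as_labels(s, "reference labels")
    s_star = _as_labels(s_star, "imputed labels")
    if len(s) != len(s_star):
        raise CohortValidationError(
            f"label vectors differ in length: {len(s_star)} imputed vs {len(s)} reference"
        )
    ref_classes, ref_codes = np.unique(s, return_inverse=True)
    imp_classes, imp_codes = np.unique(s_star, return_inverse=True)
    return ref_classes, ref_codes, imp_classes, imp_codes


@dataclasses.dataclass(frozen=True)
class JointClassCounts:
    """Joint and marginal class fractions of a (reference, imputed) labelling.

    ``p_ab[a, b]`` is the fraction of samples in reference class
    ``ref_classes[a]`` and imputed class ``imp_classes[b]``; ``q`` and ``r``
    are the reference and imputed marginals.  Fractions sum to one and the
    marginals are consistent with the joint by construction.
    """

    ref_classes: tuple
    imp_classes: tuple
    p_ab: np.ndarray
    q: np.ndarray
    r: np.ndarray
    n: int


def joint_counts(s_star, s) -> JointClassCounts:
    """Tabulate joint class fractions of imputed vs reference labels."""
    ref_classes, ref_codes, imp_classes, imp_codes = _encode_pair(s_star, s)
    n = len(ref_codes)
    counts = np.bincount(
        ref_codes * len(imp_classes) + imp_codes,
        minlength=len(ref_classes) * len(imp_classes),
    ).reshape(len(ref_classes), len(imp_classes))
    # marginals from the integer counts, not from summing p: integer sums
    # are exact, so e.g. a constant imputation has r identically 1 and the
    # mutual information vanishes exactly rather than to rounding error
    return JointClassCounts(
        ref_classes=tuple(ref_classes),
        imp_classes=tuple(imp_classes),
        p_ab=counts / n,
        q=counts.sum(axis=1) / n,
        r=counts.sum(axis=0) / n,
        n=n,
    )


def entropy(labels) -> float:
    """Shannon entropy of a labelling, in nats."""
    arr = _as_labels(labels, "labels")
    _, counts = np.unique(arr, return_counts=True)
    q = counts / arr.size
    return float(-(q * np.log(q)).sum())


def _mi_from_fractions(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> float:
    mask = p > 0
    qr = np.outer(q, r)
    return float((p[mask] * np.log(p[mask] / qr[mask])).sum())


def mutual_information(s_star, s) -> float:
    """Plug-in mutual information I(S*, S | U) in nats (always >= 0)."""
    jc = joint_counts(s_star, s)
    return _mi_from_fractions(jc.p_ab, jc.q, jc.r)


def relative_mutual_information(s_star, s) -> float:
    """Mutual information normalised by the reference-label entropy.

    Equals 1 when ``s_star`` reproduces ``s`` exactly, 0 when independent.
    Raises :class:`UndefinedNormalizationError` when the reference labelling
    has a single class (zero entropy).
    """
    jc = joint_counts(s_star, s)
    if len(jc.ref_classes) < 2:
        raise UndefinedNormalizationError(
            "relative mutual information is undefined for a single-class reference"
        )
    h_ref = float(-(jc.q * np.log(jc.q)).sum())
    return _mi_from_fractions(jc.p_ab, jc.q, jc.r) / h_ref


def permutation_pvalue(
    s_star,
    s,
    n_perm: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Permutation p-value for the observed relative mutual information.

    The reference labels are shuffled uniformly ``n_perm`` times and the
    add-one rule p = (1 + #{i_perm >= i_obs}) / (1 + n_perm) is applied, so
    0 < p <= 1 always.  Reproducible for a fixed integer ``seed``.
    """
    if n_perm < 1:
        raise CohortValidationError("n_perm must be >= 1")
    ref_classes, ref_codes, imp_classes, imp_codes = _encode_pair(s_star, s)
    if len(ref_classes) < 2:
        raise UndefinedNormalizationError(
            "permutation test on relative mutual information needs >= 2 reference classes"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = len(ref_codes)
    n_imp = len(imp_classes)
    n_cells = len(ref_classes) * n_imp

    def _rmi(codes: np.ndarray) -> float:
        counts = np.bincount(codes * n_imp + imp_codes, minlength=n_cells).reshape(
            len(ref_classes), n_imp
        )
        p = counts / n
        q = counts.sum(axis=1) / n
        r = counts.sum(axis=0) / n
        h_ref = float(-(q[q > 0] * np.log(q[q > 0])).sum())
        return _mi_from_fractions(p, q, r) / h_ref

    observed = _rmi(ref_codes)
    exceed = 0
    for _ in range(n_perm):
        if _rmi(rng.permutation(ref_codes)) >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)
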