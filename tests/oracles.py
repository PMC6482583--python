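"""Independent straight-line reimplementations used as test oracles.

Everything here is deliberately naive: Counter-based tabulation, explicit
per-sample if/else classification and full enumeration over threshold
grids, with no shared code paths with the package implementation.
"""

import math
from collections import Counter


def mi_oracle(s_star, s):
    """Mutual information by direct cell summation, nats."""
    n = len(s)
    joint = Counter(zip(s, s_star))
    qs = Counter(s)
    rs = Counter(s_star)
    total = 0.0
    for (a, b), c in joint.items():
        p = c / n
        total += p * math.log(p / ((qs[a] / n) * (rs[b] / n)))
    return total


def entropy_oracle(labels):
    n = len(labels)
    return -sum((c / n) * math.log(c / n) for c in Counter(labels).values())


def joint_entropy_oracle(s_star, s):
    return entropy_oracle(list(zip(s, s_star)))


def rmi_oracle(s_star, s):
    return mi_oracle(s_star, s) / entropy_oracle(s)


def candidates_oracle(values):
    """Sorted distinct values with one sentinel below and one above (same
    contract as the package grid, re-derived independently)."""
    distinct = sorted(set(float(v) for v in values))
    lo = distinct[0] / 2.0 if distinct[0] > 0 else distinct[0] - 1.0
    hi = distinct[-1] * 2.0 if distinct[-1] > 0 else 1.0
    return [lo] + distinct + [hi]


def impute_f_oracle(formate, f_t):
    return ["c" if f < f_t else "h" for f in formate]


def impute_gf_oracle(glucose, formate, g_t, f_t):
    labels = []
    for g, f in zip(glucose, formate):
        if g > g_t:
            labels.append("o")
        elif g < g_t and f < f_t:
            labels.append("c")
        else:
            labels.append("h")
    return labels


#: Same tie tolerance as the implementation: mathematically equal optima can
#: differ by an ulp between summation orders, genuine gaps are far larger.
TIE_ATOL = 1e-12


def brute_force_f(formate, merged):
    """Exhaustive F_0 search on h/c samples; ties -> smallest F_T."""
    pairs = [(f, m) for f, m in zip(formate, merged) if m in ("h", "c")]
    fs = [f for f, _ in pairs]
    ref = [m for _, m in pairs]
    grid = [
        (f_t, rmi_oracle(impute_f_oracle(fs, f_t), ref))
        for f_t in candidates_oracle(fs)
    ]
    best = max(i for _, i in grid)
    ties = [f_t for f_t, i in grid if i >= best - TIE_ATOL]
    return min(ties), best


def brute_force_gf(glucose, formate, merged):
    """Exhaustive (G_0, F_0) search; ties -> smallest F_T then smallest G_T."""
    merged = list(merged)
    grid = [
        (g_t, f_t, rmi_oracle(impute_gf_oracle(glucose, formate, g_t, f_t), merged))
        for g_t in candidates_oracle(glucose)
        for f_t in candidates_oracle(formate)
    ]
    best = max(i for _, _, i in grid)
    ties = [(f_t, g_t) for g_t, f_t, i in grid if i >= best - TIE_ATOL]
    f_0, g_0 = min(ties)
    return g_0, f_0, best


def welch_p_oracle(a, b):
    """Two-tailed Welch p from the textbook statistic and the
    Welch-Satterthwaite degrees of freedom."""
    import numpy as np
    from scipy.stats import t as t_dist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return 2 * t_dist.sf(abs(t), df)


def tpr_oracle(reference, imputed, positive="c"):
    hits = sum(1 for r, s in zip(reference, imputed) if r == positive and s == positive)
    total = sum(1 for r in reference if r == positive)
    return hits / total


def fpr_oracle(reference, imputed, p_o=0.0, positive="c"):
    """Set-intersection transcription of the weighted FPR definition."""
    n_h = sum(1 for r in reference if r == "h")
    n_o = sum(1 for r in reference if r == "o")
    fp_h = sum(1 for r, s in zip(reference, imputed) if r == "h" and s == positive)
    fp_o = sum(1 for r, s in zip(reference, imputed) if r == "o" and s == positive)
    if p_o == 0:
        return fp_h / n_h
    x = p_o * n_h / n_o
    return (fp_h + x * fp_o) / (n_h + x * n_o)
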