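"""Independent brute-force reference implementations used as test oracles.

These are deliberately naive (per-cell loops, direct formulas, full sorts)
and share no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def tpm_naive(counts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    out = np.zeros_like(counts, dtype=float)
    for j in range(counts.shape[1]):
        rates = [counts[i, j] / lengths[i] for i in range(counts.shape[0])]
        total = sum(rates)
        for i in range(counts.shape[0]):
            out[i, j] = 1e6 * rates[i] / total if total > 0 else 0.0
    return out


def bh_naive(pvalues: np.ndarray) -> np.ndarray:
    """Direct step-up: q_i = min over p_j >= p_i of m * p_j / rank_j."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = np.empty(m)
    running_min = 1.0
    for i in range(m - 1, -1, -1):
        running_min = min(running_min, m * ranked[i] / (i + 1))
        q[i] = running_min
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def tmm_naive(counts: np.ndarray, ref_col: int, obs_col: int,
              logratio_trim: float = 0.3, abs_trim: float = 0.05) -> float:
    """Straight-line trimmed weighted-mean-of-M-values factor for one pair."""
    lib = counts.sum(axis=0).astype(float)
    o_all = counts[:, obs_col].astype(float)
    r_all = counts[:, ref_col].astype(float)
    m_list, a_list, w_list = [], [], []
    for o, r in zip(o_all, r_all):
        if o > 0 and r > 0:
            m_list.append(np.log2((o / lib[obs_col]) / (r / lib[ref_col])))
            a_list.append(0.5 * np.log2((o / lib[obs_col]) * (r / lib[ref_col])))
            w_list.append((lib[obs_col] - o) / (lib[obs_col] * o)
                          + (lib[ref_col] - r) / (lib[ref_col] * r))
    m = np.array(m_list)
    a = np.array(a_list)
    w = np.array(w_list)
    if len(m) == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
    lo_a, hi_a = np.floor(n * abs_trim) + 1, n - np.floor(n * abs_trim)
    # average ranks for ties, 1-based
    def ranks(x):
        order = np.argsort(x, kind="stable")
        rk = np.empty(len(x))
        i = 0
        sx = x[order]
        while i < len(x):
            j = i
            while j + 1 < len(x) and sx[j + 1] == sx[i]:
                j += 1
            rk[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return rk
    rm, ra = ranks(m), ranks(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    return float(2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])))


def anova_ss_naive(values: np.ndarray, groups: np.ndarray):
    """Direct sum-of-squares decomposition; returns (F, df_b, df_w)."""
    labels = list(dict.fromkeys(groups))
    grand = np.mean(values)
    ssb = ssw = 0.0
    for g in labels:
        v = values[np.asarray(groups) == g]
        ssb += len(v) * (np.mean(v) - grand) ** 2
        for x in v:
            ssw += (x - np.mean(v)) ** 2
    df_b, df_w = len(labels) - 1, len(values) - len(labels)
    return (ssb / df_b) / (ssw / df_w), df_b, df_w


def leading_logfc_naive(mat: np.ndarray, top: int) -> np.ndarray:
    """Per-pair sort-and-average distance."""
    n = mat.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            sq = sorted((mat[:, i] - mat[:, j]) ** 2, reverse=True)[:top]
            d[i, j] = np.sqrt(np.mean(sq))
    return d


def poisson_deviance_pvalue(y_a: np.ndarray, y_b: np.ndarray,
                            lib_a: np.ndarray, lib_b: np.ndarray) -> float:
    """Two-group Poisson LRT (deviance) p-value with library-size offsets."""
    from scipy.stats import chi2

    def ll(y, mu):
        mu = np.maximum(mu, 1e-300)
        return float(np.sum(y * np.log(mu) - mu))

    rate_a = y_a.sum() / lib_a.sum()
    rate_b = y_b.sum() / lib_b.sum()
    rate_0 = (y_a.sum() + y_b.sum()) / (lib_a.sum() + lib_b.sum())
    dev = 2 * (ll(y_a, rate_a * lib_a) + ll(y_b, rate_b * lib_b)
               - ll(y_a, rate_0 * lib_a) - ll(y_b, rate_0 * lib_b))
    return float(chi2.sf(max(dev, 0.0), 1))
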