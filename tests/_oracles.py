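"""Naive, independently-written reference computations used only in tests."""

import itertools

import numpy as np
import scipy.stats as st


def permanova_oneway_F(d: np.ndarray, labels) -> float:
    """Double-loop one-way pseudo-F from raw pairwise distances."""
    labels = np.asarray(labels)
    n = len(labels)
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d[i, j] ** 2
    ss_total /= n
    ss_within = 0.0
    levels = np.unique(labels)
    for lev in levels:
        idx = np.where(labels == lev)[0]
        acc = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                acc += d[idx[a], idx[b]] ** 2
        ss_within += acc / len(idx)
    ss_between = ss_total - ss_within
    df_a = len(levels) - 1
    df_w = n - len(levels)
    return (ss_between / df_a) / (ss_within / df_w)


def permanova_exhaustive_p(d: np.ndarray, labels) -> float:
    """Exact permutation p over all n! relabelings (identity included)."""
    f_obs = permanova_oneway_F(d, labels)
    labels = np.asarray(labels)
    n = len(labels)
    hits = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        f = permanova_oneway_F(d, labels[np.asarray(perm)])
        hits += f >= f_obs * (1 - 1e-9)
        total += 1
    return hits / total


def mantel_exhaustive(d1: np.ndarray, d2: np.ndarray) -> tuple[float, float]:
    """Brute-force one-sided exhaustive Spearman Mantel."""
    n = d1.shape[0]
    tri = np.tril_indices(n, k=-1)
    r_obs = st.spearmanr(d1[tri], d2[tri]).statistic
    hits = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        idx = np.asarray(perm)
        r = st.spearmanr(d1[tri], d2[np.ix_(idx, idx)][tri]).statistic
        hits += r >= r_obs - 1e-12
        total += 1
    return float(r_obs), hits / total


def regression_r2(y: np.ndarray, x: np.ndarray) -> float:
    """Share of total (column-centered) variance explained by one predictor."""
    yc = y - y.mean(axis=0)
    xc = x - x.mean()
    beta = yc.T @ xc / (xc @ xc)
    fitted = np.outer(xc, beta)
    return float((fitted**2).sum() / (yc**2).sum())
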