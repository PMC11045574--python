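"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written along a different computational
path from the package: pairwise cross-tables instead of matrix products,
step-indicator probabilities instead of value covariances, explicit loops
instead of vectorized code.
"""

from __future__ import annotations

import itertools

import numpy as np


def crosstab(x: np.ndarray, y: np.ndarray, levels: int) -> np.ndarray:
    """levels x levels joint count table."""
    t = np.zeros((levels, levels), dtype=np.int64)
    for a, b in zip(x, y):
        t[a, b] += 1
    return t


def cov_from_table(table: np.ndarray) -> float:
    """Divide-by-n covariance read off a joint count table."""
    n = table.sum()
    levels = table.shape[0]
    exy = sum(
        table[a, b] * a * b for a in range(levels) for b in range(levels)
    ) / n
    ex = sum(table[a, :].sum() * a for a in range(levels)) / n
    ey = sum(table[:, b].sum() * b for b in range(levels)) / n
    return exy - ex * ey


def maxcov_from_margins(margin_x: np.ndarray, margin_y: np.ndarray) -> float:
    """Comonotone-coupling covariance computed from a greedy table fill.

    Fill the joint table by pairing the highest remaining levels of both
    margins first (the top-left-to-bottom-right staircase), then read the
    covariance off that table.
    """
    mx = list(margin_x)
    my = list(margin_y)
    levels = len(mx)
    table = np.zeros((levels, levels), dtype=np.int64)
    a, b = 0, 0
    while a < levels and b < levels:
        if mx[a] == 0:
            a += 1
            continue
        if my[b] == 0:
            b += 1
            continue
        k = min(mx[a], my[b])
        table[a, b] += k
        mx[a] -= k
        my[b] -= k
    return cov_from_table(table)


def brute_force_H(values: np.ndarray, levels: int):
    """(H_pair, H_item, H_scale) from explicit pairwise cross-tables."""
    n, j = values.shape
    cov = np.zeros((j, j))
    mc = np.zeros((j, j))
    for a in range(j):
        for b in range(j):
            if a == b:
                continue
            t = crosstab(values[:, a], values[:, b], levels)
            cov[a, b] = cov_from_table(t)
            mc[a, b] = maxcov_from_margins(t.sum(axis=1), t.sum(axis=0))
    h_pair = np.full((j, j), np.nan)
    h_item = np.zeros(j)
    for a in range(j):
        for b in range(j):
            if a != b:
                h_pair[a, b] = cov[a, b] / mc[a, b]
        h_item[a] = cov[a].sum() / mc[a].sum()
    h_scale = cov.sum() / mc.sum()
    return h_pair, h_item, h_scale


def guttman_error_H_pair(x: np.ndarray, y: np.ndarray, levels: int) -> float:
    """H_ij as 1 - (weighted Guttman errors)/(expected errors), via step
    indicator probabilities: an entirely covariance-free formulation."""
    n = len(x)
    m = levels - 1
    p_joint = np.zeros((m, m))
    p_x = np.zeros(m)
    p_y = np.zeros(m)
    for s in range(1, m + 1):
        p_x[s - 1] = np.mean(x >= s)
        p_y[s - 1] = np.mean(y >= s)
        for t in range(1, m + 1):
            p_joint[s - 1, t - 1] = np.mean((x >= s) & (y >= t))
    errors = 0.0
    expected = 0.0
    for s in range(m):
        for t in range(m):
            top = min(p_x[s], p_y[t])
            errors += top - p_joint[s, t]
            expected += top - p_x[s] * p_y[t]
    return 1.0 - errors / expected


def max_cov_by_enumeration(sample_x: np.ndarray, sample_y: np.ndarray) -> float:
    """Maximum covariance over every pairing of two small samples."""
    n = len(sample_x)
    best = -np.inf
    for perm in itertools.permutations(range(n)):
        paired = sample_y[list(perm)]
        c = np.mean(sample_x * paired) - sample_x.mean() * paired.mean()
        best = max(best, c)
    return best


def alpha_direct(columns: list[np.ndarray]) -> float:
    """Cronbach's alpha from scratch with plain Python sums."""
    j = len(columns)
    total = sum(columns)
    var = lambda v: float(np.sum((v - np.mean(v)) ** 2) / (len(v) - 1))
    return j / (j - 1) * (1.0 - sum(var(c) for c in columns) / var(total))


def lambda2_direct(columns: list[np.ndarray]) -> float:
    """Guttman's lambda-2 from scratch."""
    j = len(columns)
    total = sum(columns)
    n = len(total)
    var_total = float(np.sum((total - np.mean(total)) ** 2) / (n - 1))
    c_sum = 0.0
    c_sq = 0.0
    for a in range(j):
        for b in range(j):
            if a == b:
                continue
            ca = columns[a] - np.mean(columns[a])
            cb = columns[b] - np.mean(columns[b])
            cab = float(np.sum(ca * cb) / (n - 1))
            c_sum += cab
            c_sq += cab**2
    return (c_sum + np.sqrt(j / (j - 1) * c_sq)) / var_total


def u_statistic_by_pairs(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of group a by direct pair counting with ties = 1/2."""
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else (0.5 if x == y else 0.0)
    return u


def spearman_direct(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho as the Pearson correlation of mid-ranks."""

    def midranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            k = i
            while k + 1 < len(v) and sv[k + 1] == sv[i]:
                k += 1
            ranks[order[i : k + 1]] = (i + k) / 2.0 + 1.0
            i = k + 1
        return ranks

    rx, ry = midranks(np.asarray(x)), midranks(np.asarray(y))
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))
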