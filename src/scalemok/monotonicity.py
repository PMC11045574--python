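"""Manifest monotonicity checks over rest-score groups.

For each item, respondents are partitioned into ordered groups by their
rest score (scale total minus the item itself).  The item step response
functions P(X >= x | group) must not decrease as the rest score increases;
decreases larger than `minvi` are counted as violations, and each violation
is additionally tested for significance with a one-sided pooled
two-proportion z-test.

The `crit` diagnostic aggregates an item's scalability shortfall and its
violation count, magnitudes and significance counts into one misfit score.
The definition used here (see :func:`crit_value`) guarantees crit = 0
exactly when there are no violations and increases monotonically in every
ingredient; its numeric scale is this package's own and is not comparable
across software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ResponseMatrix, ScaleDefinition, complete_cases
from .errors import ConfigurationError
from .scalability import compute_H

__all__ = [
    "RestScoreGrouping",
    "IsrfEstimate",
    "MonotonicityResult",
    "default_minsize",
    "group_rest_scores",
    "make_restscore_groups",
    "check_monotonicity",
    "irf_table",
    "crit_value",
]


def default_minsize(n: int) -> int:
    """Minimum rest-score group size ladder, as in standard Mokken practice.

    N/10 for N >= 500, N/5 for 250 <= N < 500, else max(N/3, 50).
    """
    if n >= 500:
        return n // 10
    if n >= 250:
        return n // 5
    return max(n // 3, 50)


@dataclass
class RestScoreGrouping:
    """Ordered partition of respondents into contiguous rest-score bins."""

    group_edges: list[tuple[int, int]]  # inclusive (lo, hi) rest-score bounds
    group_index: np.ndarray  # per-respondent group id, 0-based
    group_sizes: np.ndarray
    rest_scores: np.ndarray

    @property
    def n_groups(self) -> int:
        return len(self.group_edges)


def group_rest_scores(rest_scores: np.ndarray, minsize: int) -> RestScoreGrouping:
    """Merge adjacent raw rest-score values from the low end until every
    group holds at least `minsize` respondents; a trailing undersized group
    merges into its left neighbour."""
    if minsize < 1:
        raise ConfigurationError("minsize must be >= 1")
    rest_scores = np.asarray(rest_scores)
    values, counts = np.unique(rest_scores, return_counts=True)

    edges: list[tuple[int, int]] = []
    start = 0
    acc = 0
    for k, c in enumerate(counts):
        acc += c
        if acc >= minsize:
            edges.append((int(values[start]), int(values[k])))
            start = k + 1
            acc = 0
    if acc > 0:  # trailing remainder
        if edges:
            lo, _ = edges[-1]
            edges[-1] = (lo, int(values[-1]))
        else:
            edges.append((int(values[0]), int(values[-1])))

    boundaries = np.array([hi for _, hi in edges])
    group_index = np.searchsorted(boundaries, rest_scores, side="left")
    group_sizes = np.bincount(group_index, minlength=len(edges))
    return RestScoreGrouping(edges, group_index, group_sizes, rest_scores)


def make_restscore_groups(
    matrix: ResponseMatrix,
    item: str,
    minsize: int,
    scale: ScaleDefinition | None = None,
) -> RestScoreGrouping:
    """Rest-score groups for one item (the item excluded from its own rest).

    With N < 2 * minsize the merging rule forces a single group, which
    yields zero active comparisons downstream.
    """
    if scale is None:
        scale = ScaleDefinition("all", list(matrix.item_ids))
    data = complete_cases(matrix, scale)
    jj = data.item_index(item)
    rest = data.values.sum(axis=1) - data.values[:, jj]
    return group_rest_scores(rest, minsize)


@dataclass
class IsrfEstimate:
    """Estimated ISRFs P(X >= x | group) per item over its rest-score groups."""

    item_ids: list[str]
    probs: dict[str, np.ndarray]  # item -> (m, n_groups) cumulative probabilities
    groupings: dict[str, RestScoreGrouping]

    def irf(self, item_id: str) -> np.ndarray:
        """Expected-score curve: IRF(g) = sum over steps of P(X >= x | g)."""
        return self.probs[item_id].sum(axis=0)


@dataclass
class MonotonicityResult:
    """Per-item violation diagnostics (ac, vi, maxvi, sum_vi, zsig, crit)."""

    item_ids: list[str]
    ac: np.ndarray
    vi: np.ndarray
    maxvi: np.ndarray
    sum_vi: np.ndarray
    zsig: np.ndarray
    crit: np.ndarray
    h_item: np.ndarray
    minvi: float
    minsize: int
    violations: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item": self.item_ids,
                "ac": self.ac,
                "vi": self.vi,
                "maxvi": self.maxvi,
                "sum_vi": self.sum_vi,
                "zsig": self.zsig,
                "crit": self.crit,
            }
        )

    @property
    def total_violations(self) -> int:
        return int(self.vi.sum())


def crit_value(
    h_item: float,
    ac: int,
    vi: int,
    maxvi: float,
    sum_vi: float,
    zsig: int,
    h_bound: float = 0.3,
) -> float:
    """Composite misfit diagnostic.

    Zero when there are no violations; otherwise a weighted sum of the
    item's scalability shortfall below `h_bound`, the violation rate, count,
    magnitudes and number of significant violations.  Monotone
    non-decreasing in each ingredient.
    """
    if vi == 0:
        return 0.0
    return float(
        50.0 * max(0.0, h_bound - h_item)
        + np.sqrt(vi)
        + 100.0 * vi / ac
        + 100.0 * maxvi
        + 100.0 * sum_vi
        + 10.0 * np.sqrt(zsig)
    )


def _two_proportion_z(p_low: float, p_high: float, n_low: int, n_high: int) -> float:
    """One-sided z for a decrease p_high < p_low, pooled variance."""
    pooled = (p_low * n_low + p_high * n_high) / (n_low + n_high)
    var = pooled * (1.0 - pooled) * (1.0 / n_low + 1.0 / n_high)
    if var <= 0:
        return 0.0
    return (p_low - p_high) / np.sqrt(var)


def check_monotonicity(
    matrix: ResponseMatrix,
    scale: ScaleDefinition | None = None,
    minvi: float = 0.03,
    minsize: int | None = None,
    alpha: float = 0.05,
    adjacent_only: bool = False,
) -> tuple[MonotonicityResult, IsrfEstimate]:
    """Count manifest monotonicity violations of every item in the scale.

    Each item's rest score excludes the item itself.  By default every
    ordered group pair (g < h) is compared, the stricter reading of
    non-decrease over increasing rest score; ``adjacent_only=True``
    restricts to consecutive groups.
    """
    if scale is None:
        scale = ScaleDefinition("all", list(matrix.item_ids))
    data = complete_cases(matrix, scale)
    v = data.values
    n, j = v.shape
    m = data.max_level
    if minsize is None:
        minsize = default_minsize(n)
    zcrit = stats.norm.ppf(1.0 - alpha)

    h = compute_H(data, bootstrap_reps=0)
    totals = v.sum(axis=1)

    ac = np.zeros(j, dtype=np.int64)
    vi = np.zeros(j, dtype=np.int64)
    maxvi = np.zeros(j)
    sum_vi = np.zeros(j)
    zsig = np.zeros(j, dtype=np.int64)
    probs: dict[str, np.ndarray] = {}
    groupings: dict[str, RestScoreGrouping] = {}
    violations: list[dict] = []

    for jj, item in enumerate(data.item_ids):
        rest = totals - v[:, jj]
        grouping = group_rest_scores(rest, minsize)
        g = grouping.n_groups
        # (m, g) matrix of P(X >= x | group); x runs over internal steps 1..m
        p = np.empty((m, g))
        sizes = grouping.group_sizes
        for gi in range(g):
            in_g = grouping.group_index == gi
            xg = v[in_g, jj]
            for x in range(1, m + 1):
                p[x - 1, gi] = np.mean(xg >= x)
        probs[item] = p
        groupings[item] = grouping

        if g < 2:
            continue  # ac = vi = 0: nothing comparable
        pair_list = (
            [(a, a + 1) for a in range(g - 1)]
            if adjacent_only
            else [(a, b) for a in range(g - 1) for b in range(a + 1, g)]
        )
        for x in range(m):
            for a, b in pair_list:
                ac[jj] += 1
                drop = p[x, a] - p[x, b]
                if drop > minvi:
                    vi[jj] += 1
                    sum_vi[jj] += drop
                    maxvi[jj] = max(maxvi[jj], drop)
                    z = _two_proportion_z(p[x, a], p[x, b], sizes[a], sizes[b])
                    if z > zcrit:
                        zsig[jj] += 1
                    violations.append(
                        {
                            "item": item,
                            "step": x + 1,
                            "group_low": a,
                            "group_high": b,
                            "magnitude": float(drop),
                            "z": float(z),
                        }
                    )

    crit = np.array(
        [
            crit_value(h.H_item[k], int(ac[k]), int(vi[k]), maxvi[k], sum_vi[k], int(zsig[k]))
            for k in range(j)
        ]
    )
    result = MonotonicityResult(
        item_ids=list(data.item_ids),
        ac=ac,
        vi=vi,
        maxvi=maxvi,
        sum_vi=sum_vi,
        zsig=zsig,
        crit=crit,
        h_item=h.H_item,
        minvi=minvi,
        minsize=minsize,
        violations=violations,
    )
    return result, IsrfEstimate(list(data.item_ids), probs, groupings)


def irf_table(isrf: IsrfEstimate) -> pd.DataFrame:
    """Per-item expected-score curves over rest-score groups (long format).

    IRF(g) = sum over steps of P(X >= x | g); values lie in [0, m].
    """
    rows = []
    for item in isrf.item_ids:
        curve = isrf.irf(item)
        grouping = isrf.groupings[item]
        for gi, (edge, value) in enumerate(zip(grouping.group_edges, curve)):
            rows.append(
                {
                    "item": item,
                    "group": gi,
                    "rest_lo": edge[0],
                    "rest_hi": edge[1],
                    "n": int(grouping.group_sizes[gi]),
                    "irf": float(value),
                }
            )
    return pd.DataFrame(rows)
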