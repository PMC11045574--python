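"""Manifest invariant item ordering (MIIO) and the H^T ordering coefficient.

If items keep the same difficulty order at every level of the latent trait,
the ordering of their conditional mean scores must not reverse across
rest-score groups.  Items are ordered by overall mean; for each pair the
rest score excludes both items, and a reversal larger than
``(levels - 1) * 0.03`` (the per-step reporting floor times the number of
item steps) counts as a violation.  Backward selection removes the worst
item until no violations remain.

H^T applies the Loevinger H machinery to the transposed data matrix —
respondents play the role of items — and measures how consistently the
sample orders the items.  Respondents with constant responses carry no
ordering information and are excluded (counted, not an error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ResponseMatrix, ScaleDefinition, complete_cases
from .errors import DegenerateItemError, ScalemokError
from .monotonicity import crit_value, default_minsize, group_rest_scores
from .scalability import classify_H, compute_H

__all__ = ["IIOResult", "HTResult", "check_miio", "compute_HT", "classify_HT"]


@dataclass
class HTResult:
    """H computed on the transposed matrix, with its ordering-accuracy label."""

    value: float
    label: str
    n_respondents_used: int
    n_constant_excluded: int

    def __float__(self) -> float:
        return self.value


def classify_HT(ht: float) -> str:
    """Ordering-accuracy label for H^T.

    Below 0.3 items cannot be ordered; [0.3, 0.4) low accuracy; [0.4, 0.5]
    accurate; above 0.5 highly accurate.
    """
    if ht > 0.5:
        return "highly accurate"
    if ht >= 0.4:
        return "accurate"
    if ht >= 0.3:
        return "low"
    return "cannot be ordered"


def compute_HT(matrix: ResponseMatrix, scale: ScaleDefinition | None = None) -> HTResult:
    """Loevinger H of the transposed data (respondents as items).

    Uses the same divide-by-n covariance and comonotone max-covariance as
    :func:`scalemok.scalability.compute_H`, but evaluated over respondent
    pairs with the J items as observations.  Only the aggregate sums are
    needed, so the N x N matrices are never materialized.
    """
    if scale is None:
        scale = ScaleDefinition("all", list(matrix.item_ids))
    data = complete_cases(matrix, scale)
    v = data.values.astype(np.float64)
    n, j = v.shape
    if j < 3:
        raise ScalemokError("H^T needs at least 3 items")

    keep = v.std(axis=1) > 0
    n_excluded = int(n - keep.sum())
    v = v[keep]
    n_used = v.shape[0]
    if n_used < 2:
        raise DegenerateItemError(
            "fewer than 2 respondents with non-constant responses; H^T undefined"
        )

    # transposed matrix W: rows = items (observations), cols = respondents
    w = v.T
    means = w.mean(axis=0)  # per-respondent mean over items
    wc = w - means
    # sum over all respondent pairs (p, q) of cov_pq, via row sums
    total_cov = np.sum(wc.sum(axis=1) ** 2) / j
    trace = np.sum(wc**2) / j  # per-respondent variances
    off_cov = (total_cov - trace) / 2.0

    s = np.sort(w, axis=0)  # each respondent's responses sorted: comonotone
    total_max = np.sum(s.sum(axis=1) ** 2) / j - means.sum() ** 2
    off_max = (total_max - trace) / 2.0
    if off_max <= 0:
        raise DegenerateItemError("non-positive max-covariance sum; H^T undefined")
    ht = float(off_cov / off_max)
    return HTResult(ht, classify_HT(ht), n_used, n_excluded)


@dataclass
class IIOResult:
    """MIIO diagnostics: pair reversals, per-item counts, backward selection."""

    item_ids: list[str]  # analysis order (ascending overall mean)
    item_order: list[str]
    overall_means: np.ndarray
    ac: np.ndarray
    vi: np.ndarray
    maxvi: np.ndarray
    sum_vi: np.ndarray
    zsig: np.ndarray
    crit: np.ndarray
    pair_violations: dict[tuple[str, str], int]
    removed_items: list[str]
    HT: HTResult | None
    minvi_pair: float
    minsize: int
    tied_means: bool = False
    violations: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item": self.item_ids,
                "mean": self.overall_means,
                "ac": self.ac,
                "vi": self.vi,
                "maxvi": self.maxvi,
                "zsig": self.zsig,
                "crit": self.crit,
            }
        )

    @property
    def total_violations(self) -> int:
        return int(sum(self.pair_violations.values()))


def _pair_scan(
    v: np.ndarray,
    item_ids: list[str],
    order: np.ndarray,
    minsize: int,
    minvi_pair: float,
    alpha: float,
):
    """Violation scan over all ordered item pairs on values `v` (complete).

    Returns per-item tallies (in original column order) and the pair table.
    `order` lists column indices by ascending overall mean.
    """
    n, j = v.shape
    totals = v.sum(axis=1)
    tcrit = stats.norm.ppf(1.0 - alpha)

    ac = np.zeros(j, dtype=np.int64)
    vi = np.zeros(j, dtype=np.int64)
    maxvi = np.zeros(j)
    sum_vi = np.zeros(j)
    zsig = np.zeros(j, dtype=np.int64)
    pair_counts: dict[tuple[str, str], int] = {}
    detail: list[dict] = []

    for a_pos in range(j - 1):
        for b_pos in range(a_pos + 1, j):
            i, k = order[a_pos], order[b_pos]  # mean_i <= mean_k
            rest = totals - v[:, i] - v[:, k]
            grouping = group_rest_scores(rest, minsize)
            key = (item_ids[i], item_ids[k])
            pair_counts.setdefault(key, 0)
            for g in range(grouping.n_groups):
                in_g = grouping.group_index == g
                ac[i] += 1
                ac[k] += 1
                d = v[in_g, i] - v[in_g, k]
                diff = float(d.mean())  # E[X_i|g] - E[X_k|g], expected <= 0
                if diff > minvi_pair:
                    vi[i] += 1
                    vi[k] += 1
                    pair_counts[key] += 1
                    sum_vi[i] += diff
                    sum_vi[k] += diff
                    maxvi[i] = max(maxvi[i], diff)
                    maxvi[k] = max(maxvi[k], diff)
                    # paired one-sided test of the reversal within the group
                    sd = d.std(ddof=1)
                    z = diff / (sd / np.sqrt(d.size)) if sd > 0 and d.size > 1 else np.inf
                    if z > tcrit:
                        zsig[i] += 1
                        zsig[k] += 1
                    detail.append(
                        {
                            "item_low": item_ids[i],
                            "item_high": item_ids[k],
                            "group": g,
                            "magnitude": diff,
                            "z": float(z),
                        }
                    )
    return ac, vi, maxvi, sum_vi, zsig, pair_counts, detail


def check_miio(
    matrix: ResponseMatrix,
    scale: ScaleDefinition | None = None,
    minsize: int | None = None,
    minvi_pair: float | None = None,
    alpha: float = 0.05,
    compute_ht: bool = True,
) -> IIOResult:
    """Check manifest invariant item ordering with backward item selection.

    The reversal threshold defaults to ``(levels - 1) * 0.03``: the
    per-comparison floor 0.03 scaled by the number of ISRFs per item (0.12
    for five-level items).  Backward selection removes the item with the
    most violations (ties: larger crit, then lower column index) and
    rescans until the surviving set is violation-free.
    """
    if scale is None:
        scale = ScaleDefinition("all", list(matrix.item_ids))
    data = complete_cases(matrix, scale)
    v = data.values
    n, j = v.shape
    if minsize is None:
        minsize = default_minsize(n)
    if minvi_pair is None:
        minvi_pair = data.max_level * 0.03

    means = v.mean(axis=0)
    tied = bool(np.unique(means).size < j)
    order = np.lexsort((np.arange(j), means))  # ascending mean, ties by index

    ac, vi, maxvi, sum_vi, zsig, pair_counts, detail = _pair_scan(
        v, data.item_ids, order, minsize, minvi_pair, alpha
    )
    h = compute_H(data, bootstrap_reps=0)
    crit = np.array(
        [
            crit_value(h.H_item[k], int(ac[k]), int(vi[k]), maxvi[k], sum_vi[k], int(zsig[k]))
            if ac[k] > 0
            else 0.0
            for k in range(j)
        ]
    )

    # backward selection on a working copy of the item set
    removed: list[str] = []
    cols = list(range(j))
    cur_vi, cur_crit = vi.copy(), crit.copy()
    while len(cols) > 2 and cur_vi[cols].sum() > 0:
        worst = max(cols, key=lambda c: (cur_vi[c], cur_crit[c], -c))
        removed.append(data.item_ids[worst])
        cols.remove(worst)
        sub = v[:, cols]
        sub_means = sub.mean(axis=0)
        sub_order = np.lexsort((np.arange(len(cols)), sub_means))
        s_ac, s_vi, s_maxvi, s_sumvi, s_zsig, _, _ = _pair_scan(
            sub,
            [data.item_ids[c] for c in cols],
            sub_order,
            minsize,
            minvi_pair,
            alpha,
        )
        sub_h = compute_H(data.select_items([data.item_ids[c] for c in cols]), bootstrap_reps=0)
        cur_vi = np.zeros(j, dtype=np.int64)
        cur_crit = np.zeros(j)
        for pos, c in enumerate(cols):
            cur_vi[c] = s_vi[pos]
            cur_crit[c] = crit_value(
                sub_h.H_item[pos],
                int(s_ac[pos]),
                int(s_vi[pos]),
                s_maxvi[pos],
                s_sumvi[pos],
                int(s_zsig[pos]),
            ) if s_ac[pos] > 0 else 0.0

    ht = compute_HT(data) if compute_ht and j >= 3 else None
    return IIOResult(
        item_ids=list(data.item_ids),
        item_order=[data.item_ids[k] for k in order],
        overall_means=means,
        ac=ac,
        vi=vi,
        maxvi=maxvi,
        sum_vi=sum_vi,
        zsig=zsig,
        crit=crit,
        pair_violations=pair_counts,
        removed_items=removed,
        HT=ht,
        minvi_pair=minvi_pair,
        minsize=minsize,
        tied_means=tied,
        violations=detail,
    )
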