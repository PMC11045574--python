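"""Automated item selection procedure (AISP) for Mokken scales.

Greedy bottom-up partitioning of items into scales at a scalability lower
bound c: start from the strongest admissible item pair, grow the scale one
item at a time, close it when no item qualifies, and restart on the
remainder.  Items never placed are labelled 0 (unscalable).

An item may join only if (a) its pairwise H with every current member is
significantly positive, and (b) after joining, every member's within-scale
H_item is at least c.  Condition (b) is stricter than checking the entrant
alone; it makes the partition validity invariant (all within-scale H_item
>= c) hold by construction rather than by luck of the greedy path.

Significance of H_ij > 0 uses a one-sided z-test with a seeded bootstrap
standard error; pair statistics are computed once and shared across the
lower-bound sweep and the split-threshold search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ResponseMatrix, ScaleDefinition, complete_cases
from .errors import ConfigurationError
from .scalability import pairwise_cov_maxcov

__all__ = [
    "AispPartition",
    "PairStats",
    "prepare_pair_stats",
    "run_aisp",
    "sweep_lower_bounds",
    "find_split_threshold",
]


@dataclass
class AispPartition:
    """Per-item scale assignment at one lower bound.

    Labels: 0 = unscalable, 1 = first scale, 2 = second scale, ...
    """

    lower_bound: float
    item_ids: list[str]
    assignment: np.ndarray

    @property
    def n_scales(self) -> int:
        return int(self.assignment.max(initial=0))

    def scale_members(self, label: int) -> list[str]:
        return [i for i, a in zip(self.item_ids, self.assignment) if a == label]


@dataclass
class PairStats:
    """Pairwise covariance machinery shared by AISP runs on one dataset."""

    item_ids: list[str]
    cov: np.ndarray
    maxcov: np.ndarray
    h_pair: np.ndarray
    se_pair: np.ndarray
    n: int
    bootstrap_reps: int
    seed: int | None

    def h_item_within(self, members: list[int]) -> np.ndarray:
        """Within-subset H_item for each member of `members`."""
        idx = np.asarray(members)
        c = self.cov[np.ix_(idx, idx)]
        m = self.maxcov[np.ix_(idx, idx)]
        off = ~np.eye(idx.size, dtype=bool)
        return np.where(off, c, 0.0).sum(1) / np.where(off, m, 0.0).sum(1)

    def h_scale_within(self, members: list[int]) -> float:
        idx = np.asarray(members)
        c = self.cov[np.ix_(idx, idx)]
        m = self.maxcov[np.ix_(idx, idx)]
        off = ~np.eye(idx.size, dtype=bool)
        return float(c[off].sum() / m[off].sum())


def prepare_pair_stats(
    matrix: ResponseMatrix,
    scale: ScaleDefinition | None = None,
    bootstrap_reps: int = 200,
    seed: int | None = 0,
) -> PairStats:
    """Compute covariance, max-covariance and bootstrap SEs for all pairs."""
    if scale is None:
        scale = ScaleDefinition("all", list(matrix.item_ids))
    data = complete_cases(matrix, scale)
    v = data.values.astype(np.float64)
    n, j = v.shape
    cov, maxcov = pairwise_cov_maxcov(v)
    off = ~np.eye(j, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_pair = np.where(off, cov / maxcov, np.nan)

    rng = np.random.default_rng(seed)
    boot = np.empty((bootstrap_reps, j, j))
    for b in range(bootstrap_reps):
        idx = rng.integers(0, n, n)
        bc, bm = pairwise_cov_maxcov(v[idx])
        with np.errstate(divide="ignore", invalid="ignore"):
            boot[b] = np.where(off, bc / bm, np.nan)
    se_pair = boot.std(axis=0, ddof=1)
    return PairStats(
        item_ids=list(data.item_ids),
        cov=cov,
        maxcov=maxcov,
        h_pair=h_pair,
        se_pair=se_pair,
        n=n,
        bootstrap_reps=bootstrap_reps,
        seed=seed,
    )


def _greedy_partition(ps: PairStats, lower_bound: float, alpha: float) -> np.ndarray:
    j = len(ps.item_ids)
    zcrit = stats.norm.ppf(1.0 - alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        zscore = ps.h_pair / ps.se_pair
    significant = (ps.h_pair > 0) & (zscore > zcrit)

    assignment = np.zeros(j, dtype=np.int64)
    label = 0
    while True:
        free = np.flatnonzero(assignment == 0)
        # admissible starting pair: largest significant H_pair >= c,
        # ties broken by lower (i, j) index order
        best_pair = None
        best_h = -np.inf
        for a_pos, a in enumerate(free):
            for b in free[a_pos + 1 :]:
                h = ps.h_pair[a, b]
                if np.isnan(h) or not significant[a, b] or h < lower_bound:
                    continue
                if h > best_h:
                    best_h = h
                    best_pair = (a, b)
        if best_pair is None:
            break
        label += 1
        members = list(best_pair)
        while True:
            candidates = []
            for k in np.flatnonzero(assignment == 0):
                if k in members:
                    continue
                if not all(significant[k, m] for m in members):
                    continue
                trial = members + [k]
                if np.any(ps.h_item_within(trial) < lower_bound):
                    continue
                candidates.append((ps.h_scale_within(trial), -k))
            if not candidates:
                break
            _, neg_k = max(candidates)
            members.append(-neg_k)
        assignment[members] = label
        # a "scale" needs >= 2 items; the starting pair guarantees that
    return assignment


def run_aisp(
    matrix: ResponseMatrix,
    lower_bound: float,
    alpha: float = 0.05,
    bootstrap_reps: int = 200,
    seed: int | None = 0,
    pair_stats: PairStats | None = None,
) -> AispPartition:
    """Partition items into Mokken scales at one lower bound.

    If no admissible starting pair exists all items are labelled 0 — that
    is a valid outcome, not an error.
    """
    if not (0.0 < lower_bound < 1.0):
        raise ConfigurationError("lower_bound must lie in (0, 1)")
    ps = pair_stats or prepare_pair_stats(
        matrix, bootstrap_reps=bootstrap_reps, seed=seed
    )
    assignment = _greedy_partition(ps, lower_bound, alpha)
    return AispPartition(lower_bound, list(ps.item_ids), assignment)


def sweep_lower_bounds(
    matrix: ResponseMatrix,
    bounds,
    alpha: float = 0.05,
    bootstrap_reps: int = 200,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Run AISP at each lower bound; items x bounds assignment table."""
    bounds = list(bounds)
    if not bounds:
        raise ConfigurationError("bounds list is empty")
    arr = np.asarray(bounds, dtype=float)
    if np.any(arr <= 0) or np.any(arr >= 1) or np.any(np.diff(arr) <= 0):
        raise ConfigurationError("bounds must be strictly increasing within (0, 1)")
    ps = prepare_pair_stats(matrix, bootstrap_reps=bootstrap_reps, seed=seed)
    table = {
        f"{c:.3g}": run_aisp(matrix, c, alpha=alpha, pair_stats=ps).assignment
        for c in bounds
    }
    return pd.DataFrame(table, index=ps.item_ids)


def find_split_threshold(
    matrix: ResponseMatrix,
    step: float = 0.001,
    alpha: float = 0.05,
    bootstrap_reps: int = 200,
    seed: int | None = 0,
    pair_stats: PairStats | None = None,
) -> float | None:
    """Smallest grid bound at which one scale is no longer appropriate.

    Scans c = step, 2*step, ... and returns the first grid value where AISP
    yields more than one scale or leaves any item unscalable.  Returns
    ``None`` (the no-split sentinel) only if a single all-item scale
    survives the entire grid below 1, i.e. perfectly Guttman-like data.
    """
    if step <= 0:
        raise ConfigurationError("step must be positive")
    ps = pair_stats or prepare_pair_stats(
        matrix, bootstrap_reps=bootstrap_reps, seed=seed
    )
    n_grid = int(np.ceil(1.0 / step)) - 1
    for k in range(1, n_grid + 1):
        c = k * step
        if c >= 1.0:
            break
        part = run_aisp(matrix, c, alpha=alpha, pair_stats=ps)
        if part.n_scales > 1 or np.any(part.assignment == 0):
            return float(round(c, 12))
    return None
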