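"""Loevinger scalability coefficients H for polytomous Mokken scales.

H norms the observed inter-item covariance by its maximum attainable value
given the item margins.  The maximum is realized by the comonotone coupling:
sort both items' observed values and pair them rank for rank.  All
covariances here use the divide-by-n (biased) convention so that numerator
and denominator conventions cancel exactly in every ratio.

Three aggregation levels share one ratio-of-sums form:

* item pair:  H_ij = cov(X_i, X_j) / maxcov(X_i, X_j)
* item:       H_i  = sum_{j != i} cov_ij / sum_{j != i} maxcov_ij,
              which equals the covariance of item i with its rest score
              normed by that covariance's maximum
* scale:      H_S  = sum_{i<j} cov_ij / sum_{i<j} maxcov_ij,
              the maxcov-weighted mean of the H_i
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ResponseMatrix, ScaleDefinition, complete_cases
from .errors import DegenerateItemError, ScalemokError

__all__ = [
    "ScalabilityResult",
    "max_covariance",
    "compute_H",
    "classify_H",
    "pairwise_cov_maxcov",
]


def max_covariance(margin_i: np.ndarray, margin_j: np.ndarray, n: int) -> float:
    """Maximum sample covariance attainable under the given level margins.

    `margin_i` / `margin_j` are frequency vectors over the ordered levels
    0..m.  The comonotone coupling pairs the two sorted samples rank for
    rank; its covariance (divide-by-n) is the maximum over all joint tables
    with these margins.
    """
    margin_i = np.asarray(margin_i, dtype=np.int64)
    margin_j = np.asarray(margin_j, dtype=np.int64)
    if margin_i.sum() != n or margin_j.sum() != n:
        raise ScalemokError("margins must each sum to n")
    if n < 2:
        raise ScalemokError("need n >= 2")
    xi = np.repeat(np.arange(margin_i.size), margin_i)  # sorted ascending
    xj = np.repeat(np.arange(margin_j.size), margin_j)
    if xi.min() == xi.max() or xj.min() == xj.max():
        raise DegenerateItemError("zero-variance margin: H undefined for this pair")
    return float(np.mean(xi * xj) - xi.mean() * xj.mean())


def pairwise_cov_maxcov(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Observed and maximum covariance matrices for complete data columns.

    Sorting each column independently realizes the comonotone coupling for
    every pair at once, so ``maxcov = sorted.T @ sorted / n - outer(means)``.
    Diagonals equal the item variances in both matrices.
    """
    v = np.asarray(values, dtype=np.float64)
    n = v.shape[0]
    means = v.mean(axis=0)
    cov = v.T @ v / n - np.outer(means, means)
    s = np.sort(v, axis=0)
    maxcov = s.T @ s / n - np.outer(means, means)
    return cov, maxcov


@dataclass
class ScalabilityResult:
    """H estimates at pair, item and scale level with bootstrap SEs."""

    item_ids: list[str]
    H_pair: np.ndarray  # J x J, diagonal NaN
    H_item: np.ndarray  # length J
    H_scale: float
    se_item: np.ndarray | None = None
    se_scale: float | None = None
    n_used: int = 0
    bootstrap_reps: int = 0
    seed: int | None = None
    excluded_items: list[str] = field(default_factory=list)
    se_method: str = "nonparametric bootstrap over respondents"

    @property
    def label(self) -> str:
        return classify_H(self.H_scale)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"item": self.item_ids, "H_item": self.H_item})
        if self.se_item is not None:
            df["SE"] = self.se_item
        return df

    def to_dict(self) -> dict:
        return {
            "items": self.item_ids,
            "H_item": [None if np.isnan(h) else float(h) for h in self.H_item],
            "H_scale": float(self.H_scale),
            "se_item": None
            if self.se_item is None
            else [float(s) for s in self.se_item],
            "se_scale": None if self.se_scale is None else float(self.se_scale),
            "label": self.label,
            "n_used": self.n_used,
            "bootstrap_reps": self.bootstrap_reps,
            "seed": self.seed,
            "excluded_items": self.excluded_items,
            "se_method": self.se_method,
        }


def _h_from_matrices(cov: np.ndarray, maxcov: np.ndarray):
    """(H_pair, H_item, H_scale) from covariance matrices; off-diagonal only."""
    j = cov.shape[0]
    off = ~np.eye(j, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_pair = np.where(off, cov / maxcov, np.nan)
    num_item = np.where(off, cov, 0.0).sum(axis=1)
    den_item = np.where(off, maxcov, 0.0).sum(axis=1)
    h_item = num_item / den_item
    h_scale = float(num_item.sum() / den_item.sum())  # = sum_{i<j} ratio, doubled
    return h_pair, h_item, h_scale


def compute_H(
    matrix: ResponseMatrix,
    scale: ScaleDefinition | None = None,
    bootstrap_reps: int = 1000,
    seed: int | None = None,
) -> ScalabilityResult:
    """Loevinger H at pair, item and scale level on complete cases.

    Zero-variance items are excluded with a warning (their H entries are
    NaN); if fewer than two items remain the scale is degenerate and a
    :class:`DegenerateItemError` is raised.  Standard errors come from a
    seeded nonparametric bootstrap over respondents; pass
    ``bootstrap_reps=0`` to skip them.
    """
    if scale is None:
        scale = ScaleDefinition("all", list(matrix.item_ids))
    data = complete_cases(matrix, scale)
    v = data.values.astype(np.float64)
    n, j = v.shape

    variances = v.var(axis=0)
    degenerate = variances == 0.0
    excluded = [data.item_ids[k] for k in np.flatnonzero(degenerate)]
    if j - len(excluded) < 2:
        raise DegenerateItemError(
            f"fewer than 2 items with positive variance in scale {scale.name!r}",
            items=excluded,
        )
    if excluded:
        warnings.warn(
            f"excluding zero-variance items from H computation: {excluded}",
            stacklevel=2,
        )
    keep = np.flatnonzero(~degenerate)
    vk = v[:, keep]

    cov, maxcov = pairwise_cov_maxcov(vk)
    h_pair_k, h_item_k, h_scale = _h_from_matrices(cov, maxcov)

    h_pair = np.full((j, j), np.nan)
    h_pair[np.ix_(keep, keep)] = h_pair_k
    h_item = np.full(j, np.nan)
    h_item[keep] = h_item_k

    se_item = None
    se_scale = None
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        boot_item = np.empty((bootstrap_reps, keep.size))
        boot_scale = np.empty(bootstrap_reps)
        for b in range(bootstrap_reps):
            idx = rng.integers(0, n, n)
            bc, bm = pairwise_cov_maxcov(vk[idx])
            _, bi, bs = _h_from_matrices(bc, bm)
            boot_item[b] = bi
            boot_scale[b] = bs
        se_item = np.full(j, np.nan)
        se_item[keep] = boot_item.std(axis=0, ddof=1)
        se_scale = float(boot_scale.std(ddof=1))

    return ScalabilityResult(
        item_ids=list(data.item_ids),
        H_pair=h_pair,
        H_item=h_item,
        H_scale=h_scale,
        se_item=se_item,
        se_scale=se_scale,
        n_used=n,
        bootstrap_reps=bootstrap_reps,
        seed=seed,
        excluded_items=excluded,
    )


def classify_H(h: float) -> str:
    """Scale-strength label by the standard rules of thumb.

    Half-open bins: below 0.3 unacceptable, [0.3, 0.4) weak, [0.4, 0.5)
    moderate, 0.5 and above strong.
    """
    if h >= 0.5:
        return "strong"
    if h >= 0.4:
        return "moderate"
    if h >= 0.3:
        return "weak"
    return "unacceptable"
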