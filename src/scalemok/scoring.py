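"""Level sum scores, composite items, and internal-consistency reliability.

The level sum score (LSS) assigns each response its level number (1 = least
severe ... 5 = most severe in external coding), sums over the scale's
items, and linearly rescales to 0-100 so scales of different length are
comparable.  Higher scores mean more problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    EXTERNAL_OFFSET,
    ResponseMatrix,
    ScaleDefinition,
    complete_cases,
)
from .errors import ConfigurationError, UndefinedReliabilityError

__all__ = [
    "LSSResult",
    "CompositeRule",
    "build_composite",
    "compute_lss",
    "cronbach_alpha",
    "guttman_lambda2",
]


@dataclass
class LSSResult:
    """Per-respondent raw and 0-100 level sum scores for one scale."""

    scale_name: str
    raw_sum: np.ndarray  # external coding: range [J*1, J*levels]
    transformed: np.ndarray  # exactly (raw - J) / (J * (levels - 1)) * 100
    respondent_index: np.ndarray  # original row positions of scored respondents
    n_items: int
    levels: int
    n_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "respondent": self.respondent_index,
                "raw": self.raw_sum,
                "lss_0_100": self.transformed,
            }
        )


@dataclass
class CompositeRule:
    """Merge two items into one composite level via a symmetric 5x5 table.

    The default table takes the worse (maximum) of the two levels, the
    conservative severity-respecting merge.  Any explicit table overrides
    it, subject to: values within 1..levels, diagonal identity
    mapping(l, l) = l, and symmetry in the two arguments.
    """

    source_item_pair: tuple[str, str]
    composite_id: str
    mapping: np.ndarray | None = None  # external levels; mapping[a-1, b-1]
    levels: int = 5
    is_default_max: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        if self.mapping is None:
            grid = np.arange(1, self.levels + 1)
            self.mapping = np.maximum.outer(grid, grid)
            self.is_default_max = True
        self.mapping = np.asarray(self.mapping, dtype=np.int64)
        if self.mapping.shape != (self.levels, self.levels):
            raise ConfigurationError("composite mapping must be levels x levels")
        if self.mapping.min() < 1 or self.mapping.max() > self.levels:
            raise ConfigurationError("composite mapping values must lie in 1..levels")
        diag = np.diag(self.mapping)
        if not np.array_equal(diag, np.arange(1, self.levels + 1)):
            raise ConfigurationError("composite mapping must map (l, l) -> l")
        if not np.array_equal(self.mapping, self.mapping.T):
            raise ConfigurationError("composite mapping must be symmetric")

    def apply(self, a_external: int, b_external: int) -> int:
        return int(self.mapping[a_external - 1, b_external - 1])


def build_composite(
    matrix: ResponseMatrix,
    rule: CompositeRule,
    drop_sources: bool = False,
) -> ResponseMatrix:
    """Append a composite item column built from a pair of source items.

    A respondent missing either source has the composite missing.  Source
    columns are retained by default so originals and composites can be
    modelled side by side.
    """
    ia = matrix.item_index(rule.source_item_pair[0])
    ib = matrix.item_index(rule.source_item_pair[1])
    if rule.composite_id in matrix.item_ids:
        raise ConfigurationError(f"item id {rule.composite_id!r} already exists")
    ext = matrix.values + EXTERNAL_OFFSET
    comp_missing = matrix.missing_mask[:, ia] | matrix.missing_mask[:, ib]
    a = np.where(comp_missing, 1, ext[:, ia])
    b = np.where(comp_missing, 1, ext[:, ib])
    comp_ext = rule.mapping[a - 1, b - 1]
    comp_internal = np.where(comp_missing, 0, comp_ext - EXTERNAL_OFFSET)

    values = np.column_stack([matrix.values, comp_internal])
    mask = np.column_stack([matrix.missing_mask, comp_missing])
    item_ids = matrix.item_ids + [rule.composite_id]
    if drop_sources:
        keep = [k for k in range(len(item_ids)) if k not in (ia, ib)]
        values, mask = values[:, keep], mask[:, keep]
        item_ids = [item_ids[k] for k in keep]
    return ResponseMatrix(
        values, item_ids, mask, levels=matrix.levels, row_index=matrix.row_index
    )


def compute_lss(matrix: ResponseMatrix, scale: ScaleDefinition) -> LSSResult:
    """Level sum score on complete cases, raw and rescaled to 0-100.

    transformed = (raw - J) / (J * (levels - 1)) * 100, an exact linear map
    sending the all-least-severe profile to 0 and the all-most-severe
    profile to 100.  Respondents with any missing scale item are excluded
    and counted.
    """
    sub = matrix.select_items(scale.member_item_ids)
    keep = ~sub.missing_mask.any(axis=1)
    data = sub.select_rows(keep)
    j = data.n_items
    raw = data.values.sum(axis=1) + j * EXTERNAL_OFFSET
    transformed = (raw - j) / (j * (data.levels - 1)) * 100.0
    return LSSResult(
        scale_name=scale.name,
        raw_sum=raw,
        transformed=transformed,
        respondent_index=data.row_index,
        n_items=j,
        levels=data.levels,
        n_excluded=int((~keep).sum()),
    )


def _scale_covariance(matrix: ResponseMatrix, scale: ScaleDefinition) -> np.ndarray:
    data = complete_cases(matrix, scale)
    if data.n_respondents < 2:
        raise UndefinedReliabilityError("need at least 2 complete cases")
    return np.cov(data.values.astype(float), rowvar=False)


def cronbach_alpha(matrix: ResponseMatrix, scale: ScaleDefinition) -> float:
    """Cronbach's alpha: (J/(J-1)) * (1 - sum var(X_j) / var(sum X_j))."""
    c = _scale_covariance(matrix, scale)
    j = c.shape[0]
    total_var = c.sum()
    if total_var <= 0:
        raise UndefinedReliabilityError("zero total-score variance")
    return float(j / (j - 1) * (1.0 - np.trace(c) / total_var))


def guttman_lambda2(matrix: ResponseMatrix, scale: ScaleDefinition) -> float:
    """Guttman's lambda-2, never below alpha.

    lambda2 = [sum_{i != j} c_ij + sqrt(J/(J-1) * sum_{i != j} c_ij^2)]
              / var(sum X_j)
    """
    c = _scale_covariance(matrix, scale)
    j = c.shape[0]
    total_var = c.sum()
    if total_var <= 0:
        raise UndefinedReliabilityError("zero total-score variance")
    off = ~np.eye(j, dtype=bool)
    off_sum = c[off].sum()
    off_sq = (c[off] ** 2).sum()
    return float((off_sum + np.sqrt(j / (j - 1) * off_sq)) / total_var)
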