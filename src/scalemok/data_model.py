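"""Core data containers for ordinal questionnaire data.

Responses are coded 1..levels externally (as in the instrument) and 0..m
internally with m = levels - 1; the offset is a fixed 1, so covariances and
every H coefficient are identical in either coding.  Missing entries are
tracked in a boolean mask, never as sentinel codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyDataError, ParseError

EXTERNAL_OFFSET = 1  # external code = internal code + 1


@dataclass
class LoadReport:
    """Counts accumulated while reading a response file."""

    n_rows: int = 0
    n_out_of_range: int = 0
    n_blank: int = 0

    @property
    def n_missing(self) -> int:
        return self.n_out_of_range + self.n_blank


@dataclass
class ScaleDefinition:
    """A named subset of at least two items treated as one scale."""

    name: str
    member_item_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.member_item_ids) < 2:
            raise ConfigurationError(
                f"scale {self.name!r} needs >= 2 items, got {len(self.member_item_ids)}"
            )
        if len(set(self.member_item_ids)) != len(self.member_item_ids):
            raise ConfigurationError(f"scale {self.name!r} has duplicate items")


@dataclass
class GroupLabels:
    """Per-respondent categorical labels for stratification variables."""

    labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.labels.values()}
        if len(lengths) > 1:
            raise ConfigurationError("group label vectors have differing lengths")

    def __len__(self) -> int:
        return 0 if not self.labels else len(next(iter(self.labels.values())))

    def subset(self, row_index: np.ndarray) -> "GroupLabels":
        return GroupLabels({k: np.asarray(v)[row_index] for k, v in self.labels.items()})


@dataclass
class ResponseMatrix:
    """N x J ordinal item responses, internally coded 0..levels-1.

    `values` holds internal codes; masked entries hold 0 and must never be
    read.  `row_index` tracks the original respondent positions through
    subsetting so scores can be joined back to group labels.
    """

    values: np.ndarray
    item_ids: list[str]
    missing_mask: np.ndarray
    levels: int = 5
    row_index: np.ndarray | None = None
    load_report: LoadReport | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, j = self.values.shape
        if n < 1 or j < 2:
            raise ConfigurationError(f"need N >= 1 and J >= 2, got shape {(n, j)}")
        if len(self.item_ids) != j:
            raise ConfigurationError("item_ids length does not match matrix width")
        if len(set(self.item_ids)) != j:
            raise ConfigurationError("item_ids must be unique")
        if self.missing_mask.shape != self.values.shape:
            raise ConfigurationError("missing_mask shape does not match values")
        observed = self.values[~self.missing_mask]
        if observed.size and (observed.min() < 0 or observed.max() > self.levels - 1):
            raise ConfigurationError(
                f"internal codes must lie in [0, {self.levels - 1}]"
            )
        if self.row_index is None:
            self.row_index = np.arange(n)

    # -- basic geometry ----------------------------------------------------
    @property
    def n_respondents(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def max_level(self) -> int:
        """m = levels - 1, the number of item steps (ISRFs) per item."""
        return self.levels - 1

    def item_index(self, item_id: str) -> int:
        try:
            return self.item_ids.index(item_id)
        except ValueError:
            raise ConfigurationError(f"unknown item {item_id!r}") from None

    # -- coding ------------------------------------------------------------
    @classmethod
    def from_external(
        cls,
        external: np.ndarray,
        item_ids: list[str],
        levels: int = 5,
        missing_mask: np.ndarray | None = None,
    ) -> "ResponseMatrix":
        """Build from externally coded (1..levels) integer responses."""
        external = np.asarray(external, dtype=np.int64)
        if missing_mask is None:
            missing_mask = np.zeros(external.shape, dtype=bool)
        internal = np.where(missing_mask, 0, external - EXTERNAL_OFFSET)
        return cls(internal, list(item_ids), missing_mask, levels=levels)

    def to_external(self) -> np.ndarray:
        """Externally coded values; missing entries become -1."""
        out = self.values + EXTERNAL_OFFSET
        return np.where(self.missing_mask, -1, out)

    def to_frame(self) -> pd.DataFrame:
        """External coding as a DataFrame with NA for missing entries."""
        ext = self.to_external().astype(float)
        ext[self.missing_mask] = np.nan
        return pd.DataFrame(ext, columns=self.item_ids)

    # -- subsetting --------------------------------------------------------
    def select_items(self, item_ids: list[str]) -> "ResponseMatrix":
        cols = [self.item_index(i) for i in item_ids]
        return replace(
            self,
            values=self.values[:, cols],
            item_ids=list(item_ids),
            missing_mask=self.missing_mask[:, cols],
            load_report=None,
        )

    def select_rows(self, row_mask: np.ndarray) -> "ResponseMatrix":
        if not np.any(row_mask):
            raise EmptyDataError("row selection leaves no respondents")
        return replace(
            self,
            values=self.values[row_mask],
            missing_mask=self.missing_mask[row_mask],
            row_index=self.row_index[row_mask],
            load_report=None,
        )


def load_responses(
    path,
    item_columns: list[str],
    level_range: tuple[int, int] = (1, 5),
    sep: str | None = None,
) -> ResponseMatrix:
    """Read wide-format delimited text into a ResponseMatrix.

    Cells outside `level_range` are flagged missing and counted in the
    attached ``load_report``; blank cells are missing; non-integer cells
    raise :class:`ParseError` with their row and column.
    """
    lo, hi = level_range
    if not item_columns:
        raise ConfigurationError("item_columns must be non-empty")
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing_cols = [c for c in item_columns if c not in df.columns]
    if missing_cols:
        raise ConfigurationError(f"columns not found in {path}: {missing_cols}")

    n = len(df)
    j = len(item_columns)
    external = np.zeros((n, j), dtype=np.int64)
    mask = np.zeros((n, j), dtype=bool)
    report = LoadReport(n_rows=n)
    na_tokens = {"", "na", "nan", "n/a", "."}
    for cj, col in enumerate(item_columns):
        for ri, cell in enumerate(df[col].to_numpy()):
            text = str(cell).strip()
            if text.lower() in na_tokens:
                mask[ri, cj] = True
                report.n_blank += 1
                continue
            try:
                value = int(text)
            except ValueError:
                raise ParseError(
                    f"non-integer cell {text!r} at row {ri}, column {col!r}",
                    row=ri,
                    column=col,
                )
            if value < lo or value > hi:
                mask[ri, cj] = True
                report.n_out_of_range += 1
            else:
                external[ri, cj] = value
    external = np.where(mask, lo, external)  # placeholder under the mask
    matrix = ResponseMatrix.from_external(
        external, item_columns, levels=hi - lo + 1, missing_mask=mask
    )
    matrix.load_report = report
    return matrix


def complete_cases(matrix: ResponseMatrix, scale: ScaleDefinition) -> ResponseMatrix:
    """Listwise deletion on the scale's items only.

    Restricting deletion to the analyzed item set means subscale analyses
    keep every respondent who answered that subscale, even if they skipped
    items elsewhere.
    """
    sub = matrix.select_items(scale.member_item_ids)
    keep = ~sub.missing_mask.any(axis=1)
    if not keep.any():
        raise EmptyDataError(
            f"no complete cases on scale {scale.name!r} ({matrix.n_respondents} rows)"
        )
    return sub.select_rows(keep)
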