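"""Table cleaning: deduplication, mean imputation, min-max normalization.

The cleaning pipeline runs in a fixed order — deduplicate, impute, convert
to a numeric matrix, min-max normalize — because each step's contract
assumes the previous one ran: imputation means are computed over observed
values only, and normalization requires a fully numeric matrix.
Deduplication precedes imputation so that rows made identical *by*
imputation do not masquerade as true duplicates.

Normalization bounds learned on training data are carried on the
:class:`FeatureMatrix` and can be re-applied to held-out tables; values
falling outside the training range are clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import PreprocessingError, ValidationError
from .synth import MISSING, RawTable

__all__ = [
    "FeatureMatrix",
    "deduplicate",
    "impute_missing",
    "to_matrix",
    "matrix_to_table",
    "minmax_normalize",
    "apply_bounds",
    "preprocess_table",
    "save_bounds",
    "load_bounds",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """L x P numeric matrix with labels and per-column normalization bounds.

    ``column_mins``/``column_maxs`` are the pre-normalization attribute
    bounds; they are None until :func:`minmax_normalize` has run.
    """

    values: np.ndarray  # (L, P) float
    labels: np.ndarray  # (L,) int
    attribute_names: tuple[str, ...]
    column_mins: np.ndarray | None = None
    column_maxs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValidationError("feature matrix must be 2-D")
        if len(self.labels) != self.values.shape[0]:
            raise ValidationError("label vector length != row count")
        if len(self.attribute_names) != self.values.shape[1]:
            raise ValidationError("attribute name count != column count")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    @property
    def normalized(self) -> bool:
        return self.column_mins is not None


def deduplicate(table: RawTable) -> RawTable:
    """Keep the first occurrence of each fully identical row, in order."""
    seen: set[tuple] = set()
    kept = []
    for row in table.rows:
        if row not in seen:
            seen.add(row)
            kept.append(row)
    return table.with_rows(kept)


def impute_missing(table: RawTable) -> RawTable:
    """Replace each '?' by its column's mean over *observed* values.

    Means are computed once, before any replacement, so imputed values never
    feed back into other imputations.  A column with no observed value has
    no defined mean and raises.
    """
    li = table.label_index
    n_cols = len(table.header)
    means: dict[int, float] = {}
    for j in range(n_cols):
        if j == li:
            continue
        observed = [float(r[j]) for r in table.rows if r[j] != MISSING]
        if any(r[j] == MISSING for r in table.rows):
            if not observed:
                raise PreprocessingError(
                    f"column {table.header[j]!r} is fully missing"
                )
            means[j] = sum(observed) / len(observed)
    if not means:
        return table
    new_rows = [
        tuple(
            means[j] if cell == MISSING else cell
            for j, cell in enumerate(row)
        )
        for row in table.rows
    ]
    return table.with_rows(new_rows)


def to_matrix(table: RawTable) -> FeatureMatrix:
    """Split a clean numeric table into an L x P matrix plus label vector."""
    if table.n_rows == 0:
        raise ValidationError("cannot build a matrix from an empty table")
    li = table.label_index
    values = []
    labels = []
    for row in table.rows:
        if any(c == MISSING for c in row):
            raise ValidationError(
                "table still contains missing markers; impute first"
            )
        cells = [float(c) for i, c in enumerate(row) if i != li]
        values.append(cells)
        labels.append(int(float(row[li])))
    return FeatureMatrix(
        values=np.asarray(values, dtype=float),
        labels=np.asarray(labels, dtype=int),
        attribute_names=table.attribute_names,
    )


def matrix_to_table(matrix: FeatureMatrix) -> RawTable:
    """Inverse of :func:`to_matrix` (labels re-appended as the last column)."""
    header = matrix.attribute_names + ("label",)
    rows = tuple(
        tuple(map(float, matrix.values[i])) + (float(matrix.labels[i]),)
        for i in range(matrix.n_rows)
    )
    return RawTable(header=header, rows=rows)


def minmax_normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Rescale each attribute to [0, 1] via (x - min) / (max - min).

    Constant columns are mapped to 0.0 (the ratio is undefined there and a
    constant attribute carries no information either way).  The bounds are
    stored on the result for reuse on held-out data.
    """
    mins = matrix.values.min(axis=0)
    maxs = matrix.values.max(axis=0)
    span = maxs - mins
    safe = np.where(span == 0, 1.0, span)
    scaled = (matrix.values - mins) / safe
    scaled[:, span == 0] = 0.0
    return FeatureMatrix(
        values=scaled,
        labels=matrix.labels,
        attribute_names=matrix.attribute_names,
        column_mins=mins,
        column_maxs=maxs,
    )


def apply_bounds(
    matrix: FeatureMatrix, mins: np.ndarray, maxs: np.ndarray
) -> FeatureMatrix:
    """Normalize held-out data with training bounds, clipping to [0, 1]."""
    mins = np.asarray(mins, dtype=float)
    maxs = np.asarray(maxs, dtype=float)
    if mins.shape != (matrix.n_attributes,) or maxs.shape != mins.shape:
        raise ValidationError("bounds shape does not match attribute count")
    span = maxs - mins
    safe = np.where(span == 0, 1.0, span)
    scaled = (matrix.values - mins) / safe
    scaled[:, span == 0] = 0.0
    scaled = np.clip(scaled, 0.0, 1.0)
    return FeatureMatrix(
        values=scaled,
        labels=matrix.labels,
        attribute_names=matrix.attribute_names,
        column_mins=mins,
        column_maxs=maxs,
    )


def preprocess_table(
    table: RawTable,
    *,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> FeatureMatrix:
    """Full cleaning pipeline: dedup -> impute -> matrix -> normalize.

    With ``bounds`` given (training mins/maxs), normalization reuses them
    and clips, as appropriate for held-out data.
    """
    matrix = to_matrix(impute_missing(deduplicate(table)))
    if bounds is None:
        return minmax_normalize(matrix)
    return apply_bounds(matrix, *bounds)


# -- bounds persistence (key-value text) ------------------------------------


def save_bounds(matrix: FeatureMatrix, path: str | Path) -> None:
    if not matrix.normalized:
        raise ValidationError("matrix carries no normalization bounds")
    assert matrix.column_mins is not None and matrix.column_maxs is not None
    lines = [
        f"{name}\t{float(lo)!r}\t{float(hi)!r}"
        for name, lo, hi in zip(
            matrix.attribute_names, matrix.column_mins, matrix.column_maxs
        )
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_bounds(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    mins, maxs = [], []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        _, lo, hi = line.split("\t")
        mins.append(float(lo))
        maxs.append(float(hi))
    return np.asarray(mins), np.asarray(maxs)
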