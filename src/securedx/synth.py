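"""Seeded synthetic patient tables in the UCI heart-disease CSV dialect.

The generator emulates the *shape* of the UCI heart-disease tables (the
Hungarian-style dialect): numeric attributes, ``'?'`` as the missing-value
marker, and an integer class label (0 = normal, higher = disease severity).
It makes no attempt to match the real dataset's marginal distributions or
attribute semantics — it exists so every downstream stage (deduplication,
imputation, normalization, reduction, classification) can be exercised and
tested without downloading external data.

Rows are drawn class-conditionally Gaussian: class k has mean
``mu_k = k * class_mean_separation * u`` along a fixed unit direction ``u``,
so ``||mu_k - mu_j|| = class_mean_separation * |k - j|``, with isotropic
noise of standard deviation ``noise_sd``.  Labels are uniform over the
classes.  After generation, a ``duplicate_rate`` fraction of rows is copied
verbatim and appended, then a ``missing_rate`` fraction of non-label cells
is replaced by ``'?'`` — in that order, so deduplication and imputation are
separately exercisable.  Identical config and seed give byte-identical
serialized output.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError

__all__ = [
    "MISSING",
    "SyntheticConfig",
    "RawTable",
    "generate_dataset",
    "table_to_csv",
    "table_from_csv",
    "write_csv",
    "read_csv",
]

MISSING = "?"

Cell = float | str  # a numeric value or the '?' marker


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic patient-table generator.

    Defaults mirror common usage of the UCI heart-disease tables: 13 numeric
    attributes and a binary normal/disease label.  ``class_mean_separation``
    is the distance between adjacent class means in feature units.
    """

    n_records: int = 300
    n_attributes: int = 13
    n_classes: int = 2
    class_mean_separation: float = 2.0
    noise_sd: float = 1.0
    missing_rate: float = 0.05
    duplicate_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1 or self.n_attributes < 1:
            raise ConfigurationError("n_records and n_attributes must be >= 1")
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        if self.class_mean_separation < 0:
            raise ConfigurationError("class_mean_separation must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if not 0 <= self.duplicate_rate < 1:
            raise ConfigurationError("duplicate_rate must lie in [0, 1)")


@dataclass(frozen=True)
class RawTable:
    """An ordered table of records with a header and a label column.

    Cells are floats or the ``'?'`` marker; label cells are never missing.
    """

    header: tuple[str, ...]
    rows: tuple[tuple[Cell, ...], ...]
    label_column: str = "label"

    def __post_init__(self) -> None:
        if self.label_column not in self.header:
            raise ValidationError(
                f"label column {self.label_column!r} not in header"
            )
        width = len(self.header)
        li = self.label_index
        for row in self.rows:
            if len(row) != width:
                raise ValidationError("ragged row in table")
            if row[li] == MISSING:
                raise ValidationError("label cell may not be missing")

    @property
    def label_index(self) -> int:
        return self.header.index(self.label_column)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def attribute_names(self) -> tuple[str, ...]:
        li = self.label_index
        return tuple(h for i, h in enumerate(self.header) if i != li)

    def with_rows(self, rows: Sequence[Sequence[Cell]]) -> "RawTable":
        return replace(self, rows=tuple(tuple(r) for r in rows))


def generate_dataset(config: SyntheticConfig) -> RawTable:
    """Draw a synthetic patient table per the class-conditional model."""
    rng = np.random.default_rng(config.seed)
    L, P = config.n_records, config.n_attributes

    direction = np.ones(P) / np.sqrt(P)
    labels = rng.integers(0, config.n_classes, size=L)
    means = labels[:, None] * config.class_mean_separation * direction[None, :]
    values = means + rng.normal(0.0, config.noise_sd, size=(L, P))

    rows: list[list[Cell]] = [
        [*map(float, values[i]), float(labels[i])] for i in range(L)
    ]

    # verbatim duplicates appended after generation
    n_dup = int(round(config.duplicate_rate * L))
    if n_dup:
        dup_idx = rng.integers(0, L, size=n_dup)
        rows.extend([list(rows[i]) for i in dup_idx])

    # then missing markers over non-label cells
    total_cells = len(rows) * P
    n_missing = int(round(config.missing_rate * total_cells))
    if n_missing:
        flat = rng.choice(total_cells, size=n_missing, replace=False)
        for pos in flat:
            rows[pos // P][pos % P] = MISSING

    header = tuple(f"attr_{j + 1}" for j in range(P)) + ("label",)
    return RawTable(header=header, rows=tuple(tuple(r) for r in rows))


def _format_cell(cell: Cell) -> str:
    if cell == MISSING:
        return MISSING
    value = float(cell)
    if value == int(value):
        return str(int(value))
    return repr(value)


def table_to_csv(table: RawTable) -> str:
    """Serialize in the '?'-dialect: comma-separated, header row, LF endings."""
    buf = io.StringIO()
    buf.write(",".join(table.header) + "\n")
    for row in table.rows:
        buf.write(",".join(_format_cell(c) for c in row) + "\n")
    return buf.getvalue()


def table_from_csv(text: str, label_column: str = "label") -> RawTable:
    lines = [ln for ln in text.split("\n") if ln.strip()]
    if not lines:
        raise ValidationError("empty table file")
    header = tuple(lines[0].split(","))
    rows: list[tuple[Cell, ...]] = []
    for ln in lines[1:]:
        cells: list[Cell] = []
        for raw in ln.split(","):
            raw = raw.strip()
            cells.append(MISSING if raw == MISSING else float(raw))
        rows.append(tuple(cells))
    return RawTable(header=header, rows=tuple(rows), label_column=label_column)


def write_csv(table: RawTable, path: str | Path) -> None:
    Path(path).write_text(table_to_csv(table), encoding="utf-8", newline="\n")


def read_csv(path: str | Path, label_column: str = "label") -> RawTable:
    return table_from_csv(
        Path(path).read_text(encoding="utf-8"), label_column=label_column
    )
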