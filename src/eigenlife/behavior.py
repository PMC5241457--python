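"""Binary behavior matrices built from diary entries.

A behavior matrix B for one subject and one category is a binary D x H
matrix: one row per annotated day, one column per (class, period) pair,
with a 1 wherever at least one annotation of that class overlaps that
period on that day.  Group-level matrices hold one row per subject — the
subject's *average behavior* (column means of their individual matrix) —
and therefore take values in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diary import DiaryEntry, assign_periods, map_to_class, preprocess_annotation
from .lexicons import CATEGORIES, ClassLexicon, PeriodScheme, default_lexicon, default_scheme


@dataclass
class BehaviorMatrix:
    """Days-by-columns (or subjects-by-columns) behavior matrix.

    ``values`` is binary for individual matrices and lies in [0, 1] for
    group matrices of averaged rows.  Columns are class-major in lexicon
    order with periods ascending within a class, so H = n_classes *
    n_periods (27 for activity, 72 for diet) regardless of which classes
    actually occur.
    """

    category: str
    row_labels: list
    col_labels: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("values shape does not match labels")
        if self.values.min(initial=0.0) < 0 or self.values.max(initial=0.0) > 1:
            raise ValueError("behavior values must lie in [0, 1]")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels,
                            columns=self.col_labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="row")

    @classmethod
    def from_csv(cls, path: str | Path, category: str) -> "BehaviorMatrix":
        # round_trip parsing keeps fractional group-average values bit-exact
        frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
        return cls(category=category,
                   row_labels=list(frame.index),
                   col_labels=list(frame.columns),
                   values=frame.to_numpy(dtype=float))


def behavior_columns(lexicon: ClassLexicon, scheme: PeriodScheme) -> list[str]:
    return [f"{cls}_{p}" for cls in lexicon.classes for p in scheme.labels]


def build_behavior_matrix(entries: list[DiaryEntry],
                          lexicon: ClassLexicon | None = None,
                          scheme: PeriodScheme | None = None) -> BehaviorMatrix:
    """Binary behavior matrix for one subject and one category.

    Rows are ordered by day index; only annotated days appear.  A cell
    (day, class_Pk) is 1 iff at least one entry of that class overlaps
    period Pk on that day, so duplicates are idempotent and the result is
    invariant to entry order.
    """
    if not entries:
        raise ValueError("no diary entries: zero annotated days")
    subjects = {e.subject_id for e in entries}
    categories = {e.category for e in entries}
    if len(subjects) > 1 or len(categories) > 1:
        raise ValueError("entries must share subject_id and category")
    category = categories.pop()
    lexicon = lexicon if lexicon is not None else default_lexicon(category)
    scheme = scheme if scheme is not None else default_scheme(category)
    if lexicon.category != category or scheme.category != category:
        raise ValueError("lexicon/scheme category mismatch")

    columns = behavior_columns(lexicon, scheme)
    col_index = {c: i for i, c in enumerate(columns)}
    days = sorted({e.day_index for e in entries})
    day_row = {d: i for i, d in enumerate(days)}
    values = np.zeros((len(days), len(columns)))
    for entry in entries:
        classes = map_to_class(preprocess_annotation(entry.text, lexicon),
                               lexicon)
        periods = assign_periods(entry, scheme)
        for cls in classes:
            for period in periods:
                values[day_row[entry.day_index], col_index[f"{cls}_{period}"]] = 1.0
    return BehaviorMatrix(category=category, row_labels=days,
                          col_labels=columns, values=values)


def average_behavior(matrix: BehaviorMatrix) -> np.ndarray:
    """Average behavior Psi: column means over days, in [0, 1] elementwise."""
    if matrix.n_rows < 1:
        raise ValueError("behavior matrix has no rows")
    return matrix.values.mean(axis=0)


def group_behavior_matrix(individual: dict[str, BehaviorMatrix],
                          subject_ids: list[str] | None = None) -> BehaviorMatrix:
    """Group-level matrix: one row per subject, holding average behaviors."""
    if not individual:
        raise ValueError("no individual matrices")
    ids = subject_ids if subject_ids is not None else sorted(individual)
    first = individual[ids[0]]
    rows = []
    for sid in ids:
        m = individual[sid]
        if m.col_labels != first.col_labels or m.category != first.category:
            raise ValueError("individual matrices are not column-compatible")
        rows.append(average_behavior(m))
    return BehaviorMatrix(category=first.category, row_labels=list(ids),
                          col_labels=list(first.col_labels),
                          values=np.vstack(rows))
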