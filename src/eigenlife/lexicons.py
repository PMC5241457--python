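"""Class lexicons and day-period schemes for the diet and activity behavior spaces.

Free-text diary annotations are mapped onto a fixed set of behavior classes
per category (9 activity classes, 12 diet classes), and each day is divided
into a fixed set of periods (3 for activity, 6 for diet).  A behavior-space
column is a (class, period) pair, labelled ``"<class>_P<k>"``, giving
27 activity columns and 72 diet columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

ACTIVITY = "activity"
DIET = "diet"
CATEGORIES = (ACTIVITY, DIET)

ACTIVITY_CLASSES: tuple[str, ...] = (
    "entertainment/relax",
    "work/study",
    "sport",
    "social",
    "vehicle",
    "none",
    "others",
    "walk",
    "bike",
)

DIET_CLASSES: tuple[str, ...] = (
    "fruit product",
    "grain product",
    "composite product",
    "vegetables",
    "meat product",
    "snacks",
    "alcohol drink",
    "others",
    "seafood",
    "caffeine drink",
    "starchy product",
    "dairy product",
)

_ACTIVITY_WORDS: dict[str, tuple[str, ...]] = {
    "entertainment/relax": ("shop", "travel", "watch", "game", "play",
                            "computer", "tv", "movie"),
    "work/study": ("exam", "homework", "read", "work", "lesson",
                   "university", "lecture", "school", "study"),
    "sport": ("run", "sport", "gym", "hockey", "swim", "fitness",
              "soccer", "workout"),
    "social": ("meet", "friends", "call", "party", "talk", "phone",
               "parent", "visit"),
    "vehicle": ("car", "bus", "train", "taxi", "drive"),
    "none": ("none",),
    "others": ("wait", "household", "pack", "shower"),
    "walk": ("walk",),
    "bike": ("bike", "cycle"),
}

_DIET_WORDS: dict[str, tuple[str, ...]] = {
    "fruit product": ("fruit", "orange", "apple", "banana", "kiwi",
                      "sultana", "pineapple", "smoothie", "juice"),
    "grain product": ("noodles", "oatmeal", "muesli", "bread", "macaroni"),
    "composite product": ("sandwich", "pizza", "soup", "rice", "pasta",
                          "lasagna", "hamburger"),
    "vegetables": ("cucumber", "spinach", "carrot", "pumpkin", "broccoli",
                   "tomato"),
    "meat product": ("beef", "bacon", "meat", "sausage", "chicken", "steak"),
    "snacks": ("nut", "pie", "candy", "icecream", "chocolate", "cake",
               "snack", "cookie"),
    "alcohol drink": ("beer", "wine", "alcohol"),
    "others": ("butter",),
    "seafood": ("fish", "tuna", "salmon"),
    "caffeine drink": ("cola", "tea", "coffee", "cappuccino"),
    "starchy product": ("potato", "chip", "fries"),
    "dairy product": ("shake", "milk", "cheese", "yoghurt"),
}


@dataclass(frozen=True)
class ClassLexicon:
    """Mapping from annotation vocabulary to behavior classes.

    Parameters
    ----------
    category : str
        ``"activity"`` or ``"diet"``.
    classes : tuple of str
        Ordered class names; the order fixes behavior-matrix column order.
    word_map : dict
        token -> class name; every token resolves to exactly one class.
    """

    category: str
    classes: tuple[str, ...]
    word_map: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        unknown = {c for c in self.word_map.values()} - set(self.classes)
        if unknown:
            raise ValueError(f"word_map targets unknown classes: {unknown}")

    @property
    def vocabulary(self) -> frozenset[str]:
        return frozenset(self.word_map)

    def class_of(self, token: str) -> str | None:
        """Class of a recognized token, or None."""
        return self.word_map.get(token)

    def to_json(self, path: str | Path) -> None:
        by_class: dict[str, list[str]] = {c: [] for c in self.classes}
        for word, cls in self.word_map.items():
            by_class[cls].append(word)
        payload = {self.category: {c: sorted(ws) for c, ws in by_class.items()}}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path, category: str) -> "ClassLexicon":
        payload = json.loads(Path(path).read_text())
        mapping = payload[category]
        classes = tuple(mapping)
        word_map = {w: c for c, words in mapping.items() for w in words}
        return cls(category=category, classes=classes, word_map=word_map)


def _build(category: str, words: dict[str, tuple[str, ...]],
           classes: tuple[str, ...]) -> ClassLexicon:
    word_map = {w: c for c, ws in words.items() for w in ws}
    return ClassLexicon(category=category, classes=classes, word_map=word_map)


ACTIVITY_LEXICON = _build(ACTIVITY, _ACTIVITY_WORDS, ACTIVITY_CLASSES)
DIET_LEXICON = _build(DIET, _DIET_WORDS, DIET_CLASSES)


def default_lexicon(category: str) -> ClassLexicon:
    return {ACTIVITY: ACTIVITY_LEXICON, DIET: DIET_LEXICON}[category]


@dataclass(frozen=True)
class PeriodScheme:
    """Partition of the day into labelled half-open intervals [start, end).

    Times are minutes since midnight; the intervals are contiguous and cover
    [0, 1440).  A point event at minute t belongs to the unique interval
    containing t; an interval event belongs to every period it overlaps.
    """

    category: str
    boundaries: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for label, start, end in self.boundaries:
            if start != prev_end or end <= start:
                raise ValueError("periods must be contiguous, increasing and "
                                 "cover [0, 1440)")
            prev_end = end
        if prev_end != 1440:
            raise ValueError("periods must cover the full day")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.boundaries)

    @property
    def n_periods(self) -> int:
        return len(self.boundaries)

    def period_of(self, minute: float) -> str:
        """Label of the half-open period containing ``minute``."""
        if not 0 <= minute < 1440:
            raise ValueError(f"time {minute} outside [0, 1440)")
        for label, start, end in self.boundaries:
            if start <= minute < end:
                return label
        raise AssertionError("unreachable: scheme covers [0, 1440)")

    def periods_overlapping(self, start: float, end: float) -> tuple[str, ...]:
        """Labels of every period the half-open interval [start, end) overlaps."""
        if not 0 <= start < 1440:
            raise ValueError(f"start time {start} outside [0, 1440)")
        if not start < end <= 1440:
            raise ValueError(f"end time {end} outside ({start}, 1440]")
        return tuple(label for label, p0, p1 in self.boundaries
                     if start < p1 and end > p0)


# Activity: morning / afternoon / evening.
ACTIVITY_PERIODS = PeriodScheme(ACTIVITY, (
    ("P0", 0, 720),      # 00:00-12:00 morning
    ("P1", 720, 1020),   # 12:00-17:00 afternoon
    ("P2", 1020, 1440),  # 17:00-24:00 evening
))

# Diet: breakfast / morning / lunch / afternoon / dinner / evening.
DIET_PERIODS = PeriodScheme(DIET, (
    ("P0", 0, 540),      # 00:00-09:00 breakfast
    ("P1", 540, 720),    # 09:00-12:00 morning
    ("P2", 720, 840),    # 12:00-14:00 lunch
    ("P3", 840, 1020),   # 14:00-17:00 afternoon
    ("P4", 1020, 1140),  # 17:00-19:00 dinner
    ("P5", 1140, 1440),  # 19:00-24:00 evening
))


def default_scheme(category: str) -> PeriodScheme:
    return {ACTIVITY: ACTIVITY_PERIODS, DIET: DIET_PERIODS}[category]


def column_labels(category: str) -> list[str]:
    """Behavior-space column labels, class-major in lexicon order."""
    lex = default_lexicon(category)
    scheme = default_scheme(category)
    return [f"{cls}_{p}" for cls in lex.classes for p in scheme.labels]
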