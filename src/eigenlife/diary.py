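"""Diary ingestion: free-text annotation preprocessing and class mapping.

Each diary row is a timestamped free-text entry ("watched TV and played
games", "cappuccino").  Preprocessing follows the usual NLP pipeline for
short annotations: tokenization, stop-word and punctuation removal,
lemmatization, and spell correction against the class lexicon (nearest
word within Levenshtein distance 2; ties broken lexicographically).
Recognized tokens are then mapped to behavior classes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import edlib
import pandas as pd

from .lexicons import CATEGORIES, ClassLexicon, PeriodScheme

logger = logging.getLogger(__name__)

# Small English stop-word list; enough for terse diary annotations.
STOPWORDS = frozenset("""
a an the and or but if then than so as of at by for with about into
through during before after to from in on off out over under again once
here there when where why how all any both each few more most other some
such no nor not only own same too very can will just don should now i me
my we our you your he him his she her it its they them their this that
these those am is are was were be been being have has had do does did
doing went go g went get got had ate eat drank drink took take
""".split())

_TOKEN_RE = re.compile(r"[a-z]+")

# Irregular forms worth knowing about for diary vocabulary.
_IRREGULAR = {
    "ran": "run",
    "swam": "swim",
    "swum": "swim",
    "met": "meet",
    "drove": "drive",
    "driven": "drive",
    "read": "read",
    "children": "child",
    "feet": "foot",
}


def tokenize(text: str) -> list[str]:
    """Lowercase alphabetic tokens, punctuation and digits discarded."""
    return _TOKEN_RE.findall(text.lower())


def lemmatize(token: str, vocabulary: frozenset[str] = frozenset()) -> str:
    """Reduce an inflected token to a base form with simple suffix rules.

    Tokens already present in ``vocabulary`` are left untouched (lexicon
    words such as "fries" or "noodles" are stored inflected); otherwise
    candidate base forms are preferred when they are in the vocabulary.
    """
    if token in vocabulary:
        return token
    if token in _IRREGULAR:
        return _IRREGULAR[token]

    candidates: list[str] = []
    if token.endswith("ies") and len(token) > 4:
        candidates.append(token[:-3] + "y")
    if token.endswith("es") and len(token) > 3:
        candidates.append(token[:-2])
    if token.endswith("s") and not token.endswith("ss") and len(token) > 3:
        candidates.append(token[:-1])
    for suffix in ("ing", "ed"):
        if token.endswith(suffix) and len(token) > len(suffix) + 2:
            stem = token[: -len(suffix)]
            candidates.append(stem)
            candidates.append(stem + "e")          # bake -> baking/baked
            if len(stem) > 2 and stem[-1] == stem[-2]:
                candidates.append(stem[:-1])       # run -> running
    for cand in candidates:
        if cand in vocabulary:
            return cand
    return candidates[0] if candidates else token


def spell_correct(token: str, vocabulary: frozenset[str],
                  max_distance: int = 2) -> str:
    """Correct a token to the nearest lexicon word within an edit distance.

    Ties on distance are broken lexicographically; tokens farther than
    ``max_distance`` from every lexicon word are returned unchanged.
    """
    if token in vocabulary:
        return token
    best_word, best_dist = None, max_distance + 1
    for word in sorted(vocabulary):
        dist = edlib.align(token, word, mode="NW", k=best_dist)["editDistance"]
        if dist != -1 and dist < best_dist:
            best_word, best_dist = word, dist
    return best_word if best_word is not None else token


def preprocess_annotation(text: str, lexicon: ClassLexicon) -> list[str]:
    """Tokenize, clean, lemmatize and spell-correct a raw annotation.

    Raises ``ValueError`` on empty (or whitespace-only) input; an empty
    *result* is valid (the annotation maps to nothing).
    """
    if not text or not text.strip():
        raise ValueError("empty annotation")
    vocab = lexicon.vocabulary
    tokens = [t for t in tokenize(text) if t not in STOPWORDS]
    tokens = [lemmatize(t, vocab) for t in tokens]
    return [spell_correct(t, vocab) for t in tokens]


def map_to_class(tokens: list[str], lexicon: ClassLexicon) -> set[str]:
    """Union of behavior classes of the recognized tokens.

    Unrecognized tokens are ignored (and logged at debug level).
    """
    classes: set[str] = set()
    for token in tokens:
        cls = lexicon.class_of(token)
        if cls is None:
            logger.debug("unrecognized token %r (%s lexicon)",
                         token, lexicon.category)
        else:
            classes.add(cls)
    return classes


@dataclass(frozen=True)
class DiaryEntry:
    """One timestamped diary annotation.

    ``start_time``/``end_time`` are minutes since midnight.  Diet entries
    are point events (``end_time`` is None); activity entries are
    intervals with ``start_time < end_time <= 1440``.
    """

    subject_id: str
    day_index: int
    category: str
    start_time: float
    end_time: float | None
    text: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not 0 <= self.start_time < 1440:
            raise ValueError(f"start time {self.start_time} outside [0, 1440)")
        if self.end_time is not None and not (
                self.start_time < self.end_time <= 1440):
            raise ValueError("end time must lie in (start, 1440]")
        if self.day_index < 1:
            raise ValueError("day_index must be >= 1")


def assign_periods(entry: DiaryEntry, scheme: PeriodScheme) -> set[str]:
    """Period labels an entry contributes to.

    Point events map to the unique half-open period containing their time;
    interval events map to every period their [start, end) overlaps.
    """
    if entry.end_time is None:
        return {scheme.period_of(entry.start_time)}
    return set(scheme.periods_overlapping(entry.start_time, entry.end_time))


def _parse_time(value: str) -> float:
    """'HH:MM' -> minutes since midnight (24:00 allowed as an end time)."""
    hh, mm = value.strip().split(":")
    return int(hh) * 60 + int(mm)


def read_diary_csv(path: str | Path) -> list[DiaryEntry]:
    """Read diary entries from CSV.

    Columns: subject_id, day_index, category, start, end, text; times are
    HH:MM and ``end`` is blank for point (diet) events.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    entries = []
    for row in frame.itertuples(index=False):
        end = row.end.strip() if row.end else ""
        entries.append(DiaryEntry(
            subject_id=row.subject_id,
            day_index=int(row.day_index),
            category=row.category,
            start_time=_parse_time(row.start),
            end_time=_parse_time(end) if end else None,
            text=row.text,
        ))
    return entries


def write_diary_csv(entries: list[DiaryEntry], path: str | Path) -> None:
    def fmt(minutes: float | None) -> str:
        if minutes is None:
            return ""
        return f"{int(minutes) // 60:02d}:{int(minutes) % 60:02d}"

    frame = pd.DataFrame(
        [(e.subject_id, e.day_index, e.category, fmt(e.start_time),
          fmt(e.end_time), e.text) for e in entries],
        columns=["subject_id", "day_index", "category", "start", "end", "text"],
    )
    frame.to_csv(path, index=False)
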