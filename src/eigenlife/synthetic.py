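"""Synthetic cohorts with the structure the double-layer analysis assumes.

The generator emulates a small diary study: ~21 subjects annotating ~10
days each, with two latent groups.  Health indicators are drawn from
group-conditional Gaussians whose mixture reproduces the pooled cohort
moments; the group profile mirrors the male/female physiology contrast
(higher VO2max, BEE, height, weight and fat-free mass in one group,
higher fat mass and fat percentage in the other), with VO2max and BEE
carrying the largest shift.  Daily routines are drawn from Bernoulli
day-type templates: activity templates are group-specific (the grouping
is visible in activity behavior), diet templates are shared between
groups and sparser (diet behavior carries no group signal), matching the
regime the validation machinery is meant to discriminate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import BehaviorMatrix, behavior_columns, group_behavior_matrix
from .diary import DiaryEntry
from .lexicons import ACTIVITY, DIET, default_lexicon, default_scheme

# Pooled cohort moments: mean, SD per indicator.
POOLED_INDICATORS: dict[str, tuple[float, float]] = {
    "age": (26.0, 6.0),
    "bmi": (22.7, 2.5),
    "weight": (69.7, 10.8),
    "height": (174.9, 9.2),
    "vo2max": (3009.0, 679.0),
    "rel_vo2max": (43.0, 6.8),
    "rmr": (1.2, 0.16),
    "bee": (1567.0, 215.0),
    "fat_mass": (14.4, 6.9),
    "fat_free_mass": (55.3, 9.4),
    "pct_fat": (20.4, 7.7),
}

# Between-group mean difference per indicator in pooled-SD units, at the
# default effect size (group 1 minus group 0).  The profile follows known
# sex differences in body composition and fitness; VO2max and BEE carry
# the largest shift.  All entries scale linearly with group_shift_sd.
GROUP_PROFILE: dict[str, float] = {
    "age": 0.0,
    "bmi": 0.3,
    "weight": 1.2,
    "height": 1.4,
    "vo2max": 2.0,
    "rel_vo2max": 1.2,
    "rmr": 1.2,
    "bee": 2.0,
    "fat_mass": -1.0,
    "fat_free_mass": 1.5,
    "pct_fat": -1.4,
}

# Floor on the within-group share of pooled variance (keeps sampling
# well-defined at large effect sizes).
_MIN_WITHIN_VAR_FRACTION = 0.05


@dataclass(frozen=True)
class RoutineTemplate:
    """Bernoulli day-type templates over the H behavior-space cells.

    Each day first draws a day type (e.g. a routine weekday vs a free
    day) from ``weights``, then every cell independently from the type's
    probability row.  One or two day types give low-rank mean structure
    plus Bernoulli noise — the regime eigenbehavior analysis assumes.
    """

    probs: np.ndarray   # (n_day_types, H)
    weights: np.ndarray  # (n_day_types,)

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if probs.min() < 0 or probs.max() > 1:
            raise ValueError("template probabilities must lie in [0, 1]")
        if not np.isclose(weights.sum(), 1.0) or (weights < 0).any():
            raise ValueError("day-type weights must be a distribution")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "weights", weights)

    def scaled(self, factor: float) -> "RoutineTemplate":
        return RoutineTemplate(self.probs * factor, self.weights)

    def mean_profile(self) -> np.ndarray:
        return self.weights @ self.probs


def _template(category: str, day_types: list[dict[str, float]],
              weights: list[float], background: float) -> RoutineTemplate:
    columns = behavior_columns(default_lexicon(category),
                               default_scheme(category))
    index = {c: i for i, c in enumerate(columns)}
    probs = np.full((len(day_types), len(columns)), background)
    for row, cells in zip(probs, day_types):
        for cell, p in cells.items():
            row[index[cell]] = p
    return RoutineTemplate(probs, np.asarray(weights))


def default_activity_templates() -> dict[int, RoutineTemplate]:
    """Group-specific activity routines: office-centred vs sport-centred."""
    group0 = _template(ACTIVITY, [
        {  # routine weekday: commute, desk work, evening screen time
            "work/study_P0": 0.9, "work/study_P1": 0.85,
            "vehicle_P0": 0.75, "vehicle_P2": 0.4,
            "entertainment/relax_P2": 0.9, "others_P0": 0.3,
            "walk_P1": 0.35,
        },
        {  # free day: errands, social evening
            "entertainment/relax_P0": 0.7, "entertainment/relax_P1": 0.6,
            "entertainment/relax_P2": 0.8, "social_P2": 0.75,
            "social_P1": 0.4, "walk_P2": 0.5, "others_P1": 0.5,
        },
    ], weights=[0.7, 0.3], background=0.06)
    # Group 1 keeps a single highly regular day type (bike commute, work,
    # evening training): a tight within-group routine, against group 0's
    # more variable two-day-type mixture.
    group1 = _template(ACTIVITY, [
        {
            "work/study_P0": 0.9, "work/study_P1": 0.8,
            "bike_P0": 0.85, "bike_P2": 0.5, "sport_P2": 0.8,
            "entertainment/relax_P2": 0.45, "others_P2": 0.3,
        },
    ], weights=[1.0], background=0.06)
    return {0: group0, 1: group1}


def default_diet_template() -> RoutineTemplate:
    """Shared diet routine: few high-traffic meal cells, sparse elsewhere.

    Probabilities are given *before* the diet sparsity factor is applied;
    the factor emulates under-reporting of food items in the diaries.
    """
    return _template(DIET, [
        {  # typical day: cereal breakfast, coffee, warm lunch and dinner
            "grain product_P0": 0.95, "caffeine drink_P0": 0.9,
            "composite product_P2": 0.95, "composite product_P4": 0.9,
            "fruit product_P3": 0.5,
        },
        {  # variant day: meat dinner, evening drink
            "grain product_P0": 0.95, "caffeine drink_P0": 0.9,
            "composite product_P2": 0.85, "meat product_P4": 0.9,
            "alcohol drink_P5": 0.6,
        },
    ], weights=[0.75, 0.25], background=0.002)


@dataclass
class CohortSpec:
    """Parameters of a synthetic diary cohort.

    ``group_shift_sd`` is the between-group mean difference for VO2max
    and BEE in pooled-SD units; the remaining indicators shift by the
    same gender-like profile scaled proportionally, and within-group SDs
    shrink so that pooled moments stay at their nominal values.  Setting
    it to 0 makes the groups indistinguishable in distribution.
    """

    n_subjects: int = 21
    days_per_subject: int = 10
    group_fractions: tuple[float, ...] = (13 / 21, 8 / 21)
    indicator_moments: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(POOLED_INDICATORS))
    group_shift_sd: float = 2.0
    routine_templates: dict[tuple[int, str], RoutineTemplate] | None = None
    noise_flip_prob: float = 0.005
    diet_sparsity: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.group_fractions), 1.0):
            raise ValueError("group fractions must sum to 1")
        if not 0 <= self.noise_flip_prob <= 1:
            raise ValueError("noise_flip_prob must lie in [0, 1]")
        if not 0 < self.diet_sparsity <= 1:
            raise ValueError("diet_sparsity must lie in (0, 1]")

    def templates(self) -> dict[tuple[int, str], RoutineTemplate]:
        if self.routine_templates is not None:
            return self.routine_templates
        activity = default_activity_templates()
        diet = default_diet_template().scaled(self.diet_sparsity)
        return {(0, ACTIVITY): activity[0], (1, ACTIVITY): activity[1],
                (0, DIET): diet, (1, DIET): diet}

    def subject_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]

    def group_sizes(self) -> list[int]:
        sizes = [int(round(f * self.n_subjects)) for f in self.group_fractions]
        sizes[-1] = self.n_subjects - sum(sizes[:-1])
        return sizes


def sample_health_indicators(spec: CohortSpec,
                             rng: np.random.Generator | None = None
                             ) -> tuple[pd.DataFrame, pd.Series]:
    """Group-conditional Gaussian indicators plus true group labels.

    Group means are displaced along the gender-like profile (pooled mean
    preserved by size-weighting) and within-group variances shrink so the
    mixture variance matches the pooled SD.  Non-positive draws are
    redrawn (all indicators are physically positive).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    sizes = spec.group_sizes()
    if len(sizes) != 2:
        raise ValueError("indicator sampling assumes two groups")
    labels = np.repeat(np.arange(len(sizes)), sizes)
    p1 = sizes[1] / spec.n_subjects
    p0 = 1.0 - p1
    scale = spec.group_shift_sd / GROUP_PROFILE["vo2max"]
    data = {}
    for name, (mean, sd) in spec.indicator_moments.items():
        delta = GROUP_PROFILE.get(name, 0.0) * scale
        within_var = max(1.0 - p0 * p1 * delta ** 2, _MIN_WITHIN_VAR_FRACTION)
        wsd = sd * np.sqrt(within_var)
        mu = np.where(labels == 0, mean - p1 * delta * sd,
                      mean + p0 * delta * sd)
        draws = rng.normal(mu, wsd)
        while (draws <= 0).any():  # truncate at 0 by redrawing
            bad = draws <= 0
            draws[bad] = rng.normal(mu[bad], wsd)
        data[name] = draws
    ids = spec.subject_ids()
    frame = pd.DataFrame(data, index=pd.Index(ids, name="subject_id"))
    return frame, pd.Series(labels, index=frame.index, name="group")


def _sample_matrix(template: RoutineTemplate, n_days: int, category: str,
                   noise_flip_prob: float,
                   rng: np.random.Generator) -> BehaviorMatrix:
    columns = behavior_columns(default_lexicon(category),
                               default_scheme(category))
    day_types = rng.choice(len(template.weights), size=n_days,
                           p=template.weights)
    values = (rng.random((n_days, len(columns)))
              < template.probs[day_types]).astype(float)
    if noise_flip_prob > 0:
        flips = rng.random(values.shape) < noise_flip_prob
        values = np.abs(values - flips.astype(float))
    return BehaviorMatrix(category=category,
                          row_labels=list(range(1, n_days + 1)),
                          col_labels=columns, values=values)


def sample_behavior_matrices(spec: CohortSpec, labels: pd.Series,
                             rng: np.random.Generator | None = None
                             ) -> dict[str, dict[str, BehaviorMatrix]]:
    """Per-subject activity and diet matrices drawn from group templates."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    templates = spec.templates()
    out: dict[str, dict[str, BehaviorMatrix]] = {ACTIVITY: {}, DIET: {}}
    for sid, group in labels.items():
        for category in (ACTIVITY, DIET):
            out[category][sid] = _sample_matrix(
                templates[(int(group), category)], spec.days_per_subject,
                category, spec.noise_flip_prob, rng)
    return out


@dataclass
class Cohort:
    """A generated cohort: indicators, labels, and behavior matrices."""

    spec: CohortSpec
    indicators: pd.DataFrame
    labels: pd.Series
    matrices: dict[str, dict[str, BehaviorMatrix]]

    def psis_by_space(self) -> dict[str, pd.DataFrame]:
        """Per-space subjects x H frame of average behaviors."""
        out = {}
        for category, per_subject in self.matrices.items():
            gm = group_behavior_matrix(per_subject,
                                       subject_ids=list(self.labels.index))
            out[category] = gm.to_frame()
        return out


def generate_cohort(spec: CohortSpec | None = None,
                    out_dir: str | Path | None = None,
                    seed: int | None = None) -> Cohort:
    """Generate a full synthetic cohort, optionally writing it to disk.

    Deterministic given the seed.  When ``out_dir`` is given, writes
    ``indicators.csv``, one ``behavior_<subject>_<category>.csv`` per
    matrix, and ``truth.json`` recording the labels and generator
    parameters for recovery tests.
    """
    spec = spec if spec is not None else CohortSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)
    indicators, labels = sample_health_indicators(spec, rng)
    matrices = sample_behavior_matrices(spec, labels, rng)
    cohort = Cohort(spec=spec, indicators=indicators, labels=labels,
                    matrices=matrices)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        indicators.to_csv(out / "indicators.csv")
        for category, per_subject in matrices.items():
            for sid, matrix in per_subject.items():
                matrix.to_csv(out / f"behavior_{sid}_{category}.csv")
        truth = {
            "seed": spec.seed,
            "labels": {str(s): int(g) for s, g in labels.items()},
            "group_shift_sd": spec.group_shift_sd,
            "noise_flip_prob": spec.noise_flip_prob,
            "diet_sparsity": spec.diet_sparsity,
            "templates": {
                f"{g}_{cat}": {"probs": t.probs.tolist(),
                               "weights": t.weights.tolist()}
                for (g, cat), t in spec.templates().items()},
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return cohort


def diary_entries_for_row(subject_id: str, day_index: int, category: str,
                          row: np.ndarray,
                          rng: np.random.Generator) -> list[DiaryEntry]:
    """Free-text diary entries realizing one binary behavior row.

    Each active (class, period) cell becomes one annotation whose text is
    a random word from the class vocabulary, timed inside the period
    (activity entries get an interval contained in the period).  Running
    the ingest pipeline on these entries reproduces the row exactly.
    """
    lexicon = default_lexicon(category)
    scheme = default_scheme(category)
    columns = behavior_columns(lexicon, scheme)
    by_class: dict[str, list[str]] = {}
    for word, cls in lexicon.word_map.items():
        by_class.setdefault(cls, []).append(word)
    bounds = {label: (start, end) for label, start, end in scheme.boundaries}
    entries = []
    for idx in np.flatnonzero(row):
        cls, period = columns[idx].rsplit("_", 1)
        start, end = bounds[period]
        word = sorted(by_class[cls])[rng.integers(len(by_class[cls]))]
        if category == ACTIVITY:
            t0 = int(rng.integers(start, end - 1))
            t1 = int(rng.integers(t0 + 1, end + 1))
            entry = DiaryEntry(subject_id, day_index, category,
                               float(t0), float(t1), word)
        else:
            t = int(rng.integers(start, end))
            entry = DiaryEntry(subject_id, day_index, category,
                               float(t), None, word)
        entries.append(entry)
    return entries
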