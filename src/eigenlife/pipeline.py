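"""End-to-end orchestration of the double-layer analysis.

Runs the full sequence on a cohort — indicator clustering, per-subject
and per-group eigenmodels, partial-day prediction, day and subject
similarities, distance-based membership classification, and the
shuffle-null validation — writing all reports (JSON/CSV) and figures
into an output directory.  Deterministic given the inputs and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import BehaviorMatrix
from .clustering import IndicatorClustering, ClusteringResults
from .eigen import EigenBehavior, cv_prediction_accuracy
from .lexicons import ACTIVITY, DIET
from .similarity import (classify_membership, day_distance_matrix,
                         day_index_vector, individual_pair_distances,
                         overlap_percentage)
from .synthetic import Cohort, CohortSpec, generate_cohort
from .validation import compare_observed_to_null, null_distance_distributions
from .viz import dartboard_coordinates, plot_dartboard, plot_null_distributions


@dataclass
class PipelineConfig:
    """Inputs and knobs for a full run.

    Either ``data_dir`` points at an ingested dataset (indicators.csv +
    behavior_<subject>_<category>.csv files) or a synthetic cohort is
    generated from ``synthetic`` (default).
    """

    out_dir: str | Path = "dlm_output"
    data_dir: str | Path | None = None
    synthetic: CohortSpec | None = None
    categories: tuple[str, ...] = (ACTIVITY, DIET)
    variability_threshold: float = 0.9
    n_shuffles: int = 100
    k_range: list[int] | None = None
    seed: int = 0
    figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if synth is not None:
            cfg.synthetic = CohortSpec(**synth)
        if "categories" in raw:
            cfg.categories = tuple(raw["categories"])
        return cfg


def load_cohort(data_dir: str | Path) -> Cohort:
    """Load an ingested dataset laid out as generate_cohort writes it."""
    data_dir = Path(data_dir)
    indicators = pd.read_csv(data_dir / "indicators.csv", index_col=0)
    matrices: dict[str, dict[str, BehaviorMatrix]] = {}
    for path in sorted(data_dir.glob("behavior_*_*.csv")):
        _, sid, category = path.stem.split("_", 2)
        matrices.setdefault(category, {})[sid] = BehaviorMatrix.from_csv(
            path, category)
    truth_path = data_dir / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        labels = pd.Series({s: int(g) for s, g in truth["labels"].items()},
                           name="group").reindex(indicators.index)
    else:
        labels = pd.Series(np.full(len(indicators), -1),
                           index=indicators.index, name="group")
    return Cohort(spec=CohortSpec(n_subjects=len(indicators)),
                  indicators=indicators, labels=labels, matrices=matrices)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all analysis stages and write the report bundle.

    Returns the report dictionary that is also written to
    ``<out_dir>/report.json``.  Any stage failure raises with the stage
    name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}
    stage = "load"
    try:
        if config.data_dir is not None:
            cohort = load_cohort(config.data_dir)
        else:
            spec = config.synthetic or CohortSpec(seed=config.seed)
            cohort = generate_cohort(spec, out_dir=out / "cohort")
        categories = [c for c in config.categories if c in cohort.matrices]

        stage = "cluster"
        clustering = IndicatorClustering(cohort.indicators).fit(
            k_range=config.k_range, random_state=config.seed)
        report["clustering"] = clustering.to_dict()
        (out / "clustering.json").write_text(
            json.dumps(clustering.to_dict(), indent=2))
        labels = clustering.labels

        psis_by_space = {c: p for c, p in cohort.psis_by_space().items()
                         if c in categories}

        stage = "eigenmodels"
        report["primary_counts"] = _eigen_stage(cohort, psis_by_space,
                                                labels, config, out)

        stage = "prediction"
        report["prediction"] = _prediction_stage(cohort, categories,
                                                 config, out)

        stage = "day_similarity"
        report["day_overlap"] = _day_similarity_stage(cohort, categories,
                                                      config, out)

        stage = "individual_similarity"
        _individual_similarity_stage(psis_by_space, labels, config, out)

        stage = "membership"
        if labels.value_counts().min() >= 3:
            membership = classify_membership(
                psis_by_space, labels,
                threshold=config.variability_threshold,
                random_state=config.seed)
            report["membership_accuracy"] = membership.accuracies
            membership.predictions.to_csv(out / "membership.csv")

        stage = "validation"
        nd = null_distance_distributions(
            psis_by_space, labels, n_shuffles=config.n_shuffles,
            seed=config.seed, threshold=config.variability_threshold)
        comparison = compare_observed_to_null(nd)
        comparison.to_csv(out / "validation.csv")
        report["validation"] = {
            stat: {"observed": row["observed"],
                   "percentile": row["percentile"],
                   "outside_bulk": bool(row["outside_bulk"])}
            for stat, row in comparison.iterrows()}
        if config.figures:
            plot_null_distributions(nd, path=out / "validation.png")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _eigen_stage(cohort: Cohort, psis_by_space, labels, config,
                 out: Path) -> dict:
    counts: dict = {"individual": {}, "group": {}}
    for category, per_subject in cohort.matrices.items():
        if category not in psis_by_space:
            continue
        counts["individual"][category] = {}
        for sid, matrix in per_subject.items():
            res = EigenBehavior(matrix).fit()
            counts["individual"][category][sid] = (
                res.primary_count(config.variability_threshold)
                if res.rank else 0)
        counts["group"][category] = {}
        psis = psis_by_space[category]
        for g in sorted(labels.unique()):
            members = labels.index[labels == g]
            res = EigenBehavior(psis.loc[members].to_numpy()).fit()
            counts["group"][category][int(g)] = (
                res.primary_count(config.variability_threshold)
                if res.rank else 0)
    (out / "primary_counts.json").write_text(json.dumps(counts, indent=2))
    return counts


def _prediction_stage(cohort: Cohort, categories, config, out: Path) -> dict:
    rows, summary = [], {}
    for category in categories:
        accs = []
        for sid, matrix in cohort.matrices[category].items():
            result = cv_prediction_accuracy(
                matrix, threshold=config.variability_threshold)
            accs.append(result.mean_accuracy)
            for day, acc in zip(matrix.row_labels, result.per_day):
                rows.append({"subject_id": sid, "category": category,
                             "day": day, "accuracy": acc})
        summary[category] = float(np.mean(accs))
    pd.DataFrame(rows).to_csv(out / "prediction.csv", index=False)
    return summary


def _day_similarity_stage(cohort: Cohort, categories, config,
                          out: Path) -> dict:
    overlaps = {}
    if ACTIVITY in categories and DIET in categories:
        rows = []
        for sid in cohort.matrices[ACTIVITY]:
            vectors = {}
            for category in (ACTIVITY, DIET):
                dist = day_distance_matrix(
                    cohort.matrices[category][sid],
                    threshold=config.variability_threshold)
                vectors[category] = day_index_vector(dist)
            overlap = overlap_percentage(vectors[DIET], vectors[ACTIVITY])
            overlaps[sid] = overlap
            rows.append({"subject_id": sid, "overlap": overlap,
                         "diet_index": list(map(int, vectors[DIET])),
                         "activity_index": list(map(int, vectors[ACTIVITY]))})
        pd.DataFrame(rows).to_csv(out / "day_overlap.csv", index=False)
    return overlaps


def _individual_similarity_stage(psis_by_space, labels, config,
                                 out: Path) -> None:
    from .eigen import EigenBehavior

    for category, psis in psis_by_space.items():
        for g in sorted(labels.unique()):
            members = labels.index[labels == g]
            res = EigenBehavior(psis.loc[members].to_numpy()).fit()
            dist = individual_pair_distances(
                res, psis.to_numpy(),
                threshold=config.variability_threshold)
            frame = pd.DataFrame(dist, index=psis.index, columns=psis.index)
            frame.to_csv(out / f"pair_distances_{category}_g{g}.csv")
            if config.figures and len(psis.index) > 1:
                center = psis.index[0]
                layout = dartboard_coordinates(frame[center], center, labels)
                plot_dartboard(layout, projected_group=int(g),
                               path=out / f"dartboard_{category}_g{g}.png")
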