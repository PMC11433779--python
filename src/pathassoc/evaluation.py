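"""Repeated-CV evaluation with per-pathway confusion accounting.

Two aggregation modes are kept strictly separate and are not comparable
like-for-like:

* *per-iteration metrics* — accuracy, precision, recall, F1 and MCC over
  each CV iteration's whole test fold; these support a mean +/- SD across
  iterations.
* *overall MCC* — per-pathway (or per-level) confusion matrices summed
  across all iterations first, then a single MCC from the summed matrix.
  Small pathways rarely yield a valid per-iteration MCC (zero cells), so
  summation is the only sound pathway-granularity statistic; no SD exists
  at that granularity.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import CrossJoinDataset, Level, stratified_split
from .model import MLPConfig, build_model, classify, predict_scores, train

__all__ = [
    "ConfusionCounts",
    "IterationReport",
    "PathwayReport",
    "confusion",
    "mcc",
    "accuracy",
    "precision",
    "recall",
    "f1",
    "run_cv",
    "RepeatedCV",
    "CVResults",
    "overall_mcc_by_pathway",
    "overall_mcc_by_level",
    "mcc_vs_size_correlation",
    "evaluation_size_threshold_curve",
    "training_filter_experiment",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Standard 2x2 counts from equal-length binary vectors."""
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} vs {len(y_pred)}")
    if len(y_true) == 0:
        raise ValueError("confusion requires at least one pair")
    t = y_true.astype(bool)
    p = y_pred.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 by convention when any marginal
    factor of the denominator is zero (exact integer arithmetic inside)."""
    denom2 = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom2 == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom2)


def accuracy(c: ConfusionCounts) -> float:
    return (c.tp + c.tn) / c.total if c.total else 0.0


def precision(c: ConfusionCounts) -> float:
    d = c.tp + c.fp
    return c.tp / d if d else 0.0


def recall(c: ConfusionCounts) -> float:
    d = c.tp + c.fn
    return c.tp / d if d else 0.0


def f1(c: ConfusionCounts) -> float:
    d = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / d if d else 0.0


@dataclass
class IterationReport:
    """Metrics over one CV iteration's full test fold plus one confusion
    cell per pathway (zero counts when the pathway had no test entries)."""

    iteration: int
    overall: ConfusionCounts
    per_pathway: dict[str, ConfusionCounts]

    @property
    def metrics(self) -> dict[str, float]:
        c = self.overall
        return {
            "accuracy": accuracy(c),
            "precision": precision(c),
            "recall": recall(c),
            "f1": f1(c),
            "mcc": mcc(c),
        }


@dataclass
class PathwayReport:
    pathway_id: str
    level: str
    size_metabolites: int
    size_atoms: int
    confusion: ConfusionCounts
    overall_mcc: float


def run_cv(
    dataset: CrossJoinDataset,
    model_config: MLPConfig,
    n_iterations: int,
    base_seed: int = 0,
    n_folds: int = 10,
    scorer: Callable[[CrossJoinDataset, np.ndarray], np.ndarray] | None = None,
    scale_per_fold: bool = False,
    progress: Callable[[int], None] | None = None,
    checkpoint_dir: str | None = None,
) -> list[IterationReport]:
    """Repeated stratified CV: per iteration a fresh 10-fold split (seed =
    base_seed + iteration), training on 9 folds and predicting the one
    designated test fold.

    ``scorer``, when given, replaces training entirely (stub model for
    protocol-accounting runs): it maps (dataset, entry indices) -> scores.
    ``scale_per_fold`` refits min/max scaling on the training entries only
    (leakage-free variant).  With ``checkpoint_dir`` each iteration's report
    is persisted as JSON and an interrupted run resumes at iteration
    granularity.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    pathway_ids = [p.pathway_id for p in dataset.pathways]
    ckpt = Path(checkpoint_dir) if checkpoint_dir is not None else None
    if ckpt is not None:
        ckpt.mkdir(parents=True, exist_ok=True)
    reports: list[IterationReport] = []
    for it in range(n_iterations):
        if ckpt is not None:
            path = ckpt / f"iteration_{it:04d}.json"
            if path.exists():
                reports.append(_report_from_json(path))
                continue
        plan = stratified_split(
            dataset.labels, n_folds=n_folds, seed=base_seed + it, iteration=it
        )
        test_idx = plan.test_indices()
        if scorer is not None:
            scores = scorer(dataset, test_idx)
        else:
            train_idx = plan.train_indices()
            ds = dataset
            if scale_per_fold:
                ds = _rescaled_on_train(dataset, train_idx)
            cfg = model_config if model_config.seed == base_seed + it else (
                MLPConfig(**{**model_config.__dict__, "seed": base_seed + it})
            )
            tm = train(
                build_model(ds.input_width, cfg),
                ds.features(train_idx),
                ds.labels[train_idx],
            )
            scores = predict_scores(tm, ds.features(test_idx))
        preds = classify(scores, model_config.classification_threshold)
        y_true = dataset.labels[test_idx]
        overall = confusion(y_true, preds)
        pw_of = dataset.pathway_of_entries(test_idx)
        per_pathway: dict[str, ConfusionCounts] = {}
        for j, pid in enumerate(pathway_ids):
            mask = pw_of == j
            if mask.any():
                per_pathway[pid] = confusion(y_true[mask], preds[mask])
            else:
                per_pathway[pid] = ConfusionCounts()
        report = IterationReport(it, overall, per_pathway)
        if ckpt is not None:
            _report_to_json(report, ckpt / f"iteration_{it:04d}.json")
        reports.append(report)
        if progress is not None:
            progress(it)
    return reports


def _report_to_json(report: IterationReport, path: Path) -> None:
    def enc(c: ConfusionCounts) -> list[int]:
        return [c.tp, c.fp, c.tn, c.fn]

    path.write_text(json.dumps({
        "iteration": report.iteration,
        "overall": enc(report.overall),
        "per_pathway": {pid: enc(c) for pid, c in report.per_pathway.items()},
    }))


def _report_from_json(path: Path) -> IterationReport:
    raw = json.loads(path.read_text())
    dec = lambda v: ConfusionCounts(*v)  # noqa: E731
    return IterationReport(
        raw["iteration"], dec(raw["overall"]),
        {pid: dec(v) for pid, v in raw["per_pathway"].items()},
    )


def _rescaled_on_train(dataset: CrossJoinDataset, train_idx: np.ndarray) -> CrossJoinDataset:
    """Refit min/max scaling using only rows appearing in training entries."""
    from .featurization import FeatureMatrix, minmax_apply, minmax_fit

    met_idx, pw_idx = dataset.entry_pairs(train_idx)
    met_rows = np.unique(met_idx)
    pw_rows = np.unique(pw_idx)
    mm = dataset.metabolite_matrix
    pm = dataset.pathway_matrix
    met_fit = FeatureMatrix(
        [mm.row_ids[i] for i in met_rows], mm.vocabulary, mm.values[met_rows]
    )
    pw_fit = FeatureMatrix(
        [pm.row_ids[i] for i in pw_rows], pm.vocabulary, pm.values[pw_rows]
    )
    return CrossJoinDataset(
        minmax_apply(mm, minmax_fit(met_fit)),
        minmax_apply(pm, minmax_fit(pw_fit)),
        dataset.pathways,
        dataset.metabolite_atom_counts,
    )


def overall_mcc_by_pathway(
    reports: Sequence[IterationReport], dataset: CrossJoinDataset
) -> list[PathwayReport]:
    """Sum each pathway's confusion cells across iterations, then one MCC
    from the summed matrix."""
    if not reports:
        raise ValueError("need at least one iteration report")
    sizes = dataset.pathway_sizes().set_index("pathway_id")
    out: list[PathwayReport] = []
    for p in dataset.pathways:
        total = ConfusionCounts()
        for rep in reports:
            total = total + rep.per_pathway[p.pathway_id]
        row = sizes.loc[p.pathway_id]
        out.append(
            PathwayReport(
                p.pathway_id,
                p.level.value,
                int(row.size_metabolites),
                int(row.size_atoms),
                total,
                mcc(total),
            )
        )
    return out


def overall_mcc_by_level(
    reports: Sequence[IterationReport], dataset: CrossJoinDataset, level: Level | str
) -> float:
    """MCC of the confusion matrix summed over all pathways of one hierarchy
    level and all iterations."""
    level = Level(level)
    ids = {p.pathway_id for p in dataset.pathways if p.level == level}
    if not ids:
        raise ValueError(f"no pathways at level {level.value}")
    total = ConfusionCounts()
    for rep in reports:
        for pid in ids:
            total = total + rep.per_pathway[pid]
    return mcc(total)


def mcc_vs_size_correlation(pathway_reports: Sequence[PathwayReport]) -> pd.DataFrame:
    """Correlations between pathway size and overall MCC, four rows:
    Spearman on raw counts and Pearson on log10 counts, for both size
    metrics (member metabolites; summed non-hydrogen atoms)."""
    if len(pathway_reports) < 3:
        raise ValueError("need at least 3 pathways for a correlation")
    mccs = np.array([p.overall_mcc for p in pathway_reports])
    rows = []
    for metric, attr in [("metabolites", "size_metabolites"), ("atoms", "size_atoms")]:
        sizes = np.array([getattr(p, attr) for p in pathway_reports], dtype=float)
        if np.any(sizes <= 0):
            raise ValueError(f"zero-size pathway under log10 for metric {metric!r}")
        for method, x in [("spearman_regular", sizes), ("pearson_log10", np.log10(sizes))]:
            if np.allclose(x, x[0]) or np.allclose(mccs, mccs[0]):
                coef, p_value = 0.0, 1.0  # degenerate input convention
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    if method.startswith("spearman"):
                        coef, p_value = stats.spearmanr(x, mccs)
                    else:
                        coef, p_value = stats.pearsonr(x, mccs)
                if not np.isfinite(coef):
                    coef, p_value = 0.0, 1.0
            rows.append((metric, method, float(coef), float(p_value)))
    return pd.DataFrame(rows, columns=["size_metric", "method", "coefficient", "p_value"])


def evaluation_size_threshold_curve(
    pathway_reports: Sequence[PathwayReport],
    thresholds: Sequence[int],
    size_metric: str = "metabolites",
) -> pd.DataFrame:
    """Overall MCC across pathways surviving each size threshold.

    The model is NOT retrained: already-summed confusions of the surviving
    pathways are re-summed per threshold.  Threshold 0 is the overall MCC
    across all pathways.  The curve truncates (with a warning) at the first
    threshold that removes every pathway.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be nondecreasing")
    attr = {"metabolites": "size_metabolites", "atoms": "size_atoms"}[size_metric]
    rows = []
    for thr in thresholds:
        survivors = [p for p in pathway_reports if getattr(p, attr) >= thr]
        if not survivors:
            warnings.warn(
                f"threshold {thr} removes all pathways; curve truncated", stacklevel=2
            )
            break
        total = ConfusionCounts()
        for p in survivors:
            total = total + p.confusion
        rows.append((thr, mcc(total), len(survivors)))
    return pd.DataFrame(rows, columns=["threshold", "overall_mcc", "n_pathways"])


def training_filter_experiment(
    dataset: CrossJoinDataset,
    model_config: MLPConfig,
    thresholds: Sequence[int] = (3, 5, 7, 10, 12, 20, 50, 100),
    n_largest: int = 33,
    n_iterations: int = 1,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Retrain with pathways below each size threshold excluded from the
    TRAINING dataset, and score only the ``n_largest`` pathways (by member
    count, ties broken by pathway id) so the thresholds are comparable.

    Returns rows of (threshold, n pathways trained, overall MCC over the
    evaluation pathways).
    """
    from .dataset import cross_join, filter_by_size
    from .featurization import FeatureMatrix

    ranked = sorted(dataset.pathways, key=lambda p: (-p.size, p.pathway_id))
    eval_ids = {p.pathway_id for p in ranked[:n_largest]}
    rows = []
    for thr in thresholds:
        survivors, kept_mets = filter_by_size(dataset.pathways, thr)
        missing = eval_ids - {p.pathway_id for p in survivors}
        if missing:
            raise ValueError(
                f"threshold {thr} filters evaluation pathway(s) {sorted(missing)}"
            )
        mm = dataset.metabolite_matrix
        pm = dataset.pathway_matrix
        met_keep = [i for i, m in enumerate(mm.row_ids) if m in kept_mets]
        pw_keep = [i for i, p in enumerate(dataset.pathways) if p.pathway_id in
                   {q.pathway_id for q in survivors}]
        sub = cross_join(
            FeatureMatrix([mm.row_ids[i] for i in met_keep], mm.vocabulary, mm.values[met_keep]),
            FeatureMatrix([pm.row_ids[i] for i in pw_keep], pm.vocabulary, pm.values[pw_keep]),
            [dataset.pathways[i] for i in pw_keep],
            dataset.metabolite_atom_counts,
        )
        reports = run_cv(sub, model_config, n_iterations, base_seed=base_seed)
        total = ConfusionCounts()
        for rep in reports:
            for pid in eval_ids:
                total = total + rep.per_pathway[pid]
        rows.append((thr, len(survivors), mcc(total)))
    return pd.DataFrame(rows, columns=["threshold", "n_pathways_trained", "overall_mcc"])


# ---------------------------------------------------------------------------
# statsmodels-style wrapper
# ---------------------------------------------------------------------------


class RepeatedCV:
    """Evaluation protocol object: repeated stratified 10-fold CV of a
    :class:`~pathassoc.model.PathwayAssociationMLP` with one test fold per
    iteration.  ``run()`` returns :class:`CVResults`."""

    def __init__(
        self,
        model,
        n_iterations: int = 3,
        base_seed: int = 0,
        n_folds: int = 10,
        scale_per_fold: bool = False,
    ) -> None:
        self.model = model
        self.n_iterations = n_iterations
        self.base_seed = base_seed
        self.n_folds = n_folds
        self.scale_per_fold = scale_per_fold

    def run(self, scorer=None, progress=None, checkpoint_dir=None) -> "CVResults":
        reports = run_cv(
            self.model.dataset,
            self.model.config,
            self.n_iterations,
            base_seed=self.base_seed,
            n_folds=self.n_folds,
            scorer=scorer,
            scale_per_fold=self.scale_per_fold,
            progress=progress,
            checkpoint_dir=checkpoint_dir,
        )
        return CVResults(self.model.dataset, reports)


class CVResults:
    """Results of a repeated-CV evaluation.

    Attributes
    ----------
    iteration_metrics : DataFrame
        Per-iteration test-fold metrics (mean +/- SD material).
    pathway_reports : list of PathwayReport
        Summed confusions and overall MCC per pathway.
    """

    def __init__(self, dataset: CrossJoinDataset, reports: list[IterationReport]):
        self.dataset = dataset
        self.reports = reports
        self.pathway_reports = overall_mcc_by_pathway(reports, dataset)

    @property
    def iteration_metrics(self) -> pd.DataFrame:
        rows = [{"iteration": r.iteration, **r.metrics} for r in self.reports]
        return pd.DataFrame(rows)

    def mean_mcc(self) -> tuple[float, float]:
        vals = self.iteration_metrics["mcc"]
        return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    def overall_mcc(self) -> float:
        total = ConfusionCounts()
        for p in self.pathway_reports:
            total = total + p.confusion
        return mcc(total)

    def level_mcc(self, level: Level | str) -> float:
        return overall_mcc_by_level(self.reports, self.dataset, level)

    def pathway_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pathway_id": p.pathway_id,
                    "level": p.level,
                    "size_metabolites": p.size_metabolites,
                    "size_atoms": p.size_atoms,
                    "tp": p.confusion.tp,
                    "fp": p.confusion.fp,
                    "tn": p.confusion.tn,
                    "fn": p.confusion.fn,
                    "overall_mcc": p.overall_mcc,
                }
                for p in self.pathway_reports
            ]
        )

    def size_correlations(self) -> pd.DataFrame:
        return mcc_vs_size_correlation(self.pathway_reports)

    def size_threshold_curve(self, thresholds, size_metric="metabolites") -> pd.DataFrame:
        return evaluation_size_threshold_curve(self.pathway_reports, thresholds, size_metric)

    def plot_mcc_vs_size(self, ax=None, log10: bool = True, size_metric: str = "metabolites"):
        """Scatter of per-pathway overall MCC against pathway size."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        attr = {"metabolites": "size_metabolites", "atoms": "size_atoms"}[size_metric]
        x = np.array([getattr(p, attr) for p in self.pathway_reports], dtype=float)
        y = [p.overall_mcc for p in self.pathway_reports]
        if log10:
            x = np.log10(x)
            ax.set_xlabel(f"log10 pathway size ({size_metric})")
        else:
            ax.set_xlabel(f"pathway size ({size_metric})")
        ax.scatter(x, y, s=12)
        ax.set_ylabel("overall MCC")
        return ax

    def summary(self) -> str:
        mean, sd = self.mean_mcc()
        m = self.iteration_metrics
        lines = [
            "Repeated-CV evaluation — summary",
            "=" * 44,
            f"iterations             {len(self.reports):>12}",
            f"pathways               {self.dataset.n_pathways:>12}",
            f"entries                {self.dataset.n_entries:>12,}",
            f"mean MCC (per-iter)    {mean:>12.3f} +/- {sd:.3f}",
            f"overall MCC (summed)   {self.overall_mcc():>12.3f}",
            f"mean accuracy          {m['accuracy'].mean():>12.3f}",
            f"mean F1                {m['f1'].mean():>12.3f}",
        ]
        for level in (Level.L2, Level.L3):
            if any(p.level == level for p in self.dataset.pathways):
                lines.append(
                    f"overall MCC, {level.value}        {self.level_mcc(level):>12.3f}"
                )
        return "\n".join(lines)
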