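"""Confusion accounting, MCC aggregation, and the size analyses."""

import math

import numpy as np
import pandas as pd
import pytest

import pathassoc as pa
from pathassoc.evaluation import (
    ConfusionCounts,
    IterationReport,
    PathwayReport,
    confusion,
    evaluation_size_threshold_curve,
    mcc,
    mcc_vs_size_correlation,
    overall_mcc_by_level,
    overall_mcc_by_pathway,
    run_cv,
    training_filter_experiment,
)
from pathassoc.model import MLPConfig


def brute_force_confusion(y_true, y_pred) -> ConfusionCounts:
    """Oracle: explicit pair-by-pair counting."""
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if t and p:
            tp += 1
        elif not t and p:
            fp += 1
        elif not t and not p:
            tn += 1
        else:
            fn += 1
    return ConfusionCounts(tp, fp, tn, fn)


class TestConfusion:
    def test_perfect_agreement(self):
        c = confusion([1, 0, 1, 0], [1, 0, 1, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_all_missed_positives(self):
        c = confusion([1, 1], [0, 0])
        assert c.fn == 2 and c.tp == 0

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            t = rng.integers(0, 2, 50)
            p = rng.integers(0, 2, 50)
            assert confusion(t, p) == brute_force_confusion(t, p)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            confusion([1], [1, 0])

    def test_counts_are_summable(self):
        a = ConfusionCounts(1, 2, 3, 4)
        b = ConfusionCounts(5, 6, 7, 8)
        assert a + b == ConfusionCounts(6, 8, 10, 12)


class TestMCC:
    def test_perfect_classifier(self):
        assert mcc(ConfusionCounts(tp=5, tn=5)) == 1.0

    def test_direct_formula_example(self):
        c = ConfusionCounts(tp=3, fp=1, tn=4, fn=2)
        assert mcc(c) == pytest.approx(10 / math.sqrt(600), abs=1e-12)

    def test_degenerate_all_negative_predictions(self):
        assert mcc(ConfusionCounts(tn=5, fn=5)) == 0.0

    def test_agrees_with_sklearn_oracle(self):
        """Dual route: package MCC vs sklearn's on reconstructed labels."""
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(1)
        for _ in range(100):
            tp, fp, tn, fn = (int(x) for x in rng.integers(0, 20, 4))
            if tp + fp + tn + fn == 0:
                continue
            y_true = [1] * tp + [0] * fp + [0] * tn + [1] * fn
            y_pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
            expected = (
                0.0 if len(set(y_true)) < 2 or len(set(y_pred)) < 2
                else matthews_corrcoef(y_true, y_pred)
            )
            assert mcc(ConfusionCounts(tp, fp, tn, fn)) == pytest.approx(
                expected, abs=1e-12
            )


def stub_scorer_from_labels(noise=0.3, seed=0):
    """Scores = true label flipped with probability `noise`."""
    rng = np.random.default_rng(seed)

    def scorer(dataset, idx):
        flip = rng.random(len(idx)) < noise
        return np.where(flip, 1 - dataset.labels[idx], dataset.labels[idx]).astype(float)

    return scorer


class TestRunCV:
    def test_stub_run_produces_finite_metrics(self, tiny_universe):
        reports = run_cv(
            tiny_universe["dataset"], MLPConfig(), 1, scorer=stub_scorer_from_labels()
        )
        assert len(reports) == 1
        assert all(np.isfinite(v) for v in reports[0].metrics.values())

    def test_cell_count_is_iterations_times_pathways(self, tiny_universe):
        ds = tiny_universe["dataset"]
        reports = run_cv(ds, MLPConfig(), 3, scorer=stub_scorer_from_labels())
        cells = sum(len(r.per_pathway) for r in reports)
        assert cells == 3 * ds.n_pathways

    def test_partition_per_pathway_sums_to_overall(self, tiny_universe):
        reports = run_cv(
            tiny_universe["dataset"], MLPConfig(), 2, scorer=stub_scorer_from_labels()
        )
        for rep in reports:
            total = ConfusionCounts()
            for c in rep.per_pathway.values():
                total = total + c
            assert total == rep.overall

    def test_checkpoint_resume_reproduces_reports(self, tiny_universe, tmp_path):
        ds = tiny_universe["dataset"]
        scorer = stub_scorer_from_labels(seed=5)
        full = run_cv(ds, MLPConfig(), 2, scorer=scorer, checkpoint_dir=str(tmp_path))
        # resume: first two iterations come from disk, scorer state untouched
        resumed = run_cv(
            ds, MLPConfig(), 2, scorer=stub_scorer_from_labels(seed=99),
            checkpoint_dir=str(tmp_path),
        )
        for a, b in zip(full, resumed):
            assert a.overall == b.overall
            assert a.per_pathway == b.per_pathway


class TestOverallMCC:
    def test_summed_matrix_example(self, tiny_universe):
        ds = tiny_universe["dataset"]
        pid = ds.pathways[0].pathway_id
        reports = [
            IterationReport(0, ConfusionCounts(tp=1, tn=1),
                            {p.pathway_id: ConfusionCounts() for p in ds.pathways}),
            IterationReport(1, ConfusionCounts(tn=1, fn=1),
                            {p.pathway_id: ConfusionCounts() for p in ds.pathways}),
        ]
        reports[0].per_pathway[pid] = ConfusionCounts(tp=1, tn=1)
        reports[1].per_pathway[pid] = ConfusionCounts(tn=1, fn=1)
        out = overall_mcc_by_pathway(reports, ds)
        rep = next(r for r in out if r.pathway_id == pid)
        # summed: tp=1, tn=2, fn=1 -> 2 / sqrt(1*2*2*3)
        assert rep.overall_mcc == pytest.approx(2 / math.sqrt(12), abs=1e-12)

    def test_level_with_single_pathway_equals_pathway_mcc(self):
        from pathassoc.dataset import Level, Pathway, cross_join
        from test_dataset import unit_matrix

        p2 = Pathway("L2_X", Level.L2, {"m"})
        ds = cross_join(unit_matrix(["m"]), unit_matrix(["L2_X"]), [p2])
        reports = [IterationReport(0, ConfusionCounts(tp=2, fp=1, tn=3, fn=1),
                                   {"L2_X": ConfusionCounts(tp=2, fp=1, tn=3, fn=1)})]
        by_pathway = overall_mcc_by_pathway(reports, ds)
        assert overall_mcc_by_level(reports, ds, Level.L2) == by_pathway[0].overall_mcc

    def test_summation_commutes(self, tiny_universe):
        ds = tiny_universe["dataset"]
        reports = run_cv(ds, MLPConfig(), 3, scorer=stub_scorer_from_labels(seed=2))
        fwd = overall_mcc_by_level(reports, ds, "L3")
        rev = overall_mcc_by_level(list(reversed(reports)), ds, "L3")
        assert fwd == rev

    def test_unknown_level_errors(self, tiny_universe):
        reports = run_cv(
            tiny_universe["dataset"], MLPConfig(), 1, scorer=stub_scorer_from_labels()
        )
        with pytest.raises(ValueError):
            overall_mcc_by_level(reports, tiny_universe["dataset"], "L4")


def pathway_report(pid, size, mcc_value, atoms=None, level="L3"):
    return PathwayReport(pid, level, size, atoms or size * 10,
                         ConfusionCounts(tp=1, tn=1), mcc_value)


class TestSizeCorrelations:
    def test_monotone_link_gives_spearman_one(self):
        reports = [pathway_report(f"p{i}", 3 + i, 0.1 * i) for i in range(8)]
        table = mcc_vs_size_correlation(reports)
        row = table[(table.size_metric == "metabolites") & (table.method == "spearman_regular")]
        assert row.coefficient.iloc[0] == pytest.approx(1.0)

    def test_constant_mcc_handled_without_crash(self):
        reports = [pathway_report(f"p{i}", 3 + i, 0.5) for i in range(5)]
        table = mcc_vs_size_correlation(reports)
        assert (table.coefficient == 0.0).all()
        assert (table.p_value == 1.0).all()

    def test_log_link_favors_pearson_log10(self):
        rng = np.random.default_rng(0)
        sizes = np.unique(rng.integers(3, 3000, 40))[:20]
        mccs = 0.2 * np.log10(sizes) + rng.normal(0, 0.02, len(sizes))
        reports = [
            pathway_report(f"p{i}", int(s), float(m))
            for i, (s, m) in enumerate(zip(sizes, mccs))
        ]
        table = mcc_vs_size_correlation(reports).set_index(["size_metric", "method"])
        pearson = table.loc[("metabolites", "pearson_log10"), "coefficient"]
        assert pearson > 0.97

    def test_zero_size_pathway_errors(self):
        reports = [pathway_report("p0", 3, 0.5), pathway_report("p1", 4, 0.6),
                   PathwayReport("p2", "L3", 0, 0, ConfusionCounts(tp=1), 0.1)]
        with pytest.raises(ValueError, match="log10"):
            mcc_vs_size_correlation(reports)


class TestSizeThresholdCurve:
    def _reports(self):
        # small pathway entirely wrong, large pathway entirely right
        small = PathwayReport("small", "L3", 3, 30, ConfusionCounts(fp=3, fn=3), 0.0)
        big = PathwayReport("big", "L3", 50, 500, ConfusionCounts(tp=40, tn=40), 1.0)
        return [small, big]

    def test_threshold_zero_equals_all_pathway_overall(self):
        reports = self._reports()
        curve = evaluation_size_threshold_curve(reports, [0])
        total = ConfusionCounts(tp=40, tn=40, fp=3, fn=3)
        assert curve.overall_mcc.iloc[0] == mcc(total)

    def test_filtering_the_bad_small_pathway_raises_mcc(self):
        curve = evaluation_size_threshold_curve(self._reports(), [0, 10])
        assert curve.overall_mcc.iloc[1] > curve.overall_mcc.iloc[0]
        assert curve.n_pathways.tolist() == [2, 1]

    def test_threshold_above_max_truncates_with_warning(self):
        with pytest.warns(UserWarning, match="truncated"):
            curve = evaluation_size_threshold_curve(self._reports(), [0, 100])
        assert len(curve) == 1

    def test_unsorted_thresholds_error(self):
        with pytest.raises(ValueError):
            evaluation_size_threshold_curve(self._reports(), [10, 0])


class TestTrainingFilterExperiment:
    def test_stub_free_smoke_and_threshold_columns(self, tiny_universe):
        ds = tiny_universe["dataset"]
        cfg = MLPConfig(max_epochs=15, hidden_size=16, n_hidden_layers=1)
        table = training_filter_experiment(
            ds, cfg, thresholds=(0, 3), n_largest=2, n_iterations=1
        )
        assert list(table.columns) == ["threshold", "n_pathways_trained", "overall_mcc"]
        assert len(table) == 2
        assert table.n_pathways_trained.iloc[0] >= table.n_pathways_trained.iloc[1]

    def test_filtering_an_eval_pathway_is_an_error(self, tiny_universe):
        ds = tiny_universe["dataset"]
        too_high = max(p.size for p in ds.pathways)
        with pytest.raises(ValueError, match="filters evaluation pathway"):
            training_filter_experiment(
                ds, MLPConfig(max_epochs=5), thresholds=(too_high,),
                n_largest=len(ds.pathways), n_iterations=1,
            )
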