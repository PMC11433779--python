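"""Feature matrices, pathway aggregation, and the two normalizations."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathassoc.chemgraph import AtomColor, ColorCountVector
from pathassoc.featurization import (
    FeatureMatrix,
    FeatureVocabulary,
    aggregate_pathways,
    bond_count_normalize,
    bond_count_normalize_matrix,
    build_matrix,
    dedupe_columns,
    minmax_apply,
    minmax_fit,
)


def vec(**kw) -> ColorCountVector:
    """Shorthand: vec(C0=2, O1=1) -> counts of AtomColor(0,'C'), (1,'O')."""
    counts = Counter()
    for key, count in kw.items():
        counts[AtomColor(int(key[-1]), key[:-1])] = count
    return ColorCountVector(counts)


class TestBuildMatrix:
    def test_single_vector(self):
        m = build_matrix({"a": vec(C0=2)})
        assert m.values.tolist() == [[2.0]]
        assert m.row_ids == ["a"]

    def test_union_vocabulary_sorted(self):
        m = build_matrix({"a": vec(x0=1), "b": vec(x0=2, y1=1)})
        assert m.values.tolist() == [[1, 0], [2, 1]]
        assert [c.key for c in m.vocabulary.colors] == ["x", "y"]

    def test_disjoint_keys_block_structure(self):
        m = build_matrix({"a": vec(p0=1), "b": vec(q1=3)})
        assert m.values.tolist() == [[1, 0], [0, 3]]

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            build_matrix({})


class TestAggregatePathways:
    def test_single_member_identity(self):
        v = vec(C0=4, N1=1)
        out = aggregate_pathways({"p": {"a"}}, {"a": v})
        assert out["p"] == v

    def test_elementwise_sum(self):
        out = aggregate_pathways(
            {"p": {"a", "b"}}, {"a": vec(x0=1), "b": vec(x0=2, y1=1)}
        )
        assert out["p"] == vec(x0=3, y1=1)

    def test_shared_metabolite_contributes_fully_to_both(self):
        vecs = {"a": vec(x0=1), "b": vec(x0=1)}
        out = aggregate_pathways({"p": {"a", "b"}, "q": {"a"}}, vecs)
        assert out["p"] == vec(x0=2)
        assert out["q"] == vec(x0=1)

    def test_unresolvable_member_errors_with_pathway(self):
        with pytest.raises(KeyError, match="p1"):
            aggregate_pathways({"p1": {"missing"}}, {"a": vec(x0=1)})

    def test_linearity_over_disjoint_member_sets(self):
        rng = np.random.default_rng(0)
        vecs = {
            f"m{i}": vec(**{f"c{r}": int(rng.integers(1, 5)) for r in range(4)})
            for i in range(6)
        }
        joint = aggregate_pathways({"p": {"m0", "m1", "m2", "m3"}}, vecs)["p"]
        left = aggregate_pathways({"p": {"m0", "m1"}}, vecs)["p"]
        right = aggregate_pathways({"p": {"m2", "m3"}}, vecs)["p"]
        assert joint == left + right


class TestDedupeColumns:
    def _matrix(self, values):
        values = np.asarray(values, dtype=float)
        vocab = FeatureVocabulary(
            tuple(AtomColor(0, f"c{j:03d}") for j in range(values.shape[1]))
        )
        return FeatureMatrix([f"r{i}" for i in range(values.shape[0])], vocab, values)

    def test_identical_columns_keep_first(self):
        m = dedupe_columns(self._matrix([[1, 1], [2, 2]]))
        assert m.width == 1
        assert m.vocabulary.colors[0].key == "c000"
        assert m.column_provenance == {1: 0}

    def test_repeated_patterns_collapse_to_distinct(self):
        rng = np.random.default_rng(1)
        patterns = rng.integers(1, 9, size=(40, 12))
        cols = patterns[rng.integers(0, 40, size=100)]  # 100 cols, 40 patterns
        # ensure every pattern appears
        cols[:40] = patterns
        m = dedupe_columns(self._matrix(cols.T))
        assert m.width == 40

    def test_no_duplicates_unchanged(self):
        m0 = self._matrix([[1, 2], [3, 4]])
        m = dedupe_columns(m0)
        assert m.width == 2
        assert np.array_equal(m.values, m0.values)

    def test_zero_columns_removed(self):
        m = dedupe_columns(self._matrix([[0, 1], [0, 2]]))
        assert m.width == 1

    def test_rows_remain_distinguishable(self):
        rng = np.random.default_rng(2)
        values = rng.integers(0, 3, size=(8, 30))
        m = dedupe_columns(self._matrix(values))
        before = {tuple(r) for r in values}
        after = {tuple(r) for r in m.values}
        assert len(after) == len(before)


class TestBondCountNormalize:
    radii = np.array([0, 1, 1, 2])

    def test_single_nonzero_per_group_becomes_one(self):
        row = bond_count_normalize(np.array([3.0, 0, 5.0, 2.0]), self.radii)
        assert row.tolist() == [1.0, 0.0, 1.0, 1.0]

    def test_direct_division(self):
        row = bond_count_normalize(np.array([0.0, 2.0, 2.0, 1.0]), self.radii)
        assert row.tolist() == [0.0, 0.5, 0.5, 1.0]

    def test_all_zero_row_stays_zero(self):
        row = bond_count_normalize(np.zeros(4), self.radii)
        assert row.tolist() == [0.0] * 4

    def test_negative_input_errors(self):
        with pytest.raises(ValueError):
            bond_count_normalize(np.array([-1.0, 0, 0, 0]), self.radii)

    def test_exponential_variant_is_true_softmax(self):
        row = bond_count_normalize(
            np.array([0.0, 1.0, 2.0, 3.0]), self.radii, exponential=True
        )
        expect = np.exp([1.0, 2.0]) / np.exp([1.0, 2.0]).sum()
        assert row[1] == pytest.approx(expect[0])
        assert row[2] == pytest.approx(expect[1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=8, max_size=8))
    def test_nonzero_groups_sum_to_one(self, counts):
        radii = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        row = bond_count_normalize(np.array(counts, dtype=float), radii)
        for r in range(4):
            mask = radii == r
            if np.any(np.array(counts)[mask]):
                assert abs(row[mask].sum() - 1.0) < 1e-9
            else:
                assert row[mask].sum() == 0.0


class TestMinMax:
    def _matrix(self, cols):
        values = np.asarray(cols, dtype=float).T
        vocab = FeatureVocabulary(
            tuple(AtomColor(0, f"c{j}") for j in range(values.shape[1]))
        )
        return FeatureMatrix([f"r{i}" for i in range(values.shape[0])], vocab, values)

    def test_direct_formula(self):
        m = self._matrix([[0.0, 5.0, 10.0]])
        out = minmax_apply(m, minmax_fit(m))
        assert out.values[:, 0].tolist() == [0.0, 0.5, 1.0]

    def test_constant_column_maps_to_zero(self):
        m = self._matrix([[3.0, 3.0]])
        out = minmax_apply(m, minmax_fit(m))
        assert out.values[:, 0].tolist() == [0.0, 0.0]

    def test_idempotent_on_already_scaled(self):
        m = self._matrix([[0.0, 0.25, 1.0]])
        once = minmax_apply(m, minmax_fit(m))
        twice = minmax_apply(once, minmax_fit(once))
        assert np.allclose(once.values, twice.values)

    def test_other_matrix_clipped_to_unit_interval(self):
        fit_on = self._matrix([[0.0, 2.0]])
        params = minmax_fit(fit_on)
        other = self._matrix([[-1.0, 5.0]])
        out = minmax_apply(other, params)
        assert out.values[:, 0].tolist() == [0.0, 1.0]

    def test_vocabulary_mismatch_errors(self):
        params = minmax_fit(self._matrix([[0.0, 1.0]]))
        other = FeatureMatrix(
            ["r0", "r1"],
            FeatureVocabulary((AtomColor(1, "zz"),)),
            np.zeros((2, 1)),
        )
        with pytest.raises(ValueError, match="vocabulary"):
            minmax_apply(other, params)

    def test_fitted_matrix_lands_exactly_in_unit_interval(self):
        rng = np.random.default_rng(9)
        m = self._matrix(rng.uniform(-4, 7, size=(5, 20)))
        out = minmax_apply(m, minmax_fit(m))
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0
        # every non-constant column attains both bounds
        for j in range(out.width):
            col = out.values[:, j]
            assert col.min() == 0.0 and col.max() == 1.0


def test_matrix_normalization_matches_rowwise(tiny_universe):
    from pathassoc.featurization import build_matrix

    m = build_matrix(tiny_universe["vectors"])
    norm = bond_count_normalize_matrix(m)
    i = 3
    row = bond_count_normalize(m.values[i], m.vocabulary.radii)
    assert np.allclose(norm.values[i], row)
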