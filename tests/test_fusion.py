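import math

import numpy as np
import pandas as pd
import pytest

from mscfs.fusion import (
    EvaluationResult,
    FusionWeights,
    binned_expression_correlation,
    cms_matrix,
    correlate,
    enumerate_weights,
    expression_similarity_matrix,
    fuse,
    grid_search,
    threshold_network,
)
from mscfs.io import AssociationTable, SimilarityMatrix
from mscfs.synthetic import SyntheticConfig, make_planted_fusion


def _sym(labels, off_diag):
    n = len(labels)
    v = np.full((n, n), np.nan)
    np.fill_diagonal(v, 1.0)
    for (i, j), x in off_diag.items():
        v[i, j] = v[j, i] = x
    return SimilarityMatrix(labels, v)


class TestWeights:
    def test_must_sum_to_one(self):
        with pytest.raises(ValueError):
            FusionWeights(0.5, 0.5, 0.5)

    def test_each_in_unit_interval(self):
        with pytest.raises(ValueError):
            FusionWeights(-0.1, 0.5, 0.6)


class TestFuse:
    L = ["a", "b"]

    def test_convexity_preserves_one(self):
        one = _sym(self.L, {(0, 1): 1.0})
        m = fuse(one, one, one, FusionWeights(0.2, 0.3, 0.5))
        assert m.loc("a", "b") == pytest.approx(1.0)

    def test_weighted_sum_at_reported_optimum(self):
        m = fuse(_sym(self.L, {(0, 1): 0.5}),
                 _sym(self.L, {(0, 1): 0.2}),
                 _sym(self.L, {(0, 1): 0.9}),
                 FusionWeights(0.1, 0.3, 0.6))
        assert m.loc("a", "b") == pytest.approx(0.65)

    def test_missing_modality_renormalizes(self):
        m = fuse(_sym(self.L, {}),                 # NA off-diagonal
                 _sym(self.L, {(0, 1): 0.4}),
                 _sym(self.L, {(0, 1): 0.8}),
                 FusionWeights(0.1, 0.3, 0.6))
        assert m.loc("a", "b") == pytest.approx((0.3 * 0.4 + 0.6 * 0.8) / 0.9)

    def test_strict_mode_propagates_sentinel(self):
        m = fuse(_sym(self.L, {}),
                 _sym(self.L, {(0, 1): 0.4}),
                 _sym(self.L, {(0, 1): 0.8}),
                 FusionWeights(0.1, 0.3, 0.6), strict=True)
        assert math.isnan(m.loc("a", "b"))

    def test_all_missing_stays_missing_but_diagonal_is_one(self):
        na = _sym(self.L, {})
        m = fuse(na, na, na, FusionWeights(0.1, 0.3, 0.6))
        assert math.isnan(m.loc("a", "b")) and m.loc("a", "a") == 1.0

    def test_label_mismatch_errors(self):
        a = _sym(["a", "b"], {(0, 1): 0.5})
        b = _sym(["a", "c"], {(0, 1): 0.5})
        with pytest.raises(ValueError, match="label"):
            fuse(a, b, a, FusionWeights(0.1, 0.3, 0.6))


class TestCms:
    def _t(self, mapping):
        return AssociationTable.from_pairs(
            "circ-mirna", [(c, m) for c, ms in mapping.items() for m in ms])

    def test_identical_sets(self):
        m = cms_matrix(self._t({"c1": {"m1"}, "c2": {"m1"}}), ["c1", "c2"])
        assert m.loc("c1", "c2") == 1.0

    def test_jaccard_value(self):
        m = cms_matrix(self._t({"c1": {"m1", "m2"}, "c2": {"m2", "m3"}}), ["c1", "c2"])
        assert m.loc("c1", "c2") == pytest.approx(1 / 3)

    def test_disjoint_sets_are_zero_and_both_empty_is_sentinel(self):
        m = cms_matrix(self._t({"c1": {"m1"}, "c2": {"m2"}}), ["c1", "c2", "c3", "c4"])
        assert m.loc("c1", "c2") == 0.0
        assert math.isnan(m.loc("c3", "c4"))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        mirnas = [f"m{i}" for i in range(12)]
        for _ in range(10):
            n = int(rng.integers(2, 21))
            sets = {f"c{i}": set(rng.choice(mirnas,
                                            size=int(rng.integers(0, 6)),
                                            replace=False))
                    for i in range(n)}
            ids = sorted(sets)
            m = cms_matrix(self._t(sets), ids)
            for i, a in enumerate(ids):
                for j, b in enumerate(ids):
                    if i >= j:
                        continue
                    union = sets[a] | sets[b]
                    if not union:
                        assert math.isnan(m.values[i, j])
                    else:
                        assert m.values[i, j] == pytest.approx(
                            len(sets[a] & sets[b]) / len(union))


class TestCorrelate:
    def test_affine_relation_gives_r_one(self):
        rng = np.random.default_rng(0)
        labels = [f"c{i}" for i in range(6)]
        off = {(i, j): rng.uniform(0.1, 0.8) for i in range(6) for j in range(i + 1, 6)}
        a = _sym(labels, off)
        b = _sym(labels, {k: 0.5 * v + 0.1 for k, v in off.items()})
        res = correlate(a, b)
        assert res.r == pytest.approx(1.0)
        assert res.n_pairs == 15

    def test_negated_relation_gives_minus_one(self):
        rng = np.random.default_rng(1)
        labels = [f"c{i}" for i in range(5)]
        off = {(i, j): rng.uniform(0.1, 0.8) for i in range(5) for j in range(i + 1, 5)}
        res = correlate(_sym(labels, off),
                        _sym(labels, {k: 1.0 - v for k, v in off.items()}))
        assert res.r == pytest.approx(-1.0)

    def test_constant_upper_triangle_errors(self):
        labels = ["a", "b", "c"]
        const = _sym(labels, {(0, 1): 0.4, (0, 2): 0.4, (1, 2): 0.4})
        varying = _sym(labels, {(0, 1): 0.1, (0, 2): 0.5, (1, 2): 0.9})
        with pytest.raises(ValueError, match="variance"):
            correlate(const, varying)

    def test_too_few_pairs_errors(self):
        a = _sym(["a", "b"], {(0, 1): 0.3})
        b = _sym(["a", "b"], {(0, 1): 0.6})
        with pytest.raises(ValueError, match="pairs"):
            correlate(a, b)


class TestGridSearch:
    def test_thirty_combinations_at_reported_settings(self):
        assert len(enumerate_weights(step=0.1, alpha_max=0.2)) == 30

    def test_coarse_grid_enumeration(self):
        combos = enumerate_weights(step=1.0, alpha_max=0.0)
        assert {w.as_tuple() for w in combos} == {(0.0, 0.0, 1.0), (0.0, 1.0, 0.0)}

    def test_full_range_includes_pure_modality_corners(self):
        tuples = {w.as_tuple() for w in enumerate_weights(step=0.1, alpha_max=1.0)}
        assert {(1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)} <= tuples

    def test_invalid_step_errors(self):
        with pytest.raises(ValueError):
            enumerate_weights(step=0.3, alpha_max=0.2)
        with pytest.raises(ValueError):
            enumerate_weights(step=0.1, alpha_max=0.25)

    def test_recovers_planted_weights(self):
        planted = FusionWeights(0.1, 0.3, 0.6)
        cdfs, gofs, sqfs, cms = make_planted_fusion(
            SyntheticConfig(n_circ=30, seed=21), planted, sigma=0.01)
        best, table = grid_search(cdfs, gofs, sqfs, cms)
        assert len(table) == 30
        assert best.as_tuple() == pytest.approx(planted.as_tuple())


class TestBinnedExpression:
    def _fs(self, rng, n=12):
        labels = [f"c{i}" for i in range(n)]
        off = {(i, j): rng.uniform(0.02, 0.98)
               for i in range(n) for j in range(i + 1, n)}
        return _sym(labels, off)

    def test_noiseless_monotone_coupling_gives_r_one(self):
        # Profiles p_i = cos(t_i) u + sin(t_i) w with u, w centered and
        # orthonormal give pairwise |PCC| = |cos(t_i - t_j)|.  Feeding that
        # same quantity in as the functional similarity makes expression
        # similarity an exact monotone (identity) function of it, so the
        # binned correlation must be 1.
        n = 12
        u = np.array([1.0, -1.0, 0.0, 0.0, 0.0, 0.0]) / np.sqrt(2)
        w = np.array([0.0, 0.0, 1.0, -1.0, 0.0, 0.0]) / np.sqrt(2)
        t = np.linspace(0.0, np.pi / 2, n)
        profiles = np.stack([np.cos(ti) * u + np.sin(ti) * w for ti in t])
        labels = [f"c{i}" for i in range(n)]
        expr = pd.DataFrame(profiles, index=labels,
                            columns=[f"s{j}" for j in range(6)])
        esim = expression_similarity_matrix(expr)
        res = binned_expression_correlation(esim, expr, step=0.1)
        assert res.r == pytest.approx(1.0)

    def test_single_occupied_bin_errors(self):
        labels = ["a", "b", "c"]
        fs = _sym(labels, {(0, 1): 0.42, (0, 2): 0.44, (1, 2): 0.46})
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(3, 5)), index=labels)
        with pytest.raises(ValueError, match="bin"):
            binned_expression_correlation(fs, expr, step=0.1)

    def test_per_bin_records_edges_and_sizes(self):
        rng = np.random.default_rng(4)
        fs = self._fs(rng)
        expr = pd.DataFrame(rng.normal(size=(fs.n, 8)), index=fs.labels)
        res = binned_expression_correlation(fs, expr, step=0.25)
        assert sum(b[3] for b in res.per_bin) == res.n_pairs
        assert all(lo <= mean_fs < lo + 0.25 for lo, mean_fs, _, _ in res.per_bin)


class TestThresholdNetwork:
    def _m(self):
        return _sym(["a", "b", "c"], {(0, 1): 0.82, (0, 2): 0.4, (1, 2): 0.69})

    def test_cutoff_zero_returns_all_defined_pairs(self):
        assert len(threshold_network(self._m(), 0.0)) == 3

    def test_cutoff_is_inclusive_and_one_keeps_only_exact_ones(self):
        m = _sym(["a", "b", "c"], {(0, 1): 1.0, (0, 2): 0.9999, (1, 2): 0.5})
        edges = threshold_network(m, 1.0)
        assert edges == [("a", "b", 1.0)]

    def test_hand_counted_edges_at_07(self):
        edges = threshold_network(self._m(), 0.7)
        assert edges == [("a", "b", 0.82)]

    def test_sorted_by_descending_score(self):
        edges = threshold_network(self._m(), 0.0)
        scores = [e[2] for e in edges]
        assert scores == sorted(scores, reverse=True)

    def test_sentinel_entries_excluded(self):
        m = _sym(["a", "b", "c"], {(0, 1): 0.9})
        assert len(threshold_network(m, 0.0)) == 1


def test_evaluation_result_range_check():
    with pytest.raises(ValueError):
        EvaluationResult(r=1.5, p=0.1, n_pairs=10)
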