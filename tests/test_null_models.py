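import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tempophylo as tp
from tempophylo import _kernels
from tempophylo.null_models import NullConfig, randomize

from oracles import enum_fixed_marginal_matrices


def cm(array, species=None, units=None, scale="sample"):
    a = np.asarray(array, dtype=np.int8)
    species = species or [f"s{j}" for j in range(a.shape[1])]
    units = units or [f"u{i}" for i in range(a.shape[0])]
    return tp.CommunityMatrix(pd.DataFrame(a, index=units, columns=species), scale)


class TestSwapStep:
    def test_only_checkerboard_must_flip(self, rng):
        m = cm([[1, 0], [0, 1]])
        out = tp.independent_swap_step(m, rng)
        np.testing.assert_array_equal(out.values, [[0, 1], [1, 0]])

    def test_all_ones_never_changes(self, rng):
        m = cm(np.ones((3, 3)))
        for _ in range(50):
            m = tp.independent_swap_step(m, rng)
        np.testing.assert_array_equal(m.values, np.ones((3, 3)))

    def test_marginals_conserved(self, rng):
        m = cm((rng.random((6, 8)) < 0.4).astype(int))
        rows, cols = m.values.sum(1), m.values.sum(0)
        for _ in range(500):
            m = tp.independent_swap_step(m, rng)
        np.testing.assert_array_equal(m.values.sum(1), rows)
        np.testing.assert_array_equal(m.values.sum(0), cols)

    def test_non_binary_rejected(self, rng):
        with pytest.raises(ValueError, match="binary"):
            tp.independent_swap_step(cm([[2, 0], [0, 1]]), rng)


class TestSwapKernel:
    def test_marginals_bit_identical_many_trials(self):
        rng = np.random.default_rng(3)
        m = (rng.random((10, 15)) < 0.3).astype(np.int8)
        rows, cols = m.sum(1).copy(), m.sum(0).copy()
        _kernels.swap_trials(m, 10_000, _kernels.seed_state(5))
        np.testing.assert_array_equal(m.sum(1), rows)
        np.testing.assert_array_equal(m.sum(0), cols)

    def test_row_stats_matches_reference_metrics(self, ten_tip_tree):
        d = tp.node_count_distance_matrix(ten_tip_tree)
        rng = np.random.default_rng(11)
        m = (rng.random((8, 10)) < 0.5).astype(np.int8)
        mpd_k, mntd_k = _kernels.row_stats(m, d.values.astype(float))
        for r in range(8):
            present = {d.labels[j] for j in np.flatnonzero(m[r])}
            if len(present) < 2:
                assert math.isnan(mpd_k[r]) and math.isnan(mntd_k[r])
            else:
                assert mpd_k[r] == pytest.approx(tp.mpd(present, d))
                assert mntd_k[r] == pytest.approx(tp.mntd(present, d))


class TestRandomize:
    def test_unique_configuration_null_space(self):
        # marginals (3,0) x (1,1,1) admit exactly one matrix
        m = cm([[1, 1, 1], [0, 0, 0]])
        for null in randomize(m, NullConfig(n_rand=20, seed=1)):
            np.testing.assert_array_equal(null, m.values)

    def test_swap_samples_conserve_both_marginals(self):
        rng = np.random.default_rng(8)
        m = cm((rng.random((12, 20)) < 0.35).astype(int))
        rows, cols = m.values.sum(1), m.values.sum(0)
        for null in randomize(m, NullConfig(n_rand=30, seed=2)):
            np.testing.assert_array_equal(null.sum(1), rows)
            np.testing.assert_array_equal(null.sum(0), cols)

    def test_richness_null_preserves_row_sums_only(self):
        m = cm([[1, 1, 0, 0], [1, 0, 0, 0], [1, 1, 1, 0]])
        seen_col_change = False
        for null in randomize(m, NullConfig(model="richness", n_rand=50, seed=3)):
            np.testing.assert_array_equal(null.sum(1), m.values.sum(1))
            if not np.array_equal(null.sum(0), m.values.sum(0)):
                seen_col_change = True
        assert seen_col_change

    def test_frequency_null_preserves_column_sums_only(self):
        m = cm([[1, 1, 0, 0], [1, 0, 0, 0], [1, 1, 1, 0]])
        seen_row_change = False
        for null in randomize(m, NullConfig(model="frequency", n_rand=50, seed=3)):
            np.testing.assert_array_equal(null.sum(0), m.values.sum(0))
            if not np.array_equal(null.sum(1), m.values.sum(1)):
                seen_row_change = True
        assert seen_row_change

    def test_swap_chain_uniform_over_enumerable_set(self):
        # the 3x3 set with marginals (2,1,1) x (2,1,1), enumerated exhaustively
        m = cm([[1, 1, 0], [1, 0, 0], [0, 0, 1]])
        space = set(enum_fixed_marginal_matrices(m.values.sum(1), m.values.sum(0)))
        counts = {s: 0 for s in space}
        for null in randomize(m, NullConfig(n_rand=9000, seed=4)):
            counts[null.tobytes()] += 1
        assert all(c > 0 for c in counts.values())
        chi = stats.chisquare(list(counts.values()))
        assert chi.pvalue > 0.01

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError, match="model"):
            NullConfig(model="curveball")


class TestSESIndices:
    def test_sign_convention_clustering_is_positive(self):
        # two well-separated clades; every unit holds exactly one clade, so
        # observed MPD is far below the label-permutation null
        t = tp.read_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        d = tp.node_count_distance_matrix(t)
        units = [[1, 1, 1, 1, 0, 0, 0, 0], [0, 0, 0, 0, 1, 1, 1, 1]] * 3
        m = cm(units, species=list("ABCDEFGH"))
        res = tp.ses_indices(m, d, NullConfig(model="taxa_labels", n_rand=999, seed=5))
        nri = [r for r in res if r.index == "NRI"]
        assert all(r.ses > 0 for r in nri)
        assert all(r.pattern == "clustered" for r in nri)

    def test_ses_equation(self):
        # recompute -(obs - mean)/sd from the same null stream
        t = tp.simulate_tree(8, seed=0)
        d = tp.node_count_distance_matrix(t)
        rng = np.random.default_rng(9)
        m = cm((rng.random((5, 8)) < 0.6).astype(int), species=list(d.labels))
        config = NullConfig(model="richness", n_rand=99, seed=6)
        res = tp.ses_indices(m, d, config)
        nulls = {"NRI": [], "NTI": []}
        for null in randomize(m, config):
            mpd_r, mntd_r = _kernels.row_stats(null, d.values.astype(float))
            nulls["NRI"].append(mpd_r)
            nulls["NTI"].append(mntd_r)
        for r in res:
            if r.pattern == "undefined":
                continue
            draws = np.array(nulls[r.index])[:, m.units.index(r.unit)]
            assert r.null_mean == pytest.approx(draws.mean())
            assert r.null_sd == pytest.approx(draws.std(ddof=1))
            assert r.ses == pytest.approx(-(r.observed - draws.mean()) / draws.std(ddof=1))
            assert 0 <= r.rank <= 1

    def test_degenerate_null_sd_is_undefined_with_warning(self):
        t = tp.read_newick("((A,B),(C,D));")
        d = tp.node_count_distance_matrix(t)
        m = cm(np.ones((3, 4), dtype=int), species=list("ABCD"))  # no checkerboard
        with pytest.warns(RuntimeWarning, match="degenerate"):
            res = tp.ses_indices(m, d, NullConfig(n_rand=49, seed=7))
        assert all(r.pattern == "undefined" for r in res)

    def test_low_richness_unit_is_gap(self):
        t = tp.read_newick("((A,B),(C,D));")
        d = tp.node_count_distance_matrix(t)
        m = cm([[1, 0, 0, 0], [1, 1, 1, 0], [0, 1, 1, 1]], species=list("ABCD"))
        res = tp.ses_indices(m, d, NullConfig(model="richness", n_rand=99, seed=8))
        u0 = [r for r in res if r.unit == "u0"]
        assert all(r.pattern == "undefined" and math.isnan(r.observed) for r in u0)

    def test_seeded_determinism(self, ten_tip_tree):
        d = tp.node_count_distance_matrix(ten_tip_tree)
        rng = np.random.default_rng(10)
        m = cm((rng.random((6, 10)) < 0.5).astype(int), species=list(d.labels))
        config = NullConfig(n_rand=99, seed=123)
        a = tp.ses_indices(m, d, config)
        b = tp.ses_indices(m, d, config)
        assert [(r.ses, r.rank, r.pattern) for r in a] == [(r.ses, r.rank, r.pattern) for r in b]

    def test_taxa_labels_null_runs(self, ten_tip_tree):
        d = tp.node_count_distance_matrix(ten_tip_tree)
        rng = np.random.default_rng(12)
        m = cm((rng.random((5, 10)) < 0.5).astype(int), species=list(d.labels))
        res = tp.ses_indices(m, d, NullConfig(model="taxa_labels", n_rand=99, seed=1))
        assert len(res) == 10  # 5 units x 2 indices


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "rank,expected",
        [(0.01, "clustered"), (0.99, "overdispersed"), (0.5, "random"),
         (0.025, "clustered"), (0.975, "overdispersed"), (math.nan, "undefined")],
    )
    def test_rank_thresholds(self, rank, expected):
        assert tp.classify_pattern(rank, alpha=0.05) == expected
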