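import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import lncffl
from lncffl.network import LncFFL
from lncffl.scoring import (
    EdgeCorrelations,
    classify_pattern,
    composite_scores,
    differential_pvalues,
    dysregulated_ffls,
    edge_correlations,
    permutation_test,
    rank_and_combine,
    score_ffls,
)

from .conftest import make_bundle


def _toy_bundle(gene_vals, mirna_vals, lncrna_vals, n_case=4):
    return make_bundle(
        {"G1": gene_vals}, {"M1": mirna_vals}, {"L1": lncrna_vals}, n_case=n_case
    )


class TestDifferentialPvalues:
    def test_identical_groups_give_p_one(self, single_ffl):
        v = [1, 2, 3, 4, 1, 2, 3, 4]
        b = _toy_bundle(v, v, v)
        assert differential_pvalues(b, single_ffl) == (1.0, 1.0, 1.0)

    def test_hand_computed_student_t(self, single_ffl):
        case, ctrl = [10, 11, 12, 13], [1, 2, 3, 4]
        b = _toy_bundle(case + ctrl, case + ctrl, case + ctrl)
        # pooled-variance formula by hand: s_p^2 = 5/3, t = 9 / sqrt(5/3 * 1/2)
        t = 9.0 / np.sqrt((5.0 / 3.0) * 0.5)
        expected = 2.0 * stats.t.sf(t, df=6)
        p_gene, _, _ = differential_pvalues(b, single_ffl)
        assert p_gene == pytest.approx(expected, rel=1e-12)

    def test_one_group_constant_uses_pooled_variance(self, single_ffl):
        case, ctrl = [5.0] * 4, [1.0, 2.0, 3.0, 4.0]
        b = _toy_bundle(case + ctrl, case + ctrl, case + ctrl)
        sp2 = (0.0 * 3 + np.var(ctrl, ddof=1) * 3) / 6
        t = (5.0 - 2.5) / np.sqrt(sp2 * 0.5)
        expected = 2.0 * stats.t.sf(abs(t), df=6)
        p_gene, _, _ = differential_pvalues(b, single_ffl)
        assert np.isfinite(p_gene)
        assert p_gene == pytest.approx(expected, rel=1e-12)

    def test_zero_pooled_variance_maps_to_one(self, single_ffl):
        b = _toy_bundle([5.0] * 8, [5.0] * 8, [5.0] * 8)
        assert differential_pvalues(b, single_ffl) == (1.0, 1.0, 1.0)

    def test_welch_option_differs(self, single_ffl):
        case, ctrl = [10, 11, 12, 20], [1.0, 1.1, 0.9, 1.0]
        b = _toy_bundle(case + ctrl, case + ctrl, case + ctrl)
        p_student, _, _ = differential_pvalues(b, single_ffl, equal_var=True)
        p_welch, _, _ = differential_pvalues(b, single_ffl, equal_var=False)
        assert p_student != p_welch


class TestEdgeCorrelations:
    def test_identical_vectors_corr_one(self, single_ffl):
        v = [1.0, 2.0, 3.0, 5.0, 9.0, 2.0, 4.0, 8.0]
        b = _toy_bundle(v, v, v)
        c = edge_correlations(b, single_ffl)
        assert c.case_lnc_mir == pytest.approx(1.0)
        assert c.ctrl_mir_gene == pytest.approx(1.0)

    def test_negated_vectors_corr_minus_one(self, single_ffl):
        v = [1.0, 2.0, 3.0, 5.0, 9.0, 2.0, 4.0, 8.0]
        b = _toy_bundle(v, [-x for x in v], v)
        c = edge_correlations(b, single_ffl)
        assert c.case_lnc_mir == pytest.approx(-1.0)

    def test_matches_manual_covariance_formula(self, single_ffl):
        rng = np.random.default_rng(5)
        g, m, l = rng.normal(size=(3, 8))
        b = _toy_bundle(list(g), list(m), list(l))
        c = edge_correlations(b, single_ffl)
        gc, mc, lc = g[:4], m[:4], l[:4]

        def manual(x, y):
            x, y = x - x.mean(), y - y.mean()
            return float((x * y).sum() / np.sqrt((x**2).sum() * (y**2).sum()))

        assert c.case_lnc_mir == pytest.approx(manual(lc, mc), abs=1e-12)
        assert c.case_lnc_gene == pytest.approx(manual(lc, gc), abs=1e-12)
        assert c.case_mir_gene == pytest.approx(manual(mc, gc), abs=1e-12)

    def test_zero_variance_maps_to_zero_with_warning(self, single_ffl, caplog):
        v = [1.0, 2.0, 3.0, 5.0, 9.0, 2.0, 4.0, 8.0]
        b = _toy_bundle([7.0] * 8, v, v)
        with caplog.at_level("WARNING"):
            c = edge_correlations(b, single_ffl)
        assert c.case_lnc_gene == 0.0 and c.ctrl_mir_gene == 0.0
        assert "undefined correlation" in caplog.text


ZERO_CORRS = EdgeCorrelations(0, 0, 0, 0, 0, 0)


class TestCompositeScores:
    def test_cs_dif_is_product(self):
        cs_dif, _ = composite_scores((0.1, 0.2, 0.5), ZERO_CORRS)
        assert cs_dif == pytest.approx(0.01, abs=1e-15)

    def test_equal_correlations_give_zero_cs_pcc(self):
        c = EdgeCorrelations(0.4, -0.2, 0.7, 0.4, -0.2, 0.7)
        _, cs_pcc = composite_scores((1, 1, 1), c)
        assert cs_pcc == 0.0

    def test_full_sign_flips_give_max_eight(self):
        c = EdgeCorrelations(1, 1, 1, -1, -1, -1)
        _, cs_pcc = composite_scores((1, 1, 1), c)
        assert cs_pcc == pytest.approx(8.0)

    def test_cs_pcc_is_absolute(self):
        c = EdgeCorrelations(0.5, -0.5, 0.5, -0.5, 0.5, -0.5)
        _, cs_pcc = composite_scores((1, 1, 1), c)
        assert cs_pcc == pytest.approx(1.0) and cs_pcc >= 0


class TestRankAndCombine:
    def _frame(self, pairs):
        return pd.DataFrame(
            {"cs_dif": [p[0] for p in pairs], "cs_pcc": [p[1] for p in pairs]}
        )

    def test_two_ffls(self):
        out = rank_and_combine(self._frame([(0.001, 4.0), (0.5, 0.1)]))
        assert list(out.final_score) == [1.0, 2.0]

    def test_ties_take_average_ranks_and_conserve_sum(self):
        out = rank_and_combine(self._frame([(0.1, 1.0), (0.1, 2.0), (0.1, 3.0)]))
        assert list(out.rank_dif) == [2.0, 2.0, 2.0]
        n = len(out)
        assert out.rank_pcc.sum() == n * (n + 1) / 2

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(17)
        df = self._frame(list(zip(rng.random(100), rng.random(100))))
        out = rank_and_combine(df)
        # oracle: position in an argsorted list (no ties with continuous draws)
        oracle_dif = np.empty(100)
        oracle_dif[np.argsort(df.cs_dif.to_numpy())] = np.arange(1, 101)
        oracle_pcc = np.empty(100)
        oracle_pcc[np.argsort(-df.cs_pcc.to_numpy())] = np.arange(1, 101)
        np.testing.assert_allclose(out.rank_dif, oracle_dif)
        np.testing.assert_allclose(out.rank_pcc, oracle_pcc)
        np.testing.assert_allclose(
            out.final_score, (oracle_dif + oracle_pcc) / 2
        )

    def test_single_ffl_errors(self):
        with pytest.raises(ValueError):
            rank_and_combine(self._frame([(0.1, 1.0)]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(0, 19))
    def test_improving_a_score_never_worsens_its_rank(self, seed, i):
        rng = np.random.default_rng(seed)
        df = self._frame(list(zip(rng.random(20), rng.random(20))))
        base = rank_and_combine(df)
        better = df.copy()
        better.loc[i, "cs_dif"] *= 0.5  # smaller p-product = stronger signal
        better.loc[i, "cs_pcc"] *= 2.0  # larger rewiring = stronger signal
        out = rank_and_combine(better)
        assert out.rank_dif[i] <= base.rank_dif[i]
        assert out.rank_pcc[i] <= base.rank_pcc[i]


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "ctrl, case, expected",
        [
            (0.8, -0.7, "positive->negative"),
            (0.1, 0.2, "none->none"),
            (-0.5, 0.0, "negative->none"),
            (0.3, -0.3, "positive->negative"),  # boundary is inclusive
        ],
    )
    def test_transitions(self, ctrl, case, expected):
        c = EdgeCorrelations(case, 0, 0, ctrl, 0, 0)
        assert classify_pattern(c, tau=0.3)["pattern_lnc_mir"] == expected

    def test_tau_out_of_range(self):
        with pytest.raises(ValueError):
            classify_pattern(ZERO_CORRS, tau=1.5)


@pytest.fixture(scope="module")
def planted_run():
    _, net = lncffl.triplet_network(40)
    truth = lncffl.make_truth(net, 4, seed=2)
    bundle, tt = lncffl.generate_bundle(net, truth)
    scores = permutation_test(bundle, net.ffls, 200, seed=7)
    return scores, tt


class TestPermutationTest:
    def test_schema_and_bounds(self, planted_run):
        scores, _ = planted_run
        assert list(scores.columns) == lncffl.scoring.SCORE_COLUMNS
        assert ((scores.perm_p >= 1 / 201) & (scores.perm_p <= 1.0)).all()
        assert ((scores.cs_dif > 0) & (scores.cs_dif <= 1)).all()
        assert ((scores.cs_pcc >= 0) & (scores.cs_pcc <= 8)).all()

    def test_planted_ffls_score_best(self, planted_run):
        scores, tt = planted_run
        planted = set(tt[tt.planted].gene)
        top = set(scores.nsmallest(4, "final_score").gene)
        assert len(planted & top) >= 3

    def test_dysregulated_extraction_matches_flag(self, planted_run):
        scores, _ = planted_run
        dys = dysregulated_ffls(scores)
        assert len(dys) == int(scores.dysregulated.sum())
        assert all(isinstance(f, LncFFL) for f in dys)

    def test_too_few_permutations_rejected(self):
        _, net = lncffl.triplet_network(5)
        bundle, _ = lncffl.generate_bundle(net, lncffl.SyntheticTruth(seed=1))
        with pytest.raises(ValueError):
            permutation_test(bundle, net.ffls, 50, seed=1)

    def test_seed_reproducibility(self):
        _, net = lncffl.triplet_network(10)
        bundle, _ = lncffl.generate_bundle(net, lncffl.SyntheticTruth(seed=3))
        a = permutation_test(bundle, net.ffls, 100, seed=5)
        b = permutation_test(bundle, net.ffls, 100, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_observed_equal_to_all_permutations_gives_p_one(self, single_ffl):
        # constant matrices: every permutation reproduces the observed scores
        b = _toy_bundle([5.0] * 8, [5.0] * 8, [5.0] * 8)
        b2 = make_bundle(
            {"G1": [5.0] * 8, "G2": [5.0] * 8},
            {"M1": [5.0] * 8, "M2": [5.0] * 8},
            {"L1": [5.0] * 8, "L2": [5.0] * 8},
            n_case=4,
        )
        ffls = [LncFFL("G1", "M1", "L1"), LncFFL("G2", "M2", "L2")]
        scores = permutation_test(b2, ffls, 100, seed=1)
        assert (scores.perm_p == 1.0).all()

    def test_missing_molecule_excluded_not_crashed(self, caplog):
        b = make_bundle(
            {"G1": list(range(8)), "G2": list(range(8))},
            {"M1": list(range(8)), "M2": list(range(8))},
            {"L1": list(range(8)), "L2": list(range(8))},
            n_case=4,
        )
        ffls = [
            LncFFL("G1", "M1", "L1"),
            LncFFL("G2", "M2", "L2"),
            LncFFL("G9", "M1", "L1"),
        ]
        with caplog.at_level("WARNING"):
            scores = score_ffls(b, ffls)
        assert len(scores) == 2
        assert "excluded 1 FFLs" in caplog.text
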