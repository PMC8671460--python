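"""Extreme-group selection, moderated t, over-representation, correlation,
signature scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prismscreen import biomarker, synth
from prismscreen.biomarker import EBParams


def _expr(rows, genes=None, lines=None):
    genes = genes or [f"G{i}" for i in range(len(rows))]
    lines = lines or [f"L{i}" for i in range(len(rows[0]))]
    return pd.DataFrame(rows, index=genes, columns=lines, dtype=float)


class TestRankLines:
    def test_extremes_from_means(self):
        m = _expr([[-2.0, -1.0, 0.0, 1.0]], genes=["drug"], lines=list("abcd"))
        sens, res = biomarker.rank_lines_by_mean_response(m, ["drug"], 1)
        assert sens == ["a"] and res == ["d"]

    def test_full_partition_when_n_is_half(self):
        m = _expr([[-2.0, -1.0, 0.0, 1.0]], genes=["drug"], lines=list("abcd"))
        sens, res = biomarker.rank_lines_by_mean_response(m, ["drug"], 2)
        assert set(sens) | set(res) == set("abcd")

    def test_ties_break_lexicographically(self):
        m = _expr([[0.0, 0.0, 1.0]], genes=["drug"], lines=["b", "a", "c"])
        sens, _ = biomarker.rank_lines_by_mean_response(m, ["drug"], 1)
        assert sens == ["a"]

    def test_too_many_extremes_rejected(self):
        m = _expr([[0.0, 1.0]], genes=["drug"], lines=["a", "b"])
        with pytest.raises(ValueError):
            biomarker.rank_lines_by_mean_response(m, ["drug"], 2)

    def test_sensitive_lines_are_planted_susceptible(self, small_screen):
        drm, truth = small_screen
        block = [c for c, m in truth.moa_assignment.items() if m == "MOA_X"]
        sens, _ = biomarker.rank_lines_by_mean_response(drm, block, 3)
        susceptible = set(truth.moa_latent.columns[truth.moa_latent.loc["MOA_X"] > 0])
        assert set(sens) <= susceptible


class TestFitEbParams:
    def test_equal_variances_give_infinite_prior_df(self):
        eb = biomarker.fit_eb_params(np.full(50, 2.5), residual_df=10)
        assert np.isinf(eb.d0)
        assert eb.s0_sq == pytest.approx(2.5, rel=0.15)

    def test_model_simulated_variances_recovered(self):
        rng = np.random.default_rng(42)
        d, d0, s0 = 10, 4.0, 1.0
        s2 = s0 * (rng.chisquare(d, 5000) / d) / (rng.chisquare(d0, 5000) / d0)
        eb = biomarker.fit_eb_params(s2, residual_df=d)
        assert 3.0 <= eb.d0 <= 5.0
        assert 0.9 <= eb.s0_sq <= 1.1

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="10 genes"):
            biomarker.fit_eb_params(np.ones(5), residual_df=4)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            biomarker.fit_eb_params(np.r_[np.ones(20), -1.0], residual_df=4)


class TestModeratedT:
    def test_hand_example_with_full_shrinkage(self):
        expr = _expr([[5, 5, 6, 6, 1, 1, 2, 2]], genes=["g"], lines=list("abcdefgh"))
        (rec,) = biomarker.moderated_t_test(
            expr, list("abcd"), list("efgh"), eb=EBParams(np.inf, 0.25)
        )
        assert rec.mean_diff == pytest.approx(4.0)
        assert rec.moderated_t == pytest.approx(4.0 / (0.5 * np.sqrt(0.5)))  # 11.3137

    def test_d0_zero_equals_ordinary_pooled_t(self):
        rng = np.random.default_rng(7)
        expr = _expr(rng.normal(size=(100, 10)).tolist())
        a, b = list(expr.columns[:5]), list(expr.columns[5:])
        recs = biomarker.moderated_t_test(expr, a, b, eb=EBParams(0.0, 1.0))
        t_ref, p_ref = stats.ttest_ind(expr[a], expr[b], axis=1, equal_var=True)
        np.testing.assert_allclose([r.moderated_t for r in recs], t_ref, atol=1e-10)
        np.testing.assert_allclose([r.p_value for r in recs], p_ref, atol=1e-10)

    def test_identical_groups_give_no_hits(self):
        vals = np.tile(np.arange(8.0), (20, 1))
        expr = _expr(np.hstack([vals, vals]).tolist())
        recs = biomarker.moderated_t_test(
            expr, list(expr.columns[:8]), list(expr.columns[8:]), eb=EBParams(1.0, 1.0)
        )
        assert all(r.mean_diff == 0 for r in recs)
        assert not any(r.q_value < 0.05 for r in recs)

    def test_zero_variance_zero_diff_gene_gets_t_zero(self):
        rows = [[1.0] * 8] + (np.arange(16.0).reshape(2, 8) ** 2).tolist()
        expr = _expr(rows)
        recs = biomarker.moderated_t_test(
            expr, list(expr.columns[:4]), list(expr.columns[4:]), eb=EBParams(0.0, 1.0)
        )
        assert recs[0].moderated_t == 0.0 and recs[0].p_value == 1.0

    def test_direction_follows_sign_of_difference(self, small_expression):
        expr, truth, lines = small_expression
        recs = biomarker.moderated_t_test(expr, lines[:6], lines[6:])
        by_gene = {r.gene: r for r in recs}
        for g in truth.deg_up:
            assert by_gene[g].direction == "up"
        for g in truth.deg_down:
            assert by_gene[g].direction == "down"

    def test_q_values_monotone_in_p_rank(self, small_expression):
        expr, _, lines = small_expression
        recs = biomarker.moderated_t_test(expr, lines[:6], lines[6:])
        frame = biomarker.degs_to_frame(recs).sort_values("p_value")
        assert (np.diff(frame["q_value"].to_numpy()) >= -1e-12).all()

    def test_overlapping_groups_rejected(self, small_expression):
        expr, _, lines = small_expression
        with pytest.raises(ValueError):
            biomarker.moderated_t_test(expr, lines[:6], lines[5:])


class TestOverrepresentation:
    def test_closed_form_hypergeometric_tail(self):
        universe = [f"G{i}" for i in range(20)]
        table = biomarker.overrepresentation(
            hit_genes=universe[:4] + ["G10"],
            universe_genes=universe,
            gene_sets={"S": universe[:5]},  # overlap 4 of 5
        )
        # P(X >= 4) = (C(5,4) C(15,1) + C(5,5) C(15,0)) / C(20,5) = 76/15504
        assert table.loc["S", "p_value"] == pytest.approx(76 / 15504)

    def test_degenerate_universe_equals_set(self):
        genes = ["A", "B", "C"]
        table = biomarker.overrepresentation(genes, genes, {"S": genes})
        assert table.loc["S", "p_value"] == pytest.approx(1.0)

    def test_zero_overlap_is_uninformative(self):
        universe = [f"G{i}" for i in range(100)]
        table = biomarker.overrepresentation(
            universe[:10], universe, {"S": universe[90:93]}
        )
        assert table.loc["S", "p_value"] > 0.5

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            biomarker.overrepresentation(["X"], ["A", "B"], {})

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            biomarker.overrepresentation([], [], {})


class TestCorrelateExpression:
    def test_exact_linear_dependence(self):
        lines = [f"L{i}" for i in range(6)]
        expr = _expr([[1, 2, 3, 4, 5, 6]], genes=["g"], lines=lines)
        resp = pd.Series([-2, -4, -6, -8, -10, -12.0], index=lines)
        (hit,) = biomarker.correlate_expression(expr, resp)
        assert hit.r == pytest.approx(-1.0)
        assert hit.shortlisted

    def test_hand_computed_r(self):
        lines = [f"L{i}" for i in range(5)]
        expr = _expr([[1, 2, 3, 4, 5]], genes=["g"], lines=lines)
        resp = pd.Series([2, 1, 4, 3, 5.0], index=lines)
        (hit,) = biomarker.correlate_expression(expr, resp)
        assert hit.r == pytest.approx(0.8)

    def test_three_points_no_correlation_gives_p_one(self):
        lines = ["a", "b", "c"]
        expr = _expr([[0.0, 1.0, 0.0]], genes=["g"], lines=lines)
        resp = pd.Series([-1.0, 0.0, 1.0], index=lines)
        (hit,) = biomarker.correlate_expression(expr, resp)
        assert abs(hit.r) < 1e-12 and hit.p_value == pytest.approx(1.0)

    def test_zero_variance_gene_excluded(self):
        lines = list("abcd")
        expr = _expr([[1, 1, 1, 1], [1, 2, 3, 4]], genes=["flat", "ok"], lines=lines)
        resp = pd.Series([1.0, 2, 3, 4], index=lines)
        with pytest.warns(UserWarning, match="undefined correlation"):
            hits = biomarker.correlate_expression(expr, resp)
        assert [h.gene for h in hits] == ["ok"]

    def test_planted_correlated_gene_shortlisted(self):
        lines = [f"L{i}" for i in range(20)]
        expr, truth = synth.generate_expression(
            50, lines, lines[:10], deg_frac=0, corr_spec={"hot": -1.5}, noise_sd=0.5, seed=2
        )
        hits = {h.gene: h for h in biomarker.correlate_expression(expr, truth.response)}
        assert hits["hot"].shortlisted and hits["hot"].r < 0


class TestSignatureScore:
    def test_single_gene_signature_is_its_z_profile(self):
        expr = _expr([[1.0, 2.0, 3.0, 4.0]], genes=["g"])
        score = biomarker.signature_score(expr, ["g"])
        z = (expr.loc["g"] - expr.loc["g"].mean()) / expr.loc["g"].std(ddof=0)
        np.testing.assert_allclose(score, z, atol=1e-12)

    def test_anti_correlated_pair_cancels(self):
        expr = _expr([[1, 2, 3, 4.0], [4, 3, 2, 1.0]], genes=["up", "dn"])
        score = biomarker.signature_score(expr, ["up", "dn"])
        np.testing.assert_allclose(score, 0.0, atol=1e-12)

    def test_affine_rescaling_of_a_gene_is_invariant(self):
        rng = np.random.default_rng(4)
        expr = _expr(rng.normal(size=(3, 8)).tolist(), genes=["a", "b", "c"])
        s1 = biomarker.signature_score(expr, ["a", "b", "c"])
        expr2 = expr.copy()
        expr2.loc["b"] = 100 + 7 * expr2.loc["b"]
        s2 = biomarker.signature_score(expr2, ["a", "b", "c"])
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_absent_genes_skipped_with_warning(self):
        expr = _expr([[1, 2, 3.0]], genes=["g"])
        with pytest.warns(UserWarning, match="absent"):
            score = biomarker.signature_score(expr, ["g", "missing"])
        assert len(score) == 3

    def test_all_absent_is_error(self):
        expr = _expr([[1, 2, 3.0]], genes=["g"])
        with pytest.raises(ValueError, match="no signature gene"):
            biomarker.signature_score(expr, ["missing"])

    def test_planted_signature_tracks_response(self):
        lines = [f"L{i}" for i in range(24)]
        sig = [f"SIG{i}" for i in range(5)]
        expr, truth = synth.generate_expression(
            100, lines, lines[:12], deg_frac=0,
            corr_spec={g: -1.0 for g in sig}, noise_sd=0.5, seed=9,
        )
        score = biomarker.signature_score(expr, sig)
        expr_with_score = pd.DataFrame([score], index=["score"])
        (hit,) = biomarker.correlate_expression(expr_with_score, truth.response)
        assert hit.shortlisted and hit.r < 0
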