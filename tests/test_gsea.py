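"""Enrichment: signal-to-noise ranking, weighted-KS score, permutation stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prismscreen import gsea, synth
from prismscreen.gsea import RankedList


def _expr(rows, genes=None, lines=None):
    genes = genes or [f"G{i}" for i in range(len(rows))]
    lines = lines or [f"L{i}" for i in range(len(rows[0]))]
    return pd.DataFrame(rows, index=genes, columns=lines, dtype=float)


class TestSignalToNoise:
    def test_equal_classes_give_zero_metric(self):
        expr = _expr([[1, 1, 1, 1.0]])
        ranked = gsea.signal_to_noise_rank(expr, ["L0", "L1"], ["L2", "L3"])
        assert ranked.metric[0] == 0.0

    def test_floored_standard_deviations(self):
        # muA=2 sd 0 -> floor max(0.4, 0.2) = 0.4; muB=0 sd 0 -> floor 0.2
        expr = _expr([[2, 2, 0, 0.0]])
        ranked = gsea.signal_to_noise_rank(expr, ["L0", "L1"], ["L2", "L3"])
        assert ranked.metric[0] == pytest.approx(2 / 0.6)

    def test_label_swap_negates_and_reverses(self):
        rng = np.random.default_rng(1)
        expr = _expr(rng.normal(size=(20, 8)).tolist())
        a, b = list(expr.columns[:4]), list(expr.columns[4:])
        fwd = gsea.signal_to_noise_rank(expr, a, b)
        rev = gsea.signal_to_noise_rank(expr, b, a)
        assert fwd.genes == rev.genes[::-1]
        np.testing.assert_allclose(fwd.metric, -rev.metric[::-1], atol=1e-12)

    def test_small_class_rejected(self):
        expr = _expr([[1, 2, 3.0]])
        with pytest.raises(ValueError):
            gsea.signal_to_noise_rank(expr, ["L0"], ["L1", "L2"])


def _brute_force_es(ranked, gene_set, weight_p):
    """Independent step-by-step oracle for the weighted-KS running sum."""
    members = set(gene_set) & set(ranked.genes)
    n = len(ranked.genes)
    n_hits = len([g for g in ranked.genes if g in members])
    denom = sum(abs(ranked.metric[i]) ** weight_p
                for i, g in enumerate(ranked.genes) if g in members)
    running, best = 0.0, 0.0
    for i, g in enumerate(ranked.genes):
        if g in members:
            running += (abs(ranked.metric[i]) ** weight_p) / denom if denom else 1.0 / n_hits
        else:
            running -= 1.0 / (n - n_hits)
        if abs(running) > abs(best):
            best = running
    return best


class TestEnrichmentScore:
    def test_singleton_set_at_top_rank_scores_one(self):
        ranked = RankedList(["a", "b", "c", "d"], np.array([3.0, 2.0, 1.0, 0.5]))
        es, running = gsea.enrichment_score(ranked, {"a"})
        assert es == pytest.approx(1.0)
        assert running[-1] == pytest.approx(0.0, abs=1e-9)

    def test_singleton_set_at_bottom_rank_is_most_negative_before_hit(self):
        ranked = RankedList(list("abcde"), np.array([5.0, 4, 3, 2, 1]))
        es, _ = gsea.enrichment_score(ranked, {"e"})
        assert es == pytest.approx(-1.0)  # four misses at -1/4 each before the hit
        assert es == pytest.approx(_brute_force_es(ranked, {"e"}, 1.0))

    def test_weight_zero_reduces_to_classic_ks(self):
        rng = np.random.default_rng(2)
        metric = np.sort(rng.normal(size=12))[::-1]
        ranked = RankedList([f"g{i}" for i in range(12)], metric)
        gene_set = {"g0", "g3", "g7"}
        es, _ = gsea.enrichment_score(ranked, gene_set, weight_p=0.0)
        # classic KS: hits step 1/3, misses step -1/9, signed max deviation
        assert es == pytest.approx(_brute_force_es(ranked, gene_set, 0.0))

    def test_missing_set_genes_dropped(self):
        ranked = RankedList(["a", "b", "c"], np.array([2.0, 1.0, 0.5]))
        es_with, _ = gsea.enrichment_score(ranked, {"a", "zzz"})
        es_clean, _ = gsea.enrichment_score(ranked, {"a"})
        assert es_with == es_clean

    def test_no_set_gene_in_list_is_error(self):
        ranked = RankedList(["a", "b"], np.array([1.0, 0.5]))
        with pytest.raises(ValueError, match="no gene"):
            gsea.enrichment_score(ranked, {"zzz"})

    def test_es_bounded_and_conserved(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(5, 40)
            metric = np.sort(rng.normal(size=n))[::-1]
            ranked = RankedList([f"g{i}" for i in range(n)], metric)
            size = int(rng.integers(1, n))
            gene_set = set(rng.choice(ranked.genes, size=size, replace=False))
            es, running = gsea.enrichment_score(ranked, gene_set)
            assert -1 <= es <= 1
            if size < n:
                assert running[-1] == pytest.approx(0.0, abs=1e-9)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    n=st.integers(4, 50),
    weight_p=st.sampled_from([0.0, 1.0, 1.5, 2.0]),
)
def test_enrichment_score_matches_oracle_on_random_lists(seed, n, weight_p):
    rng = np.random.default_rng(seed)
    metric = np.sort(rng.normal(size=n))[::-1]
    ranked = RankedList([f"g{i}" for i in range(n)], metric)
    size = int(rng.integers(1, n))
    gene_set = set(rng.choice(ranked.genes, size=size, replace=False))
    es, _ = gsea.enrichment_score(ranked, gene_set, weight_p)
    assert es == pytest.approx(_brute_force_es(ranked, gene_set, weight_p), abs=1e-9)


@pytest.fixture(scope="module")
def planted():
    lines = [f"L{i:02d}" for i in range(28)]
    expr, truth = synth.generate_expression(
        1000, lines, lines[:14], deg_frac=0.06, deg_delta=2.0, seed=11
    )
    sets = dict(truth.enriched_sets)
    sets.update(synth.random_gene_sets(list(expr.index), 8, 30, seed=5))
    return expr, truth, sets, lines


class TestPermutationSignificance:
    def test_planted_set_attains_top_nes_and_small_p(self, planted):
        expr, truth, sets, lines = planted
        results = gsea.permutation_significance(
            expr, lines[:14], lines[14:], sets, n_perm=200, seed=0
        )
        top = max(results, key=lambda r: abs(r.nes))
        assert top.set_name == "PLANTED_UP"
        assert top.nominal_p <= 0.05

    def test_deterministic_given_seed(self, planted):
        expr, _, sets, lines = planted
        kw = dict(n_perm=100, seed=3)
        r1 = gsea.permutation_significance(expr, lines[:14], lines[14:], sets, **kw)
        r2 = gsea.permutation_significance(expr, lines[:14], lines[14:], sets, **kw)
        assert [(a.set_name, a.es, a.nes, a.nominal_p) for a in r1] == [
            (b.set_name, b.es, b.nes, b.nominal_p) for b in r2
        ]

    def test_nes_sign_matches_es_and_q_clipped(self, planted):
        expr, _, sets, lines = planted
        results = gsea.permutation_significance(
            expr, lines[:14], lines[14:], sets, n_perm=100, seed=1
        )
        for r in results:
            assert np.sign(r.nes) == np.sign(r.es)
            assert 0 <= r.nominal_p <= 1
            assert 0 <= r.fdr_q <= 1

    def test_undersized_sets_dropped_with_warning(self, planted):
        expr, _, _, lines = planted
        with pytest.warns(UserWarning, match="dropping gene set"):
            results = gsea.permutation_significance(
                expr, lines[:14], lines[14:], {"tiny": ["G00001", "G00002"]},
                n_perm=100, seed=0,
            )
        assert results == []

    def test_gene_set_mode_used_for_small_classes(self, planted):
        expr, _, sets, lines = planted
        results = gsea.permutation_significance(
            expr, lines[:4], lines[14:18], sets, n_perm=100, seed=0
        )  # 4v4: defaults to gene_set mode, must still run
        assert {r.set_name for r in results} == set(sets)


class TestCompareEnrichedSets:
    def _res(self, names, nes=2.0, q=0.01):
        return [gsea.EnrichmentResult(n, np.sign(nes), nes, 0.01, q, 20, []) for n in names]

    def test_identical_lists_intersect_fully(self):
        r = self._res(["H1", "H2"])
        out = gsea.compare_enriched_sets({"a": r, "b": r})
        assert out["intersection"] == {"H1", "H2"}

    def test_disjoint_lists_intersect_empty(self):
        out = gsea.compare_enriched_sets(
            {"a": self._res(["H1"]), "b": self._res(["H2"])}
        )
        assert out["intersection"] == set()

    def test_three_datasets_sharing_four_sets(self):
        shared = ["E2F", "MYC_V2", "G2M", "SPERM"]
        out = gsea.compare_enriched_sets(
            {
                "ds1": self._res(shared + ["X1"]),
                "ds2": self._res(shared + ["X2"]),
                "ds3": self._res(shared + ["X3", "X4"]),
            }
        )
        assert out["intersection"] == set(shared)
        assert out["pairwise_counts"][("ds1", "ds2")] == 4

    def test_fdr_cut_and_direction_filter(self):
        high_q = self._res(["H1"], q=0.5)
        neg = self._res(["H2"], nes=-2.0)
        out = gsea.compare_enriched_sets({"a": high_q + neg, "b": high_q + neg})
        assert out["intersection"] == set()

    def test_single_dataset_rejected(self):
        with pytest.raises(ValueError):
            gsea.compare_enriched_sets({"a": []})
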