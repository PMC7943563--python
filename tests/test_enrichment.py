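"""GMT parsing, enrichment score, permutation GSEA, ssGSEA."""

import itertools

import numpy as np
import pandas as pd
import pytest

import nescore as ns
from nescore.errors import FormatError, ValidationError
from nescore.gsea import _null_es


def brute_force_es(metric, hit_flags, p=1.0):
    """Independent plain-Python walk of the weighted KS running sum."""
    n = len(metric)
    n_hits = sum(hit_flags)
    hit_weights = [abs(m) ** p for m, h in zip(metric, hit_flags) if h]
    total = sum(hit_weights)
    running, cur, wi = [], 0.0, 0
    for m, h in zip(metric, hit_flags):
        if h:
            cur += (abs(m) ** p / total) if total > 0 else 1.0 / n_hits
            wi += 1
        else:
            cur -= 1.0 / (n - n_hits)
        running.append(cur)
    hi = max(running)
    lo = min(running)
    return hi if hi >= -lo - 1e-12 else lo  # same tie rule: positive wins


class TestReadGMT:
    def test_two_sets(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("A\tdesc\tg1\tg2\nB\tdesc\tg3\n")
        coll = ns.read_gmt(path)
        assert len(coll) == 2
        assert coll["A"] == ["g1", "g2"]

    def test_duplicate_gene_counted_once(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("A\tdesc\tg1\tg1\tg2\n")
        assert ns.read_gmt(path)["A"] == ["g1", "g2"]

    def test_set_without_genes_dropped(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("A\tdesc\tg1\nEMPTY\tdesc\t\n")
        coll = ns.read_gmt(path)
        assert list(dict(coll)) == ["A"]

    def test_short_line_is_format_error(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("A\tdesc\n")
        with pytest.raises(FormatError, match=":1"):
            ns.read_gmt(path)

    def test_gmt_round_trip(self, tmp_path, toy_sets):
        path = tmp_path / "rt.gmt"
        ns.write_gmt(toy_sets, path)
        back = ns.read_gmt(path)
        assert dict(back) == dict(toy_sets)


class TestRankGenesByCorrelation:
    def _expr(self):
        scores = np.array([0.1, -0.4, 0.7, 0.2, -0.9])
        values = pd.DataFrame(
            {
                "match": scores,
                "anti": -scores,
                "flat": np.ones(5),
                "noise": [0.3, 0.1, 0.2, -0.5, 0.4],
            },
            index=[f"s{i}" for i in range(5)],
        ).T
        return ns.ExpressionMatrix(values), scores

    def test_matching_gene_ranked_first_anti_last(self):
        expr, scores = self._expr()
        ranked = ns.rank_genes_by_correlation(expr, scores)
        assert ranked.gene_ids[0] == "match"
        assert ranked.metric[0] == pytest.approx(1.0)
        assert ranked.gene_ids[-1] == "anti"
        assert ranked.metric[-1] == pytest.approx(-1.0)
        assert "flat" not in ranked.gene_ids  # constant gene excluded

    def test_ties_broken_by_gene_id(self):
        scores = np.array([1.0, 2.0, 3.0])
        values = pd.DataFrame(
            {"b": [1.0, 2.0, 3.0], "a": [2.0, 4.0, 6.0]},
            index=["s1", "s2", "s3"],
        ).T
        ranked = ns.rank_genes_by_correlation(ns.ExpressionMatrix(values), scores)
        assert ranked.gene_ids == ("a", "b")

    def test_too_few_samples_rejected(self):
        values = pd.DataFrame({"g": [1.0, 2.0]}, index=["s1", "s2"]).T
        with pytest.raises(ValidationError, match="3 samples"):
            ns.rank_genes_by_correlation(ns.ExpressionMatrix(values), np.array([1.0, 2.0]))


class TestEnrichmentScore:
    def _ranked(self, n=5):
        return ns.RankedList(tuple(f"g{i}" for i in range(1, n + 1)),
                             np.arange(n, 0, -1, dtype=float))

    def test_top_gene_scores_one(self):
        es, _, leading = ns.enrichment_score(self._ranked(), ["g1"])
        assert es == pytest.approx(1.0)
        assert leading == ("g1",)

    def test_bottom_gene_scores_minus_one(self):
        es, _, leading = ns.enrichment_score(self._ranked(), ["g5"])
        assert es == pytest.approx(-1.0)
        assert leading == ("g5",)

    def test_hand_derived_mid_ranked_pair(self):
        # frozen hand walk: metric (5,4,3,2,1), hits at ranks 2,3, p=1 -> ES = 2/3
        es, _, leading = ns.enrichment_score(self._ranked(), ["g2", "g3"])
        assert es == pytest.approx(2.0 / 3.0)
        assert leading == ("g2", "g3")

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            ns.enrichment_score(self._ranked(), ["absent"])

    def test_full_coverage_rejected(self):
        with pytest.raises(ValidationError, match="every"):
            ns.enrichment_score(self._ranked(), [f"g{i}" for i in range(1, 6)])

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_matches_brute_force_on_all_subsets(self, n):
        rng = np.random.default_rng(n)
        metric = np.sort(rng.normal(0, 1, n))[::-1]
        ranked = ns.RankedList(tuple(f"g{i}" for i in range(n)), metric)
        for flags in itertools.product([0, 1], repeat=n):
            if not 0 < sum(flags) < n:
                continue
            members = [f"g{i}" for i, f in enumerate(flags) if f]
            es, _, _ = ns.enrichment_score(ranked, members)
            assert es == pytest.approx(brute_force_es(metric, flags), abs=1e-12)

    def test_single_gene_antisymmetry(self):
        """Reversing the ranking flips a single-gene set's ES sign exactly."""
        ranked = self._ranked(6)
        rev = ns.RankedList(tuple(reversed(ranked.gene_ids)), -ranked.metric[::-1])
        for gene in ranked.gene_ids:
            es_f, _, _ = ns.enrichment_score(ranked, [gene])
            es_r, _, _ = ns.enrichment_score(rev, [gene])
            assert es_r == pytest.approx(-es_f, abs=1e-12)


class TestPrerankedGSEA:
    def _ranked(self, n=200, seed=4):
        rng = np.random.default_rng(seed)
        metric = np.sort(rng.normal(0, 1, n))[::-1]
        return ns.RankedList(tuple(f"g{i:03d}" for i in range(n)), metric)

    def test_planted_top_set_hits_pvalue_floor(self):
        ranked = self._ranked()
        sets = ns.GeneSetCollection({"TOP": list(ranked.gene_ids[:15])})
        (res,) = ns.preranked_gsea(ranked, sets, n_perm=500, seed=0)
        assert res.nes > 0
        assert res.pvalue <= 10.0 / (res.n_perm + 1)
        assert res.pvalue >= 1.0 / (res.n_perm + 1)

    def test_same_seed_is_bitwise_identical(self):
        ranked = self._ranked()
        sets = ns.GeneSetCollection({"A": list(ranked.gene_ids[10:40]),
                                     "B": list(ranked.gene_ids[::7])})
        r1 = ns.preranked_gsea(ranked, sets, n_perm=200, seed=42)
        r2 = ns.preranked_gsea(ranked, sets, n_perm=200, seed=42)
        assert r1 == r2

    def test_unscoreable_set_skipped_not_fatal(self):
        ranked = self._ranked(20)
        sets = ns.GeneSetCollection({"OK": list(ranked.gene_ids[:3]),
                                     "MISSING": ["absent1", "absent2"]})
        results = ns.preranked_gsea(ranked, sets, n_perm=100, seed=1)
        assert [r.set_name for r in results] == ["OK"]

    def test_low_n_perm_rejected(self):
        ranked = self._ranked(20)
        with pytest.raises(ValidationError, match="n_perm"):
            ns.preranked_gsea(ranked, ns.GeneSetCollection({"A": ["g000"]}), n_perm=10)

    def test_null_matches_reference_walker(self):
        """The vectorized permutation null equals ES of explicit random sets."""
        ranked = self._ranked(30, seed=9)
        absw = np.abs(ranked.metric)
        size, n_perm = 7, 50
        rng = np.random.default_rng(123)
        fast = _null_es(absw, size, n_perm, np.random.default_rng(123))
        pos = np.argsort(rng.random((n_perm, 30)), axis=1, kind="stable")[:, :size]
        slow = []
        for row in pos:
            members = [ranked.gene_ids[i] for i in row]
            es, _, _ = ns.enrichment_score(ranked, members)
            slow.append(es)
        np.testing.assert_allclose(fast, slow, atol=1e-12)


class TestSSGSEA:
    def test_top_placement_scores_higher(self):
        values = pd.DataFrame(
            {"A": [9.0, 8.0, 1.0, 2.0], "B": [1.0, 2.0, 9.0, 8.0]},
            index=["g1", "g2", "g3", "g4"],
        )
        sets = ns.GeneSetCollection({"S": ["g1", "g2"]})
        res = ns.ssgsea(ns.ExpressionMatrix(values), sets, normalize=False)
        assert res.scores.loc["A", "S"] > res.scores.loc["B", "S"]

    def test_hand_derived_four_gene_toy(self):
        # frozen independent weighted-ECDF summation
        values = pd.DataFrame({"A": [4.0, 3.0, 2.0, 1.0]}, index=["g1", "g2", "g3", "g4"])
        sets = ns.GeneSetCollection({"S": ["g1", "g3"]})
        res = ns.ssgsea(ns.ExpressionMatrix(values), sets, alpha=0.25, normalize=False)
        assert res.scores.loc["A", "S"] == pytest.approx(1.0864272337258898, abs=1e-12)

    def test_alpha_zero_is_unweighted_ecdf_difference(self):
        # closed form: cdf_in - cdf_out summed over (1, .5-.333, 1-.333, 1-.667, 0)
        values = pd.DataFrame({"A": [5.0, 4.0, 3.0, 2.0, 1.0]},
                              index=[f"g{i}" for i in range(1, 6)])
        sets = ns.GeneSetCollection({"S": ["g1", "g3"]})
        res = ns.ssgsea(ns.ExpressionMatrix(values), sets, alpha=0.0, normalize=False)
        expected = (0.5 - 0) + (0.5 - 1 / 3) + (1 - 1 / 3) + (1 - 2 / 3) + 0.0
        assert res.scores.loc["A", "S"] == pytest.approx(expected, abs=1e-12)

    def test_normalized_output_has_unit_range(self, synthetic):
        res = ns.ssgsea(synthetic.expr, synthetic.sets, normalize=True)
        arr = res.scores.to_numpy()
        assert arr.max() - arr.min() == pytest.approx(1.0)

    def test_empty_and_full_sets_skipped(self, small_matrix):
        sets = ns.GeneSetCollection({"none": ["zz"], "all": ["gA", "gB", "gC"],
                                     "ok": ["gA"]})
        res = ns.ssgsea(small_matrix, sets, normalize=False)
        assert list(res.scores.columns) == ["ok"]


class TestLeadingEdgeTopK:
    def test_single_dataset_truncates_by_metric(self):
        edges = {"d1": [[f"g{i}" for i in range(30)]]}
        metric = pd.Series({f"g{i}": 30 - i for i in range(30)})
        top = ns.leading_edge_top_k(edges, metric, k=25)
        assert len(top) == 25
        assert top[0] == "g0"

    def test_disjoint_edges_give_empty_list(self):
        edges = {"d1": [["a", "b"]], "d2": [["c", "d"]]}
        assert ns.leading_edge_top_k(edges, pd.Series(dtype=float), k=25) == []

    def test_small_intersection_returned_in_metric_order(self):
        shared = [f"s{i}" for i in range(10)]
        edges = {"d1": [shared + ["x1"]], "d2": [shared + ["x2"]]}
        metric = pd.Series({g: -(i + 1) for i, g in enumerate(shared)})
        top = ns.leading_edge_top_k(edges, metric, k=25)
        assert top == list(reversed(shared))  # most extreme |metric| first

    def test_union_within_dataset_before_intersection(self):
        """Merged libraries: per-dataset edges are unioned, then intersected."""
        edges = {"d1": [["a"], ["b"]], "d2": [["a", "b"]]}
        metric = pd.Series({"a": 0.9, "b": -0.95})
        assert ns.leading_edge_top_k(edges, metric, k=2) == ["b", "a"]
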