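import numpy as np
import pytest

from markermine.io_formats import TaxonomyNode
from markermine.taxonomy_lca import LcaParams, Taxonomy, assign_lca, summarize_taxa
from oracles import lca_bruteforce, megan_candidates


def _toy_taxonomy():
    #          1 (root)
    #        /   \
    #       2     3          (families F and G)
    #     / | \     \
    #    4  5  6     7       (genera)
    nodes = [
        TaxonomyNode("1", "1", "root", "root"),
        TaxonomyNode("2", "1", "family", "F"),
        TaxonomyNode("3", "1", "family", "G"),
        TaxonomyNode("4", "2", "genus", "A"),
        TaxonomyNode("5", "2", "genus", "B"),
        TaxonomyNode("6", "2", "genus", "C"),
        TaxonomyNode("7", "3", "genus", "D"),
    ]
    return Taxonomy(nodes)


def random_taxonomy(rng, n_nodes):
    nodes = [TaxonomyNode("0", "0", "root", "n0")]
    for i in range(1, n_nodes):
        parent = str(int(rng.integers(0, i)))
        nodes.append(TaxonomyNode(str(i), parent, "clade", f"n{i}"))
    return Taxonomy(nodes)


class TestTaxonomy:
    def test_two_roots_rejected(self):
        with pytest.raises(ValueError, match="one root"):
            Taxonomy([
                TaxonomyNode("1", "1", "root", "a"),
                TaxonomyNode("2", "2", "root", "b"),
            ])

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            Taxonomy([
                TaxonomyNode("1", "1", "root", "a"),
                TaxonomyNode("2", "3", "x", "b"),
                TaxonomyNode("3", "2", "x", "c"),
            ])

    def test_lineage_and_depth(self):
        tax = _toy_taxonomy()
        assert tax.lineage("4") == ["1", "2", "4"]
        assert tax.depth("4") == 2
        assert tax.lca(["4", "5"]) == "2"
        assert tax.lca(["4", "7"]) == "1"


class TestAssignLca:
    def test_single_hit_assigns_its_taxon(self):
        tax = _toy_taxonomy()
        s2t = {"s1": "4"}
        assert assign_lca([("s1", 100.0)], s2t, tax) == "4"

    def test_sibling_genera_collapse_to_family(self):
        tax = _toy_taxonomy()
        s2t = {"s1": "4", "s2": "5"}
        assert assign_lca([("s1", 100.0), ("s2", 100.0)], s2t, tax) == "2"

    def test_ninety_percent_filter_excludes_weak_hits(self):
        # hits 100 (genus A), 95 (genus B), 89 (genus C): 89 < 0.9*100 is
        # excluded, so the result is LCA(A, B) = family F, not root.
        tax = _toy_taxonomy()
        s2t = {"sA": "4", "sB": "5", "sC": "7"}
        hits = [("sA", 100.0), ("sB", 95.0), ("sC", 89.0)]
        assert assign_lca(hits, s2t, tax) == "2"
        # inclusive variant at exactly 90 qualifies a boundary hit
        hits_boundary = [("sA", 100.0), ("sC", 90.0)]
        assert assign_lca(hits_boundary, s2t, tax) == "4"
        assert assign_lca(
            hits_boundary, s2t, tax, LcaParams(strict=False)
        ) == "1"

    def test_truncation_to_max_hits_happens_after_filter(self):
        tax = _toy_taxonomy()
        s2t = {f"s{i}": "4" for i in range(6)} | {"weak": "7"}
        hits = [(f"s{i}", 100.0) for i in range(6)] + [("weak", 95.0)]
        # 7 hits pass the 90% filter; truncation to 5 by (score, id) keeps
        # only genus-A subjects, so the weak genus-D hit never enters.
        assert assign_lca(hits, s2t, tax, LcaParams(max_hits=5)) == "4"

    def test_missing_taxonomy_mapping_is_an_error(self):
        tax = _toy_taxonomy()
        with pytest.raises(KeyError, match="no taxonomy mapping"):
            assign_lca([("s1", 10.0)], {}, tax)

    def test_result_is_ancestor_of_every_candidate(self, rng):
        for _ in range(50):
            tax = random_taxonomy(rng, 30)
            subjects = {f"s{i}": str(int(rng.integers(0, 30))) for i in range(8)}
            hits = [(s, float(rng.uniform(50, 100))) for s in subjects]
            result = assign_lca(hits, subjects, tax)
            kept = megan_candidates(hits)
            for s in kept:
                assert tax.is_ancestor(result, subjects[s])

    def test_stricter_params_move_result_toward_the_candidates(self, rng):
        # shrinking max_hits or raising the fraction keeps the result
        # within the original subtree: the old LCA is an ancestor of the new
        for _ in range(50):
            tax = random_taxonomy(rng, 40)
            subjects = {f"s{i}": str(int(rng.integers(0, 40))) for i in range(10)}
            hits = [(s, float(rng.uniform(80, 100))) for s in subjects]
            base = assign_lca(hits, subjects, tax, LcaParams())
            stricter = assign_lca(
                hits, subjects, tax, LcaParams(max_hits=2, min_score_fraction=0.95)
            )
            assert tax.is_ancestor(base, stricter)

    def test_agrees_with_bruteforce_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 60))
            tax = random_taxonomy(rng, n)
            parent = {t: node.parent for t, node in tax.nodes.items()}
            n_hits = int(rng.integers(1, 9))
            subjects = {f"s{i}": str(int(rng.integers(0, n))) for i in range(n_hits)}
            hits = [(s, float(np.round(rng.uniform(50, 100), 1))) for s in subjects]
            expected = lca_bruteforce(
                parent, [subjects[s] for s in megan_candidates(hits)]
            )
            assert assign_lca(hits, subjects, tax) == expected


class TestSummarizeTaxa:
    def test_single_taxon_gets_fraction_one(self):
        tax = _toy_taxonomy()
        df = summarize_taxa({"d1": ["4", "4", "4"]}, tax)
        assert df.loc["A", "d1"] == 1.0

    def test_rare_group_collapses_to_other(self):
        tax = _toy_taxonomy()
        assignments = {
            "d1": ["4"] * 995 + ["7"] * 5,
            "d2": ["4"] * 995 + ["7"] * 5,
        }
        df = summarize_taxa(assignments, tax)
        assert "D" not in df.index
        assert df.loc["other", "d1"] == pytest.approx(0.005)

    def test_group_above_threshold_in_one_dataset_is_listed(self):
        tax = _toy_taxonomy()
        assignments = {"d1": ["4"] * 90 + ["7"] * 10, "d2": ["4"] * 100}
        df = summarize_taxa(assignments, tax)
        assert df.loc["D", "d1"] == pytest.approx(0.10)
        assert df.loc["D", "d2"] == 0.0

    def test_fractions_sum_to_one(self, rng):
        tax = _toy_taxonomy()
        taxids = [str(int(t)) for t in rng.integers(4, 8, size=500)]
        df = summarize_taxa({"d1": taxids}, tax)
        assert df["d1"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_rank_collapsing(self):
        tax = _toy_taxonomy()
        df = summarize_taxa({"d1": ["4", "5", "7"]}, tax, rank="family")
        assert df.loc["F", "d1"] == pytest.approx(2 / 3)
        assert df.loc["G", "d1"] == pytest.approx(1 / 3)
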