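"""Per-taxon phylogenetic diversity: sums, profiles, adjusted ranking."""

import math

import numpy as np
import pytest

from divkit import synthetic_data, treekit
from divkit.pd_profiler import (
    adjusted_pd_profile,
    compare_rankings,
    pd_profile,
    taxon_pd,
)
from divkit.treekit import decorate, parse_newick


def oracle_pd(tree, node):
    """Edge-enumeration oracle: walk every node's ancestors instead of the
    subtree recursion the implementation uses.  Includes the stem, because
    ``node`` matches itself in the ancestry walk."""
    total = 0.0
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        anc = nd
        while anc is not None:
            if anc is node:
                total += nd.edge.length or 0.0
                break
            anc = anc.parent_node
    return total


class TestTaxonPD:
    def test_singleton_leaf_is_stem_alone(self):
        tree = parse_newick("(A:0.4,B:1.0)R;")
        leaf = next(lf for lf in tree.leaf_node_iter() if lf.taxon.label == "A")
        assert taxon_pd(tree, leaf) == 0.4

    def test_cherry_with_stem(self):
        tree = parse_newick("((A:1,B:2)X:0.5,C:9)R;")
        cherry = next(
            nd for nd in tree.preorder_node_iter()
            if not nd.is_leaf() and nd.parent_node is not None
        )
        assert taxon_pd(tree, cherry) == pytest.approx(3.5)

    def test_root_has_no_stem(self):
        tree = parse_newick("((A:1,B:2)X:0.5,C:9)R:7.0;")
        assert taxon_pd(tree, tree.seed_node) == pytest.approx(1 + 2 + 0.5 + 9)

    def test_agrees_with_edge_enumeration_oracle(self):
        """100 random (tree, node) pairs against the ancestry-walk oracle."""
        rng = np.random.default_rng(11)
        checked = 0
        seed = 0
        while checked < 100:
            sim = synthetic_data.simulate_tree(
                synthetic_data.TreeSimSpec(n_leaves=50, n_phyla=3, seed=seed)
            )
            nodes = list(sim.tree.preorder_node_iter())
            for idx in rng.choice(len(nodes), size=10, replace=False):
                node = nodes[idx]
                expected = oracle_pd(sim.tree, node)
                assert taxon_pd(sim.tree, node) == pytest.approx(expected, abs=1e-12)
                checked += 1
            seed += 1


def _two_phylum_tree():
    # p__X subtree+stem = 1+1+1 = 3; p__Y leaf-pair subtree+stem = 0.3+0.3+0.4 = 1
    return parse_newick("((A:1,B:1)X:1,(C:0.3,D:0.3)Y:0.4)R;")


def _taxonomy(assignment):
    out = {}
    for leaf, phylum in assignment.items():
        out[leaf] = [
            "d__Bacteria", f"p__{phylum}", f"c__{phylum}", f"o__{phylum}",
            f"f__{phylum}", f"g__{phylum}", f"s__{leaf}",
        ]
    return out


class TestProfile:
    def test_two_phyla_normalization(self):
        tree = _two_phylum_tree()
        taxonomy = _taxonomy({"A": "X", "B": "X", "C": "Y", "D": "Y"})
        prof = pd_profile(decorate(tree, taxonomy, "p"))
        by_taxon = {r.taxon: r for r in prof}
        assert by_taxon["p__X"].pd_fraction == pytest.approx(0.75)
        assert by_taxon["p__Y"].pd_fraction == pytest.approx(0.25)
        assert by_taxon["p__X"].rank_position == 1
        assert by_taxon["p__Y"].rank_position == 2

    def test_singleton_enters_denominator(self):
        # add singleton phylum Z with stem 1: fractions 3/5, 1/5, 1/5
        tree = parse_newick("(((A:1,B:1)X:1,(C:0.3,D:0.3)Y:0.4)I:0.0,E:1.0)R;")
        taxonomy = _taxonomy({"A": "X", "B": "X", "C": "Y", "D": "Y", "E": "Z"})
        prof = pd_profile(decorate(tree, taxonomy, "p"))
        fractions = {r.taxon: r.pd_fraction for r in prof}
        assert fractions["p__X"] == pytest.approx(0.6)
        assert fractions["p__Y"] == pytest.approx(0.2)
        assert fractions["p__Z"] == pytest.approx(0.2)
        singleton = next(r for r in prof if r.taxon == "p__Z")
        assert singleton.is_singleton

    @pytest.mark.parametrize("seed", [1, 8])
    def test_reproduces_generator_truth(self, seed):
        sim = synthetic_data.simulate_tree(
            synthetic_data.TreeSimSpec(
                n_leaves=70, n_phyla=5, n_singleton_phyla=2, seed=seed
            )
        )
        prof = pd_profile(decorate(sim.tree, sim.taxonomy, "p"))
        truth = sim.truth_at_rank("p")
        total = math.fsum(t.pd_raw for t in truth.values())
        assert abs(math.fsum(r.pd_fraction for r in prof) - 1.0) <= 1e-9
        for r in prof:
            assert r.pd_raw == pytest.approx(truth[r.taxon].pd_raw, abs=1e-9)
            assert r.pd_fraction == pytest.approx(
                truth[r.taxon].pd_raw / total, abs=1e-9
            )

    def test_raw_sums_bounded_by_total_tree_length(self, small_sim, small_decorated):
        prof = pd_profile(small_decorated)
        total_tree = sum(
            nd.edge.length or 0.0
            for nd in small_sim.tree.preorder_node_iter()
            if nd.parent_node is not None
        )
        assert math.fsum(r.pd_raw for r in prof) <= total_tree + 1e-12

    def test_degenerate_zero_length_tree_raises(self):
        tree = parse_newick("((A:0,B:0)X:0,(C:0,D:0)Y:0)R;")
        taxonomy = _taxonomy({"A": "X", "B": "X", "C": "Y", "D": "Y"})
        with pytest.raises(ValueError, match="degenerate"):
            pd_profile(decorate(tree, taxonomy, "p"))

    def test_consolidation_merges_polyphyly_suffixes(self):
        tree = parse_newick("((A:1,B:1)X:1,(C:0.3,D:0.3)Y:0.4)R;")
        taxonomy = _taxonomy({"A": "X", "B": "X_A", "C": "X_B", "D": "Y"})
        prof = pd_profile(decorate(tree, taxonomy, "p"), consolidate=True)
        names = {r.taxon for r in prof}
        assert names == {"p__X", "p__Y"}
        merged = next(r for r in prof if r.taxon == "p__X")
        # merged pd_raw is the sum over the three suffixed placements
        separate = pd_profile(decorate(tree, taxonomy, "p"))
        expected = sum(r.pd_raw for r in separate if r.taxon.startswith("p__X"))
        assert merged.pd_raw == pytest.approx(expected)


class TestAdjusted:
    def test_symmetric_tree_unchanged(self):
        # uniform lengths, fully symmetric: standard == adjusted
        tree = parse_newick("((A:1,B:1)X:1,(C:1,D:1)Y:1)R;")
        taxonomy = _taxonomy({"A": "X", "B": "X", "C": "Y", "D": "Y"})
        std = pd_profile(decorate(tree, taxonomy, "p"))
        adj = adjusted_pd_profile(tree, taxonomy, "p")
        for s, a in zip(std, adj):
            assert s.taxon == a.taxon
            assert s.pd_fraction == pytest.approx(a.pd_fraction, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 3, 9])
    def test_rate_inflated_clade_shrinks_after_adjustment(self, seed):
        spec = synthetic_data.TreeSimSpec(
            n_leaves=60, n_phyla=4, seed=seed, rate_inflation=("p__P2", 10.0)
        )
        sim = synthetic_data.simulate_tree(spec)
        std = {r.taxon: r for r in pd_profile(decorate(sim.tree, sim.taxonomy, "p"))}
        adj = {r.taxon: r for r in adjusted_pd_profile(sim.tree, sim.taxonomy, "p")}
        assert adj["p__P2"].pd_fraction < std["p__P2"].pd_fraction
        assert adj["p__P2"].rank_position >= std["p__P2"].rank_position


class TestCompareRankings:
    def test_identical_profiles_have_zero_delta(self, small_sim, small_decorated):
        prof = pd_profile(small_decorated)
        table = compare_rankings(prof, prof)
        assert (table["delta"] == 0).all()
        assert not table["missing"].any()

    def test_missing_taxon_flagged(self, small_sim, small_decorated):
        prof = pd_profile(small_decorated)
        table = compare_rankings(prof, prof[:-1])
        assert table["missing"].sum() == 1

    def test_empty_profile_rejected(self, small_decorated):
        with pytest.raises(ValueError):
            compare_rankings(pd_profile(small_decorated), [])
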