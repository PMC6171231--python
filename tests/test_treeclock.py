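"""Neighbour joining, outgroup rooting, branch averages and clock dating."""

import dendropy
import numpy as np
import pytest

from coniphy import datasets
from coniphy.treeclock import (
    CladeTree,
    ClockRate,
    DistanceMatrix,
    branch_average_ks,
    divergence_time,
    nj_tree,
    root_with_outgroup,
)


def _random_binary_tree(n_taxa, rng):
    """Random topology with positive branch lengths; returns (newick, taxa)."""
    nodes = [(f"t{i}", 0.0) for i in range(n_taxa)]  # (subtree, height-ignored)
    subs = [f"t{i}" for i in range(n_taxa)]
    while len(subs) > 2:
        i, j = sorted(rng.choice(len(subs), size=2, replace=False))
        li, lj = rng.uniform(0.05, 0.5, size=2)
        merged = f"({subs[i]}:{li:.6f},{subs[j]}:{lj:.6f})"
        subs = [s for k, s in enumerate(subs) if k not in (i, j)] + [merged]
    la, lb = rng.uniform(0.05, 0.5, size=2)
    newick = f"({subs[0]}:{la:.6f},{subs[1]}:{lb:.6f});"
    return newick, [f"t{i}" for i in range(n_taxa)]


def _tree_distances(newick, taxa):
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    lookup = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(lookup[taxa[i]], lookup[taxa[j]])
    return d


class TestDistanceMatrix:
    def test_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, -1.0], [-1.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[1.0, 0.5], [0.5, 0.0]]))  # diagonal

    def test_tsv_round_trip(self, tmp_path):
        dm = datasets.conifer_ks_matrix()
        dm.write_tsv(tmp_path / "m.tsv")
        again = DistanceMatrix.from_tsv(tmp_path / "m.tsv")
        assert again.taxa == dm.taxa
        np.testing.assert_allclose(again.values, dm.values)


class TestNeighbourJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(DistanceMatrix(("A", "B", "C"), d))
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]])))

    @pytest.mark.parametrize("n_taxa", [4, 5, 7, 10])
    def test_additive_matrix_recovered_exactly(self, n_taxa, rng):
        # distances recomputed from the NJ tree equal the additive input
        newick, taxa = _random_binary_tree(n_taxa, rng)
        d = _tree_distances(newick, taxa)
        out = nj_tree(DistanceMatrix(tuple(taxa), d))
        d_out = _tree_distances(
            out.as_string(schema="newick", unquoted_underscores=True), taxa
        )
        np.testing.assert_allclose(d_out, d, atol=1e-9)

    def test_deterministic_on_tied_matrix(self):
        dm = datasets.conifer_ks_matrix()  # many tied entries
        s1 = nj_tree(dm).as_string(schema="newick")
        s2 = nj_tree(dm).as_string(schema="newick")
        assert s1 == s2

    def test_matches_independent_nj_topology(self, rng):
        # same unrooted topology as scikit-bio's NJ on a noisy matrix
        import skbio

        newick, taxa = _random_binary_tree(8, rng)
        d = _tree_distances(newick, taxa)
        noise = rng.uniform(0, 0.01, size=d.shape)
        d = d + (noise + noise.T)  # keep exact float symmetry
        np.fill_diagonal(d, 0.0)
        ours = nj_tree(DistanceMatrix(tuple(taxa), d))
        ref = skbio.tree.nj(skbio.DistanceMatrix(d, taxa))
        ours_splits = {
            frozenset(l.taxon.label for l in e.head_node.leaf_iter())
            for e in ours.preorder_edge_iter()
            if e.head_node.parent_node is not None
        }
        ref_splits = set()
        for node in ref.traverse():
            if not node.is_root():
                tips = frozenset(t.name for t in node.tips()) or frozenset({node.name})
                ref_splits.add(tips)

        def normalize(splits):
            full = frozenset(taxa)
            return {
                min(s, full - s, key=lambda x: (len(x), sorted(x)))
                for s in splits
                if 1 < len(s) < len(taxa) - 1
            }

        assert normalize(ours_splits) == normalize(ref_splits)


class TestRooting:
    def test_three_taxon_rooting(self):
        d = np.array([[0.0, 0.4, 0.4], [0.4, 0.0, 0.2], [0.4, 0.2, 0.0]])
        ct = root_with_outgroup(nj_tree(DistanceMatrix(("A", "B", "C"), d)), "A")
        assert ct.has_clade({"B", "C"})

    def test_unknown_taxon_rejected(self):
        dm = datasets.conifer_ks_matrix()
        with pytest.raises(ValueError):
            root_with_outgroup(nj_tree(dm), "Sequoia")

    def test_rerooting_idempotent(self):
        dm = datasets.conifer_ks_matrix()
        ct1 = root_with_outgroup(nj_tree(dm), datasets.OUTGROUP)
        ct2 = root_with_outgroup(ct1.tree, datasets.OUTGROUP)
        assert ct1.newick() == ct2.newick()

    def test_conifer_panel_ingroup_is_all_pines(self):
        dm = datasets.conifer_ks_matrix()
        ct = root_with_outgroup(nj_tree(dm), datasets.OUTGROUP)
        pines = set(datasets.CONIFER_TAXA) - {datasets.OUTGROUP}
        assert ct.has_clade(pines)


class TestBranchAverage:
    def test_singleton_clades_reduce_to_entry(self):
        dm = datasets.conifer_ks_matrix()
        assert branch_average_ks(dm, ["P_kesiya"], ["P_taeda"]) == 0.04

    def test_taxon_order_invariance(self):
        dm = datasets.conifer_ks_matrix()
        a = list(datasets.SUBGENUS_STROBUS)
        b = list(datasets.SUBGENUS_PINUS)
        assert branch_average_ks(dm, a, b) == branch_average_ks(dm, a[::-1], b[::-1])

    def test_overlapping_clades_rejected(self):
        dm = datasets.conifer_ks_matrix()
        with pytest.raises(ValueError):
            branch_average_ks(dm, ["P_kesiya", "P_taeda"], ["P_taeda"])

    def test_unknown_taxon_rejected(self):
        dm = datasets.conifer_ks_matrix()
        with pytest.raises(ValueError):
            branch_average_ks(dm, ["P_kesiya"], ["Abies_alba"])


class TestClock:
    def test_linearity(self):
        assert divergence_time(0.2) == pytest.approx(2 * divergence_time(0.1), abs=0.1)

    def test_zero(self):
        assert divergence_time(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            divergence_time(-0.1)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            ClockRate(0.0)

    def test_per_lineage_halves_age(self):
        full = divergence_time(0.146)
        half = divergence_time(0.146, per_lineage=True)
        assert half == pytest.approx(full / 2, abs=0.1)

    def test_published_clock_arithmetic(self):
        # Ks 0.146 at 0.68e-9 /site/yr -> ~214.7 Mya
        assert divergence_time(0.146) == pytest.approx(214.7, abs=0.05)
        assert divergence_time(0.078) == pytest.approx(114.7, abs=0.05)
        assert divergence_time(0.035) == pytest.approx(51.5, abs=0.05)
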