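"""Brownian-motion ancestral states: GLS oracle, reference values, trees."""

import dendropy
import numpy as np
import pandas as pd
import pytest

import archolimb as al
from archolimb.phylo import (
    MAIN_LINE_NODES,
    STUDY_NODES,
    TreeError,
    ace_brownian_many,
    punctuated_tree,
)


def brute_force_ace(newick: str, trait: dict) -> dict:
    """Independent oracle: explicitly re-root with dendropy at every
    internal node and solve the GLS normal equations with V built from
    MRCA depths on the re-rooted tree."""
    base = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    labels = [n.label for n in base.preorder_internal_node_iter()]
    out = {}
    for label in labels:
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=True,
                                 preserve_underscores=True)
        tree.is_rooted = True  # else dendropy's mrca() deroots in place
        if tree.seed_node.label != label:
            node = next(
                n for n in tree.preorder_internal_node_iter()
                if n.label == label
            )
            tree.reroot_at_node(node, update_bipartitions=False)
        tips = [t for t in tree.leaf_node_iter()]
        # V[i, j] = depth (from new root) of mrca(i, j)
        def depth(node):
            d, n = 0.0, node
            while n.parent_node is not None:
                d += n.edge.length or 0.0
                n = n.parent_node
            return d

        pdm = {}
        V = np.zeros((len(tips), len(tips)))
        for i, a in enumerate(tips):
            for j, b in enumerate(tips):
                mrca = tree.mrca(taxa=[a.taxon, b.taxon])
                V[i, j] = depth(mrca)
        ones = np.ones(len(tips))
        x = np.array([trait[t.taxon.label] for t in tips])
        Vinv = np.linalg.inv(V)
        out[label] = float(ones @ Vinv @ x / (ones @ Vinv @ ones))
    return out


SMALL_TREES = [
    "((A:1.0,B:1.0)N1:1.0,C:2.0)R;",
    "((A:1.0,B:2.0)N1:1.0,(C:1.0,D:3.0)N2:2.0)R;",
    "(((A:0.5,B:1.5)N1:0.7,C:2.0)N2:1.0,(D:1.0,E:2.5)N3:0.3)R;",
    "(((A:1.0,(B:0.4,C:0.9)N1:0.6)N2:1.2,D:2.0)N3:0.8,(E:1.5,F:0.7)N4:1.1)R;",
]


class TestTreeIO:
    def test_parse_counts_tips_and_nodes(self):
        t = al.read_tree("((A:1,B:1)N1:1,C:2)R;")
        assert sorted(t.tip_labels) == ["A", "B", "C"]
        assert t.internal_labels == ["R", "N1"]

    def test_round_trip_preserves_structure(self, study_tree, tmp_path):
        text1 = al.write_tree(study_tree)
        again = al.read_tree(text1)
        assert again.tip_labels == study_tree.tip_labels
        assert al.write_tree(again) == text1

    def test_negative_length_rejected(self):
        with pytest.raises(TreeError):
            al.read_tree("((A:1,B:-1)N:1,C:2)R;")

    def test_unlabeled_internal_warns(self):
        with pytest.warns(UserWarning, match="unlabeled"):
            al.read_tree("((A:1,B:1):1,C:2)R;")

    def test_study_tree_shape(self, study_tree):
        assert len(study_tree.tip_labels) == 13
        assert set(study_tree.internal_labels) == set(STUDY_NODES)
        assert study_tree.n_edges() == 24
        assert "Gallus_gallus" in study_tree.tip_labels


class TestPunctuated:
    def test_all_edges_one_and_idempotent(self, study_tree):
        p1 = punctuated_tree(study_tree)
        lengths = [
            n.edge.length for n in p1.tree.preorder_node_iter()
            if n.parent_node is not None
        ]
        assert len(lengths) == 24 and all(l == 1.0 for l in lengths)
        p2 = punctuated_tree(p1)
        assert al.write_tree(p2) == al.write_tree(p1)
        # original untouched
        assert study_tree.tree.seed_node.child_nodes()[0].edge.length == 245.0


class TestAceBrownian:
    def test_two_tips_symmetric_root(self):
        t = al.read_tree("(A:1.0,B:1.0)R;")
        res = al.ace_brownian(t, {"A": 0.0, "B": 1.0})
        assert res["R"] == pytest.approx(0.5)

    def test_constant_trait_gives_constant_nodes(self, study_tree):
        res = al.ace_brownian(study_tree, {t: 0.7 for t in study_tree.tip_labels})
        assert np.allclose(res.estimates, 0.7)
        assert res.sigma2_ml == pytest.approx(0.0, abs=1e-20)
        assert np.allclose(res.ci95_high - res.ci95_low, 0.0, atol=1e-9)

    @pytest.mark.parametrize("newick", SMALL_TREES)
    def test_matches_brute_force_gls_rerooting(self, newick):
        gen = np.random.default_rng(5)
        t = al.read_tree(newick)
        trait = {tip: float(gen.normal()) for tip in t.tip_labels}
        res = al.ace_brownian(t, trait)
        oracle = brute_force_ace(newick, trait)
        for node, est in zip(res.nodes, res.estimates):
            assert est == pytest.approx(oracle[node], rel=1e-8, abs=1e-12)

    def test_matches_reference_fastAnc_values(self, four_taxon_tree):
        """Frozen reference: phytools::fastAnc(vars=TRUE, CI=TRUE) on this
        tree and trait returns exactly these estimates, variances and CIs."""
        res = al.ace_brownian(
            four_taxon_tree, {"A": 1.3, "B": -0.2, "C": 2.1, "D": 0.7}
        )
        expected = {
            "R": (1.158491, 0.499614, -0.226904, 2.543885),
            "N1": (0.943396, 0.272517, -0.079786, 1.966578),
            "N2": (1.588679, 0.299769, 0.515557, 2.661801),
        }
        for node, est, var, lo, hi in zip(
            res.nodes, res.estimates, res.variances, res.ci95_low, res.ci95_high
        ):
            e, v, l, h = expected[node]
            assert est == pytest.approx(e, abs=5e-7)
            assert var == pytest.approx(v, abs=5e-7)
            assert lo == pytest.approx(l, abs=5e-6)
            assert hi == pytest.approx(h, abs=5e-6)

    def test_affine_equivariance(self, study_tree):
        gen = np.random.default_rng(3)
        trait = {t: float(gen.normal()) for t in study_tree.tip_labels}
        a, b = -2.5, 0.3
        r0 = al.ace_brownian(study_tree, trait)
        r1 = al.ace_brownian(study_tree, {k: a * v + b for k, v in trait.items()})
        assert np.allclose(r1.estimates, a * r0.estimates + b, rtol=1e-10)
        w0 = r0.ci95_high - r0.ci95_low
        w1 = r1.ci95_high - r1.ci95_low
        assert np.allclose(w1, abs(a) * w0, rtol=1e-10)

    def test_estimates_within_tip_range(self, study_tree):
        gen = np.random.default_rng(9)
        trait = {t: float(gen.uniform(-1, 1)) for t in study_tree.tip_labels}
        res = al.ace_brownian(study_tree, trait)
        assert res.estimates.min() >= min(trait.values()) - 1e-12
        assert res.estimates.max() <= max(trait.values()) + 1e-12

    def test_missing_tip_value_rejected(self, four_taxon_tree):
        with pytest.raises(TreeError, match="missing"):
            al.ace_brownian(four_taxon_tree, {"A": 1.0, "B": 2.0, "C": 3.0})

    def test_vectorised_replicates_match_scalar(self, study_tree):
        gen = np.random.default_rng(21)
        X = pd.DataFrame(
            gen.normal(size=(5, 13)), columns=study_tree.tip_labels
        )
        many = ace_brownian_many(study_tree, X)
        for i in range(5):
            res = al.ace_brownian(study_tree, X.iloc[i].to_dict())
            assert np.allclose(
                many["estimate"].iloc[i][res.nodes], res.estimates, rtol=1e-12
            )
            assert np.allclose(
                many["variance"].iloc[i][res.nodes], res.variances, rtol=1e-10
            )


class TestAceAll:
    def test_shapes_and_cellwise_consistency(self, study_tree):
        gen = np.random.default_rng(17)
        mtus = [f"M{i}" for i in range(6)]
        traits = pd.DataFrame(
            gen.normal(size=(6, 13)), index=mtus, columns=study_tree.tip_labels
        )
        tables = al.ace_all(study_tree, traits, node_order=tuple(STUDY_NODES))
        assert tables["estimate"].shape == (6, 12)
        assert list(tables["estimate"].columns) == list(STUDY_NODES)
        for mtu in mtus:
            res = al.ace_brownian(study_tree, traits.loc[mtu].to_dict())
            for node, est in zip(res.nodes, res.estimates):
                assert tables["estimate"].loc[mtu, node] == pytest.approx(est)

    def test_constant_traits_give_constant_matrix(self, study_tree):
        traits = pd.DataFrame(
            0.25, index=["M1", "M2"], columns=study_tree.tip_labels
        )
        tables = al.ace_all(study_tree, traits)
        assert np.allclose(tables["estimate"].to_numpy(), 0.25)

    def test_taxon_mismatch_rejected(self, study_tree):
        traits = pd.DataFrame(
            0.1, index=["M1"], columns=study_tree.tip_labels[:-1] + ["Wrong_taxon"]
        )
        with pytest.raises(TreeError, match="mismatch"):
            al.ace_all(study_tree, traits)


def test_main_line_order_matches_study_tree(study_tree):
    """The ancestor main line must be a root-to-leafward path in the tree."""
    tree = study_tree.tree
    nodes = {n.label: n for n in tree.preorder_internal_node_iter()}
    for parent, child in zip(MAIN_LINE_NODES[:-1], MAIN_LINE_NODES[1:]):
        p, c = nodes[parent], nodes[child]
        anc = c.parent_node
        while anc is not None and anc.label != parent:
            anc = anc.parent_node
        assert anc is not None, (parent, child)
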