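"""Phylogenetic correlation, Felsenstein root weights and item scoring."""

import itertools
import math
import random

import numpy as np
import pandas as pd
import pytest

from iridograph import (
    Phylogeny,
    ReportMatrix,
    felsenstein_root_weight,
    phylo_correlation,
    score_items,
)
from iridograph.phylo import _transition


def exhaustive_root_weight(tree, presence, rate=1.0, prior=0.5):
    """Brute-force oracle: sum the joint likelihood over every assignment of
    states to the internal nodes and the root."""
    nodes = list(tree.tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    tips = [n for n in nodes if n.is_leaf()]
    total = {0: 0.0, 1: 0.0}
    for assign in itertools.product((0, 1), repeat=len(internal)):
        state = dict(zip(map(id, internal), assign))
        for tip_states in itertools.product((0, 1), repeat=len(tips)):
            ok = True
            for t, s in zip(tips, tip_states):
                obs = presence.get(t.taxon.label, None)
                if obs is True and s != 1:
                    ok = False
                    break
            if not ok:
                continue
            like = 1.0
            full = dict(state)
            full.update({id(t): s for t, s in zip(tips, tip_states)})
            for n in nodes:
                if n.parent_node is None:
                    like *= prior if full[id(n)] == 1 else (1 - prior)
                else:
                    same, diff = _transition(n.edge.length or 0.0, rate)
                    like *= same if full[id(n)] == full[id(n.parent_node)] else diff
            total[assign[0] if internal else tip_states[0]] += like
    z = total[0] + total[1]
    return total[1] / z if z else prior


def random_tree(n_tips, seed):
    from iridograph.fixtures import random_phylogeny

    return random_phylogeny(n_tips=n_tips, seed=seed, ultrametric=False)


class TestCorrelation:
    def test_star_tree_gives_identity(self, star_tree):
        corr = phylo_correlation(star_tree)
        assert np.allclose(corr.values, np.eye(4))

    def test_unit_diagonal(self, three_taxon_tree):
        corr = phylo_correlation(three_taxon_tree)
        assert np.allclose(np.diag(corr.values), 1.0)

    def test_sister_pair_shares_080_of_history(self, three_taxon_tree):
        # shared branch 0.8 on depth-1 tips: corr = 0.8/sqrt(1*1)
        corr = phylo_correlation(three_taxon_tree)
        assert corr.loc["A", "B"] == pytest.approx(0.8)
        assert corr.loc["A", "C"] == pytest.approx(0.0)

    def test_positive_semidefinite(self):
        for seed in range(5):
            corr = phylo_correlation(random_tree(7, seed))
            eig = np.linalg.eigvalsh(corr.values)
            assert eig.min() > -1e-9

    def test_zero_depth_tip_is_an_error(self):
        tree = Phylogeny.from_newick("((A:0.0,B:0.5):0.0,C:0.5);")
        with pytest.raises(ValueError):
            phylo_correlation(tree)


class TestFelsenstein:
    def test_uniform_presence_tends_to_one_on_short_branches(self):
        for scale in (1.0, 0.1, 0.01):
            tree = Phylogeny.from_newick(
                f"((A:{scale},B:{scale}):{scale},C:{2 * scale});"
            )
            w = felsenstein_root_weight(tree, {"A": True, "B": True, "C": True})
            assert w > 0.5
        assert w > 0.99  # smallest scale

    def test_all_missing_returns_the_prior(self, three_taxon_tree):
        w = felsenstein_root_weight(three_taxon_tree, {"A": False})
        assert w == pytest.approx(0.5)

    def test_empty_presence_map_is_an_error(self, three_taxon_tree):
        with pytest.raises(ValueError):
            felsenstein_root_weight(three_taxon_tree, {})

    def test_single_present_tip_matches_exhaustive_enumeration(
        self, three_taxon_tree
    ):
        presence = {"A": True}
        got = felsenstein_root_weight(three_taxon_tree, presence)
        want = exhaustive_root_weight(three_taxon_tree, presence)
        assert got == pytest.approx(want, abs=1e-10)

    def test_pruning_equals_enumeration_on_small_trees(self):
        """<=5 tips, random characters: agreement to 1e-10."""
        rng = random.Random(42)
        for seed in range(8):
            n = rng.randint(2, 5)
            tree = random_tree(n, seed)
            tips = tree.tips
            presence = {t: True for t in tips if rng.random() < 0.5}
            if not presence:
                presence = {tips[0]: True}
            got = felsenstein_root_weight(tree, presence)
            want = exhaustive_root_weight(tree, presence)
            assert got == pytest.approx(want, abs=1e-10)

    def test_weight_monotone_in_number_of_present_tips(self):
        for seed in range(4):
            tree = random_tree(6, seed)
            tips = tree.tips
            prev = 0.0
            for k in range(1, len(tips) + 1):
                w = felsenstein_root_weight(
                    tree, {t: True for t in tips[:k]}
                )
                assert w >= prev - 1e-12
                prev = w


class TestScoreItems:
    def test_identity_correlation_returns_raw_presence(self, star_tree):
        m = ReportMatrix.from_pairs(
            [("A", "x", "reported"), ("B", "y", "reported")],
            genera=["A", "B", "C", "D"],
        )
        scores = score_items(m, star_tree, scheme="correlation")
        assert scores.per_genus.loc["A", "x"] == pytest.approx(1.0)
        assert scores.per_genus.loc["B", "x"] == pytest.approx(0.0)

    def test_two_genus_hand_product(self):
        # corr(A,B)=0.6: item present in both scores 1.6 for each focal genus
        tree = Phylogeny.from_newick("((A:0.4,B:0.4):0.6,C:1.0);")
        m = ReportMatrix.from_pairs(
            [("A", "x", "reported"), ("B", "x", "reported")],
            genera=["A", "B", "C"],
        )
        scores = score_items(m, tree, scheme="correlation")
        assert scores.per_genus.loc["A", "x"] == pytest.approx(1.6)
        assert scores.per_genus.loc["B", "x"] == pytest.approx(1.6)

    def test_ubiquitous_item_maximizes_both_schemes(self, three_taxon_tree):
        pairs = [(g, "everywhere", "reported") for g in ("A", "B", "C")]
        pairs += [("A", "rare", "reported")]
        m = ReportMatrix.from_pairs(pairs)
        for scheme in ("correlation", "felsenstein"):
            scores = score_items(m, three_taxon_tree, scheme=scheme)
            assert (
                scores.aggregate["everywhere"]
                == scores.aggregate.max()
            )

    def test_unknown_scheme_or_basis_is_an_error(self, three_taxon_tree):
        m = ReportMatrix.from_pairs([("A", "x", "reported")])
        with pytest.raises(ValueError):
            score_items(m, three_taxon_tree, scheme="parsimony")
        with pytest.raises(ValueError):
            score_items(m, three_taxon_tree, basis="imagined")

    def test_vectorized_weights_match_the_scalar_recursion(self):
        from iridograph.phylo import felsenstein_root_weights_matrix

        rng = random.Random(3)
        tree = random_tree(6, 2)
        tips = tree.tips
        presence = pd.DataFrame(
            [[rng.random() < 0.5 for _ in range(12)] for _ in tips],
            index=tips,
            columns=[f"item{i}" for i in range(12)],
        )
        vec = felsenstein_root_weights_matrix(tree, presence)
        for item in presence.columns:
            scalar = felsenstein_root_weight(
                tree, {g: bool(presence.loc[g, item]) for g in tips}
            )
            assert vec[item] == pytest.approx(scalar, abs=1e-12)

    def test_felsenstein_weights_lie_in_unit_interval(self, three_taxon_tree):
        m = ReportMatrix.from_pairs(
            [("A", "x", "reported"), ("B", "y", "reported"), ("C", "y", "reported")]
        )
        scores = score_items(m, three_taxon_tree, scheme="felsenstein")
        assert ((scores.aggregate >= 0) & (scores.aggregate <= 1)).all()
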