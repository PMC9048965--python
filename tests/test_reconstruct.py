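"""Naïve prediction, tolerance pruning and the ancestral pathway."""

import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from iridograph import (
    Phylogeny,
    ReportMatrix,
    ReconstructionParams,
    ancestral_pathway,
    naive_predict,
    prune_hypothesis,
    reconstruct_all,
)
from iridograph.phylo import ItemScores
from iridograph.reconstruct import (
    _minimal_connectors_exact,
    section5_preset,
)


def toy_reports(*pairs, genera=None):
    return ReportMatrix.from_pairs(
        [(g, item, "reported") for g, item in pairs], genera=genera
    )


def vertex_scores(genus, mapping):
    per_genus = pd.DataFrame([mapping], index=[genus])
    return {
        "vertices": ItemScores(
            per_genus=per_genus,
            aggregate=per_genus.sum(axis=0),
            scheme="correlation",
            basis="reported",
        )
    }


class TestNaivePredict:
    def test_zero_extension_links_adjacent_reports(self, toy_space):
        m = toy_reports(("G", "0,0"), ("G", "1,0"))
        naive = naive_predict(m, toy_space, 0)["G"]
        assert naive.number_of_nodes() == 2
        assert naive.number_of_edges() == 1

    def test_zero_extension_single_report(self, toy_space):
        m = toy_reports(("G", "0,0"))
        naive = naive_predict(m, toy_space, 0)["G"]
        assert naive.number_of_nodes() == 1
        assert naive.number_of_edges() == 0

    def test_one_extension_bridges_a_two_step_gap(self, toy_space):
        """Opposite hypercube corners join once intermediates appear."""
        m = toy_reports(("G", "0,0"), ("G", "1,1"))
        naive0 = naive_predict(m, toy_space, 0)["G"]
        assert not nx.is_connected(naive0)
        naive1 = naive_predict(m, toy_space, 1)["G"]
        assert nx.is_connected(naive1)
        # BFS-radius oracle: nodes within 1 step of either report
        expected = set()
        for key in ("0,0", "1,1"):
            from iridograph import parse_code

            code = parse_code(key, toy_space.config)
            i = toy_space.node_id(code)
            expected |= {i} | set(toy_space.neighbor_ids(i))
        assert set(naive1.nodes) == expected

    def test_unknown_scaffold_is_named_in_the_error(self, toy_space):
        m = toy_reports(("G", "7,7"))
        with pytest.raises(KeyError, match="7,7"):
            naive_predict(m, toy_space, 0)


class TestPruning:
    def diamond(self, toy_space):
        m = toy_reports(("G", "0,0"), ("G", "1,1"))
        return naive_predict(m, toy_space, 1)["G"]

    def test_connector_enumeration_oracle(self, toy_space):
        naive = self.diamond(toy_space)
        reported = {
            n for n, d in naive.nodes(data=True) if d["status"] == "reported"
        }
        connectors = _minimal_connectors_exact(naive, reported)
        # the diamond has exactly two minimal connectors: via either corner
        assert len(connectors) == 2
        assert all(len(c) == 3 for c in connectors)

    def test_tolerance_separates_the_two_routes(self, toy_space):
        naive = self.diamond(toy_space)
        scores = vertex_scores(
            "G", {"0,0": 4.0, "1,1": 4.0, "1,0": 2.0, "0,1": 0.0}
        )
        tight = prune_hypothesis(
            "G", naive, toy_space,
            scores, ReconstructionParams(1, "reported", "correlation",
                                         "vertices", 10.0),
        )
        loose = prune_hypothesis(
            "G", naive, toy_space,
            scores, ReconstructionParams(1, "reported", "correlation",
                                         "vertices", 20.0),
        )
        # 10% of max 10 keeps only the 10-route; 20% readmits the 8-route
        assert tight.graph.number_of_nodes() == 3
        assert loose.graph.number_of_nodes() == 4

    def test_full_tolerance_returns_the_whole_component(self, toy_space):
        naive = self.diamond(toy_space)
        hyp = prune_hypothesis(
            "G", naive, toy_space, vertex_scores("G", {}),
            ReconstructionParams(1, "reported", "correlation",
                                 "vertices", 100.0),
        )
        assert set(hyp.graph.nodes) == set(naive.nodes)
        assert set(hyp.graph.edges) == set(naive.edges)

    def test_single_reported_component_survives_any_tolerance(self, toy_space):
        m = toy_reports(("G", "0,0"))
        naive = naive_predict(m, toy_space, 0)["G"]
        for tol in (0.0, 50.0, 100.0):
            hyp = prune_hypothesis(
                "G", naive, toy_space, vertex_scores("G", {"0,0": 1.0}),
                ReconstructionParams(0, "reported", "correlation",
                                     "vertices", tol),
            )
            assert hyp.graph.number_of_nodes() == 1

    def test_monotone_in_tolerance(self, space):
        """Hypothesis at tolerance t is a subgraph of tolerance t' >= t."""
        import iridograph as ig

        bundle = ig.generate_fixture(space, seed=11)
        prev_nodes, prev_edges = None, None
        naive = naive_predict(bundle.reports, space, 0)
        from iridograph.reconstruct import score_for_params

        for tol in (0.0, 30.0, 60.0, 100.0):
            params = ReconstructionParams(
                0, "reported", "correlation", "vertices", tol
            )
            scores = score_for_params(
                bundle.reports, space, bundle.tree, naive, params
            )
            genus = bundle.reports.genera[0]
            hyp = prune_hypothesis(genus, naive[genus], space, scores, params)
            nodes = set(hyp.graph.nodes)
            edges = set(map(tuple, map(sorted, hyp.graph.edges)))
            if prev_nodes is not None:
                assert prev_nodes <= nodes
                assert prev_edges <= edges
            prev_nodes, prev_edges = nodes, edges

    def test_no_reported_scaffold_is_dropped_at_full_tolerance(self, space):
        import iridograph as ig

        bundle = ig.generate_fixture(space, seed=13)
        params = ReconstructionParams(
            2, "reported", "correlation", "vertices", 100.0
        )
        hyps = reconstruct_all(bundle.reports, space, bundle.tree, params)
        for genus, hyp in hyps.items():
            row = bundle.reports.reported.loc[genus]
            for item in bundle.reports.items:
                if row[item]:
                    code = ig.parse_code(item, space.config)
                    assert space.node_id(code) in hyp.graph


class TestAncestral:
    def two_genus_hyps(self, toy_space, genera_items, params=None):
        params = params or ReconstructionParams(0, "reported", "correlation",
                                                "vertices", 100.0)
        hyps = {}
        for genus, items in genera_items.items():
            m = toy_reports(*[(genus, i) for i in items])
            naive = naive_predict(m, toy_space, 0)[genus]
            hyps[genus] = prune_hypothesis(
                genus, naive, toy_space, vertex_scores(genus, {}), params
            )
        return hyps

    def test_shared_item_on_shallow_tree_is_retained(self, toy_space):
        tree = Phylogeny.from_newick("((A:0.01,B:0.01):0.01,C:0.02);")
        hyps = self.two_genus_hyps(
            toy_space,
            {"A": ["0,0"], "B": ["0,0"], "C": ["0,0"]},
        )
        anc = ancestral_pathway(hyps, tree, toy_space, threshold=0.9)
        assert anc.number_of_nodes() == 1

    def test_private_item_on_long_branch_is_excluded(self, toy_space):
        tree = Phylogeny.from_newick("((A:1.0,B:1.0):0.5,C:1.5);")
        hyps = self.two_genus_hyps(
            toy_space,
            {"A": ["0,0", "1,0"], "B": ["0,0"], "C": ["0,0"]},
        )
        anc = ancestral_pathway(hyps, tree, toy_space, threshold=0.9)
        kept_codes = {d["code"] for _, d in anc.nodes(data=True)}
        assert "1,0" not in kept_codes

    def test_threshold_outside_unit_interval_is_an_error(self, toy_space):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        hyps = self.two_genus_hyps(toy_space, {"A": ["0,0"], "B": ["0,0"]})
        with pytest.raises(ValueError):
            ancestral_pathway(hyps, tree, toy_space, threshold=1.5)


class TestSection5Preset:
    def test_preset_connects_isolated_reports_when_possible(self, space):
        import iridograph as ig

        bundle = ig.generate_fixture(space, seed=17)
        hyps0 = reconstruct_all(
            bundle.reports, space, bundle.tree,
            ReconstructionParams(0, "reported", "correlation", "vertices", 10.0),
        )
        hyps = section5_preset(bundle.reports, space, bundle.tree)
        # the preset never loses reported scaffolds ...
        for genus in bundle.reports.genera:
            assert hyps0[genus].reported_nodes <= hyps[genus].reported_nodes
        # ... and strictly reduces isolation or keeps it unchanged
        for genus in bundle.reports.genera:
            iso0 = sum(
                1 for n in hyps0[genus].reported_nodes
                if hyps0[genus].graph.degree(n) == 0
            )
            iso1 = sum(
                1 for n in hyps[genus].reported_nodes
                if hyps[genus].graph.degree(n) == 0
            )
            assert iso1 <= iso0
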