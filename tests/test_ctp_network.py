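"""Compound–target–pathway network assembly, ranking, and export."""

import numpy as np
import pandas as pd
import pytest

from phytonet.ctp_network import (
    assemble,
    export_cytoscape,
    rank_compounds,
    select_key_compounds,
    summarize,
)
from phytonet.datasets import KEY_COMPOUNDS, KEY_TARGETS, compound_target_edges


@pytest.fixture
def marker_net():
    """Network of the bundled seven marker compounds and nine key targets."""
    return assemble(compound_target_edges(), [], KEY_TARGETS)


class TestAssemble:
    def test_node_counts_add_up(self, marker_net):
        summary = summarize(marker_net)
        assert summary["nodes"]["compound"] == 7
        assert summary["nodes"]["target"] == 9
        assert summary["nodes"]["total"] == 16

    def test_full_roster_reaches_published_size(self):
        """143 compounds + 9 targets + 20 pathways = 172 nodes."""
        compounds = [f"cmp{i:03d}" for i in range(143)]
        pathways = [f"PWY{i:02d}" for i in range(20)]
        ct = [(c, KEY_TARGETS[i % 9]) for i, c in enumerate(compounds)]
        tp = [(KEY_TARGETS[i % 9], p) for i, p in enumerate(pathways)]
        net = assemble(ct, tp, KEY_TARGETS)
        assert net.number_of_nodes() == 172

    def test_empty_inputs_empty_network(self):
        net = assemble([], [], [])
        assert net.number_of_nodes() == 0 and net.number_of_edges() == 0

    def test_duplicate_edges_collapse(self):
        net = assemble([("c1", "TNF"), ("c1", "TNF")], [], ["TNF"])
        assert net.number_of_edges() == 1

    def test_non_key_target_edges_dropped(self):
        net = assemble([("c1", "TNF"), ("c2", "NOTKEY")], [], ["TNF"])
        labels = {d["label"] for _, d in net.nodes(data=True) if d["layer"] == "compound"}
        assert labels == {"c1"}

    def test_no_cross_layer_violations(self, marker_net):
        for u, v in marker_net.edges:
            layers = {marker_net.nodes[u]["layer"], marker_net.nodes[v]["layer"]}
            assert layers in ({"compound", "target"}, {"target", "pathway"})

    def test_order_independent(self):
        edges = compound_target_edges()
        rng = np.random.default_rng(0)
        shuffled = [edges[i] for i in rng.permutation(len(edges))]
        a = export_cytoscape(assemble(edges, [], KEY_TARGETS))
        b = export_cytoscape(assemble(shuffled, [], KEY_TARGETS))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])


class TestRanking:
    def test_published_marker_degrees(self, marker_net):
        """Each marker compound's degree equals its correlating-target count
        (scopoletin 4; the other six compounds 3)."""
        ranks = {r.compound_id: r for r in rank_compounds(marker_net)}
        for compound in KEY_COMPOUNDS:
            assert ranks[compound.name].degree == len(compound.targets)
            assert ranks[compound.name].correlating_targets == tuple(sorted(compound.targets))
        assert rank_compounds(marker_net)[0].compound_id == "Scopoletin"

    def test_degree_sum_equals_ct_edges(self, marker_net):
        ranks = rank_compounds(marker_net)
        assert sum(r.degree for r in ranks) == summarize(marker_net)["edges"]["compound-target"]

    def test_zero_degree_roster_compound_ranks_last(self):
        net = assemble([("c1", "TNF")], [], ["TNF"], roster={"compound": ["lonely"]})
        ranks = rank_compounds(net)
        assert ranks[-1].compound_id == "lonely" and ranks[-1].degree == 0


class TestSelection:
    def test_degree_threshold_recovers_seven_markers(self, marker_net):
        selected = select_key_compounds(rank_compounds(marker_net), degree_min=3)
        assert {r.compound_id for r in selected} == {c.name for c in KEY_COMPOUNDS}

    def test_degree_five_selects_none(self, marker_net):
        assert select_key_compounds(rank_compounds(marker_net), degree_min=5) == []

    def test_top_one_is_scopoletin(self, marker_net):
        top = select_key_compounds(rank_compounds(marker_net), top_k=1)
        assert [r.compound_id for r in top] == ["Scopoletin"]

    def test_argument_validation(self, marker_net):
        ranks = rank_compounds(marker_net)
        with pytest.raises(ValueError):
            select_key_compounds(ranks, top_k=0)
        with pytest.raises(ValueError):
            select_key_compounds(ranks)
        with pytest.raises(ValueError):
            select_key_compounds(ranks, top_k=1, degree_min=1)


class TestExport:
    def test_row_counts(self, marker_net):
        nodes, edges = export_cytoscape(marker_net)
        assert (nodes["layer"] == "compound").sum() == 7
        assert (nodes["layer"] == "target").sum() == 9
        assert len(edges) == marker_net.number_of_edges()

    def test_empty_network_header_only(self):
        nodes, edges = export_cytoscape(assemble([], [], []))
        assert nodes.empty and list(nodes.columns) == ["id", "layer", "label", "degree"]
        assert edges.empty and list(edges.columns) == ["source", "target", "interaction"]

    def test_round_trip(self, marker_net, tmp_path):
        nodes, edges = export_cytoscape(marker_net)
        nodes.to_csv(tmp_path / "n.tsv", sep="\t", index=False)
        edges.to_csv(tmp_path / "e.tsv", sep="\t", index=False)
        n2 = pd.read_csv(tmp_path / "n.tsv", sep="\t")
        e2 = pd.read_csv(tmp_path / "e.tsv", sep="\t")
        rebuilt = assemble(
            [(e2_row["source"][4:], e2_row["target"][4:]) for _, e2_row in e2.iterrows()
             if e2_row["interaction"] == "compound-target"],
            [(r["source"][4:], r["target"][4:]) for _, r in e2.iterrows()
             if r["interaction"] == "target-pathway"],
            n2.loc[n2["layer"] == "target", "label"],
        )
        assert rebuilt.number_of_nodes() == marker_net.number_of_nodes()
        assert rebuilt.number_of_edges() == marker_net.number_of_edges()
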