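"""Adjacency / contacting cell networks, permutation z-scores and aggregation."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from spatcell import (
    CellPattern,
    LabelMask,
    Window,
    assemble_network,
    bh_fdr,
    build_acn,
    ccn_condition,
    ccn_edges,
    edge_keep,
    weighted_stouffer,
)
from spatcell.contact import ConsistencyError


def mask_pattern(pix, types):
    mask = LabelMask(np.asarray(pix, dtype=np.int64))
    labels = sorted(set(np.unique(pix)) - {0})
    cells = pd.DataFrame(
        {
            "cell_id": labels,
            "x": np.linspace(1, 2, len(labels)),
            "y": np.linspace(1, 2, len(labels)),
            "cell_type": [types[i] for i in labels],
        }
    )
    pattern = CellPattern("r", "c", Window(100, 100), cells)
    return mask, pattern


class TestBuildACN:
    def test_shared_edge_contact(self):
        pix = np.zeros((10, 20), dtype=int)
        pix[:, :10] = 1
        pix[:, 10:] = 2
        mask, pattern = mask_pattern(pix, {1: "A", 2: "B"})
        g = build_acn(mask, pattern)
        assert list(g.edges) == [(1, 2)]

    def test_one_pixel_gap_is_not_contact(self):
        pix = np.zeros((10, 21), dtype=int)
        pix[:, :10] = 1
        pix[:, 11:] = 2
        mask, pattern = mask_pattern(pix, {1: "A", 2: "B"})
        g = build_acn(mask, pattern)
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {1, 2}  # isolated cells stay in the graph

    def test_three_in_a_row_path_graph(self):
        pix = np.zeros((5, 30), dtype=int)
        pix[:, :10] = 1
        pix[:, 10:20] = 2
        pix[:, 20:] = 3
        mask, pattern = mask_pattern(pix, {1: "A", 2: "B", 3: "A"})
        g = build_acn(mask, pattern)
        assert sorted(g.edges) == [(1, 2), (2, 3)]

    def test_diagonal_contact_rule_switch(self):
        pix = np.zeros((4, 4), dtype=int)
        pix[:2, :2] = 1
        pix[2:, 2:] = 2  # corners meet diagonally
        mask, pattern = mask_pattern(pix, {1: "A", 2: "B"})
        assert build_acn(mask, pattern, "chebyshev1").number_of_edges() == 1
        assert build_acn(mask, pattern, "edge_only").number_of_edges() == 0

    def test_unknown_label_raises(self):
        pix = np.zeros((4, 4), dtype=int)
        pix[0, 0] = 9
        mask = LabelMask(pix.astype(np.int64))
        cells = pd.DataFrame(
            {"cell_id": [1], "x": [1.0], "y": [1.0], "cell_type": ["A"]}
        )
        pattern = CellPattern("r", "c", Window(10, 10), cells)
        with pytest.raises(ConsistencyError, match="9"):
            build_acn(mask, pattern)


def geometric_graph_pattern(n, types, seed, radius=40.0, w=1000.0):
    """Random geometric contact graph with typed nodes (no mask needed)."""
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, w, size=(n, 2))
    labels = rng.choice(types, n)
    cells = pd.DataFrame(
        {"cell_id": np.arange(1, n + 1), "x": xy[:, 0], "y": xy[:, 1], "cell_type": labels}
    )
    pattern = CellPattern("r", "c", Window(w, w), cells)
    g = nx.Graph()
    for i in range(n):
        g.add_node(i + 1, cell_type=labels[i])
    from scipy.spatial import cKDTree

    pairs = cKDTree(xy).query_pairs(radius)
    g.add_edges_from((i + 1, j + 1) for i, j in pairs)
    return g, pattern


class TestCCNEdges:
    def test_bipartite_structure_yields_top_positive_z(self):
        # contacts exist only between A and B cells; C is isolated
        g = nx.Graph()
        types = {}
        for i in range(1, 11):
            types[i] = "A" if i <= 5 else "B"
        for i in range(11, 17):
            types[i] = "C"
        for i, t in types.items():
            g.add_node(i, cell_type=t)
        for a in range(1, 6):
            for b in range(6, 11):
                g.add_edge(a, b)
        cells = pd.DataFrame(
            {
                "cell_id": list(types),
                "x": np.linspace(1, 50, len(types)),
                "y": np.linspace(1, 50, len(types)),
                "cell_type": list(types.values()),
            }
        )
        pattern = CellPattern("r", "c", Window(100, 100), cells)
        df = ccn_edges(g, pattern, n_perm=300, seed=1)
        ab = df.set_index(["type_a", "type_b"])
        assert ab.loc[("A", "B"), "z"] > 0
        best = df.loc[df["z"].idxmax()]
        assert {best["type_a"], best["type_b"]} == {"A", "B"}

    def test_avoidance_yields_negative_z(self):
        # 30 disjoint contact pairs, all A–C or B–C: A never touches B
        # although many A–B contacts would arise under random labelling
        g = nx.Graph()
        labels = {}
        nid = 1
        for k in range(30):
            t = "A" if k < 15 else "B"
            labels[nid], labels[nid + 1] = t, "C"
            g.add_edge(nid, nid + 1)
            nid += 2
        for i, t in labels.items():
            g.nodes[i]["cell_type"] = t
        cells = pd.DataFrame(
            {
                "cell_id": list(labels),
                "x": np.linspace(1, 90, len(labels)),
                "y": np.linspace(1, 90, len(labels)),
                "cell_type": list(labels.values()),
            }
        )
        pattern = CellPattern("r", "c", Window(100, 100), cells)
        df = ccn_edges(g, pattern, n_perm=300, seed=2).set_index(["type_a", "type_b"])
        assert df.loc[("A", "B"), "o_ab"] == 0
        assert df.loc[("A", "B"), "z"] < 0

    def test_count_and_proportion_z_identical(self):
        """With N_A fixed under label permutation, standardising the count
        O_AB and the proportion O_AB/N_A gives the same z-score."""
        g, pattern = geometric_graph_pattern(150, ["A", "B", "C"], seed=3)
        df = ccn_edges(g, pattern, n_perm=300, seed=4)
        ok = ~df["degenerate"]
        z_prop = (
            df.loc[ok, "proportion_a"]
            - df.loc[ok, "null_mean"] / df.loc[ok, "n_a"]
        ) / (df.loc[ok, "null_sd"] / df.loc[ok, "n_a"])
        assert np.allclose(z_prop, df.loc[ok, "z"], rtol=1e-12)

    def test_random_labels_calibrated(self):
        zs = []
        for seed in range(12):
            g, pattern = geometric_graph_pattern(200, ["A", "B", "C"], seed=100 + seed)
            df = ccn_edges(g, pattern, n_perm=300, seed=seed)
            zs.extend(df.loc[~df["degenerate"], "z"].tolist())
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.3
        assert 0.6 < zs.std() < 1.4

    def test_degenerate_sd_flagged(self):
        g = nx.Graph()
        g.add_node(1, cell_type="A")
        g.add_node(2, cell_type="A")
        cells = pd.DataFrame(
            {"cell_id": [1, 2], "x": [1.0, 2.0], "y": [1.0, 2.0], "cell_type": ["A", "A"]}
        )
        pattern = CellPattern("r", "c", Window(10, 10), cells)
        df = ccn_edges(g, pattern, n_perm=100, seed=5)
        assert df["degenerate"].all()
        assert (df["p"] == 1.0).all()

    def test_determinism(self):
        g, pattern = geometric_graph_pattern(100, ["A", "B"], seed=6)
        d1 = ccn_edges(g, pattern, n_perm=200, seed=7)
        d2 = ccn_edges(g, pattern, n_perm=200, seed=7)
        pd.testing.assert_frame_equal(d1, d2)


class TestConditionAggregation:
    @staticmethod
    def roi_frame(rows):
        return pd.DataFrame(
            [
                {
                    "roi_id": f"r{i}", "condition": "c", "type_a": "A", "type_b": "B",
                    "n_a": na, "o_ab": o, "proportion_a": 0.5, "null_mean": 0.0,
                    "null_sd": 1.0, "z": z, "p": p, "degenerate": False, "q": p,
                }
                for i, (z, p, na, o) in enumerate(rows)
            ]
        )

    def test_zero_weight_roi_ignored(self):
        df = self.roi_frame([(2.0, 0.02, 10, 5), (9.0, 1e-9, 0, 0)])
        out = ccn_condition(df)
        assert out.loc[0, "z"] == pytest.approx(2.0)
        # one-sided Stouffer of a single ROI reduces to that ROI's Φ̄(z)
        assert out.loc[0, "p"] == pytest.approx(norm.sf(2.0))

    def test_weighted_mean_z(self):
        df = self.roi_frame([(2.0, 0.05, 10, 5), (0.0, 0.5, 10, 0)])
        out = ccn_condition(df)
        assert out.loc[0, "z"] == pytest.approx(1.0)

    def test_equal_weight_stouffer_closed_form(self):
        z, p = weighted_stouffer([0.05, 0.05], [1.0, 1.0])
        assert z == pytest.approx(norm.ppf(0.95) * np.sqrt(2), abs=1e-4)
        assert p == pytest.approx(0.0100, abs=5e-5)

    def test_all_degenerate_flagged_undefined(self):
        df = self.roi_frame([(np.nan, 1.0, 10, 0)])
        df["degenerate"] = True
        out = ccn_condition(df)
        assert not out.loc[0, "defined"]


class TestNetworkAssembly:
    def test_filter_truth_table(self):
        for g20, z, p in itertools.product([0.5, 2.0], [-1.0, 1.0], [0.2, 0.01]):
            assert edge_keep(g20, z, p) == (g20 > 1 and z > 0 and p < 0.05)

    def test_all_fail_gives_empty_network(self):
        edges = pd.DataFrame(
            [{"condition": "c", "type_a": "A", "type_b": "B", "z": -1.0,
              "p": 0.9, "q": 0.9, "total_contacts": 3, "defined": True}]
        )
        G, table, comms = assemble_network(edges, {("A", "B"): 2.0})
        assert G.number_of_edges() == 0 and comms == []
        assert not table["keep"].any()

    def test_missing_g20_drops_edge_with_warning(self):
        edges = pd.DataFrame(
            [{"condition": "c", "type_a": "A", "type_b": "B", "z": 3.0,
              "p": 0.001, "q": 0.002, "total_contacts": 3, "defined": True}]
        )
        with pytest.warns(UserWarning, match="dropped"):
            G, table, _ = assemble_network(edges, {})
        assert not table["keep"].any()

    def test_two_communities_recovered(self):
        rows = []
        for a, b in [("A", "B"), ("B", "A"), ("C", "D"), ("D", "C")]:
            rows.append({"condition": "c", "type_a": a, "type_b": b, "z": 4.0,
                         "p": 1e-5, "q": 1e-4, "total_contacts": 10, "defined": True})
        edges = pd.DataFrame(rows)
        g20 = {k: 3.0 for k in [("A", "B"), ("B", "A"), ("C", "D"), ("D", "C")]}
        G, table, comms = assemble_network(edges, g20)
        assert nx.number_connected_components(G) == 2
        assert {frozenset(c) for c in comms} == {frozenset({"A", "B"}), frozenset({"C", "D"})}


class TestBHFDR:
    def test_hand_step_up_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_its_own_q(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0, 1, 20)
        perm = rng.permutation(20)
        q = bh_fdr(p)
        q_perm = bh_fdr(p[perm])
        assert np.allclose(q[perm], q_perm)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_nan_passthrough(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1]) and not np.isnan(q[0])
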