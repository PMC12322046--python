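"""Adjacency and contacting cell networks (ACN / CCN).

The ACN is the graph of physically contacting segmented cells: two cells are
in contact when some pixel of one lies within Chebyshev distance 1 of a
pixel of the other (8-connectivity across a shared boundary). The CCN tests
each ordered cell-type pair (A, B) for enrichment of contact: the observed
count O_AB of A cells touching at least one B cell is compared with its
distribution under random reassignment of all cell-type labels over the
fixed graph (positions and contacts never move), giving

    z_AB = (O_AB − μ(N_AB)) / σ(N_AB)

with two-sided normal p-values and BH FDR across pairs. Condition-level
estimates combine ROIs by an N_A-weighted average of z and a weighted
Stouffer combination of one-sided p-values. The final network keeps pairs
that co-locate (g(20) > 1), are contact-enriched (z > 0) and significant.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import norm

from .data import CellPattern, LabelMask
from .stats import bh_fdr, weighted_stouffer

__all__ = [
    "ConsistencyError",
    "build_acn",
    "edge_keep",
    "ccn_edges",
    "ccn_condition",
    "assemble_network",
]


class ConsistencyError(ValueError):
    """Mask labels and cell table disagree."""


_SHIFTS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_SHIFTS_4 = [(-1, 0), (0, -1), (0, 1), (1, 0)]


def build_acn(
    mask: LabelMask, pattern: CellPattern, contact_rule: str = "chebyshev1"
) -> nx.Graph:
    """Adjacency cell network from a label mask.

    Every mask label becomes a node (typed from the pattern); undirected
    edges join cells whose pixels are within Chebyshev distance 1
    (``contact_rule='chebyshev1'``, diagonal contact counts) or share a pixel
    edge (``'edge_only'``, 4-connectivity).
    """
    if contact_rule not in ("chebyshev1", "edge_only"):
        raise ValueError("contact_rule must be 'chebyshev1' or 'edge_only'")
    labels = mask.labels
    known = set(pattern.cells["cell_id"].astype(int))
    missing = sorted(set(labels.tolist()) - known)
    if missing:
        raise ConsistencyError(f"mask labels missing from cell table: {missing}")

    type_of = dict(zip(pattern.cells["cell_id"].astype(int), pattern.cells["cell_type"]))
    G = nx.Graph()
    for lab in labels:
        G.add_node(int(lab), cell_type=type_of[int(lab)])

    pix = mask.pixels
    shifts = _SHIFTS_8 if contact_rule == "chebyshev1" else _SHIFTS_4
    for dr, dc in shifts:
        a = pix[max(dr, 0) or None : pix.shape[0] + min(dr, 0) or None,
                max(dc, 0) or None : pix.shape[1] + min(dc, 0) or None]
        b = pix[max(-dr, 0) or None : pix.shape[0] + min(-dr, 0) or None,
                max(-dc, 0) or None : pix.shape[1] + min(-dc, 0) or None]
        touching = (a > 0) & (b > 0) & (a != b)
        pairs = np.unique(
            np.stack([np.minimum(a[touching], b[touching]), np.maximum(a[touching], b[touching])]),
            axis=1,
        )
        G.add_edges_from(zip(pairs[0].astype(int).tolist(), pairs[1].astype(int).tolist()))
    return G


def _o_counts(adj: sparse.spmatrix, onehot: np.ndarray) -> np.ndarray:
    """O[A, B] = number of A cells with at least one B neighbour."""
    has_b_neighbor = (adj @ onehot) > 0  # (n_cells, n_types)
    return onehot.T @ has_b_neighbor  # (n_types, n_types)


def ccn_edges(
    graph: nx.Graph,
    pattern: CellPattern,
    n_perm: int = 1000,
    seed: int = 0,
    types: list[str] | None = None,
) -> pd.DataFrame:
    """Permutation z-scores for every ordered type pair on a fixed contact graph.

    All cell-type labels are shuffled over the graph's nodes (isolated cells
    included) n_perm times without moving positions; z is the standardised
    observed count of A anchors touching ≥1 B, p = 2·Φ̄(|z|), q = BH across
    defined pairs. O_AB is anchored on A and deliberately not symmetric; both
    orientations are reported.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if graph.number_of_nodes() == 0:
        raise ValueError("contact graph is empty")
    nodes = sorted(graph.nodes)
    node_types = np.array([graph.nodes[n]["cell_type"] for n in nodes], dtype=object)
    if types is None:
        types = sorted(set(node_types.tolist()))
    tindex = {t: i for i, t in enumerate(types)}
    tcode = np.array([tindex[t] for t in node_types])
    n_cells, n_types = len(nodes), len(types)

    adj = nx.to_scipy_sparse_array(graph, nodelist=nodes, format="csr", dtype=np.int32)
    eye = np.eye(n_types, dtype=np.int32)
    onehot = eye[tcode]
    O = _o_counts(adj, onehot).astype(float)

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, n_types, n_types))
    for p in range(n_perm):
        perm_onehot = eye[rng.permutation(tcode)]
        null[p] = _o_counts(adj, perm_onehot)
    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=0)

    n_of = {t: int((node_types == t).sum()) for t in types}
    rows = []
    for a in types:
        for b in types:
            i, j = tindex[a], tindex[b]
            o = O[i, j]
            degenerate = sd[i, j] == 0
            z = np.nan if degenerate else (o - mu[i, j]) / sd[i, j]
            p_val = 1.0 if degenerate else 2.0 * norm.sf(abs(z))
            rows.append(
                {
                    "roi_id": pattern.roi_id,
                    "condition": pattern.condition,
                    "type_a": a,
                    "type_b": b,
                    "n_a": n_of[a],
                    "o_ab": int(o),
                    "proportion_a": o / n_of[a] if n_of[a] else np.nan,
                    "null_mean": mu[i, j],
                    "null_sd": sd[i, j],
                    "z": z,
                    "p": p_val,
                    "degenerate": degenerate,
                }
            )
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(np.where(df["degenerate"], np.nan, df["p"]))
    df.loc[df["degenerate"], "q"] = 1.0
    return df


def ccn_condition(roi_edges: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-ROI CCN edges to condition level.

    Per ordered pair: weighted mean z with weights w_i = N_A of ROI i, and a
    weighted Stouffer combination of one-sided (enrichment-direction)
    p-values, p_i = Φ̄(z_i); BH across pairs. Degenerate ROIs carry no weight;
    a pair with no defined ROI is flagged undefined.
    """
    out = []
    for (cond, a, b), grp in roi_edges.groupby(["condition", "type_a", "type_b"], sort=True):
        ok = ~grp["degenerate"] & grp["z"].notna()
        w = grp.loc[ok, "n_a"].to_numpy(dtype=float)
        z = grp.loc[ok, "z"].to_numpy(dtype=float)
        total_contacts = int(grp["o_ab"].sum())
        if not ok.any() or w.sum() == 0:
            out.append(
                {
                    "condition": cond, "type_a": a, "type_b": b,
                    "z": np.nan, "p": np.nan, "total_contacts": total_contacts,
                    "n_rois": int(ok.sum()), "defined": False,
                }
            )
            continue
        z_combined = float((z * w).sum() / w.sum())
        p_one = norm.sf(z)  # one-sided, enrichment direction
        _, p_combined = weighted_stouffer(p_one, w)
        out.append(
            {
                "condition": cond, "type_a": a, "type_b": b,
                "z": z_combined, "p": p_combined, "total_contacts": total_contacts,
                "n_rois": int(ok.sum()), "defined": True,
            }
        )
    df = pd.DataFrame(out)
    df["q"] = bh_fdr(np.where(df["defined"], df["p"], np.nan))
    return df


def edge_keep(g20: float, z: float, p: float, alpha: float = 0.05) -> bool:
    """Triple network filter: co-location, positive enrichment, significance."""
    return bool(g20 > 1.0 and z > 0.0 and p < alpha)


def assemble_network(
    condition_edges: pd.DataFrame,
    g20: dict,
    alpha: float = 0.05,
    densities: dict | None = None,
) -> tuple[nx.Graph, pd.DataFrame, list]:
    """Filter condition edges into the contacting-cell network.

    ``g20`` maps (type_a, type_b) → pooled g(r=20). An edge is kept when
    g20 > 1, z > 0 and q < alpha (FDR-based at condition level); pairs with
    no g20 available are dropped with a warning. Node attribute ``density``
    (cells/mm², from ``densities``) sizes nodes; edge weight is the contact
    count. Communities (greedy modularity) are reported as a visualization
    aid, not asserted science.
    """
    df = condition_edges.copy()
    keep, g_vals = [], []
    for _, row in df.iterrows():
        key = (row["type_a"], row["type_b"])
        if key not in g20:
            warnings.warn(f"no g(20) available for pair {key}; edge dropped", stacklevel=2)
            g_vals.append(np.nan)
            keep.append(False)
            continue
        g_vals.append(g20[key])
        keep.append(
            bool(row.get("defined", True))
            and edge_keep(g20[key], row["z"], row["q"], alpha)
        )
    df["g20"] = g_vals
    df["keep"] = keep

    G = nx.Graph()
    for _, row in df[df["keep"]].iterrows():
        a, b = row["type_a"], row["type_b"]
        w = row["total_contacts"]
        if G.has_edge(a, b):
            G[a][b]["weight"] = max(G[a][b]["weight"], w)
        else:
            G.add_edge(a, b, weight=w, z=row["z"], q=row["q"], g20=row["g20"])
    if densities:
        nx.set_node_attributes(G, {n: densities.get(n, np.nan) for n in G.nodes}, "density")
    communities = (
        [set(c) for c in nx.community.greedy_modularity_communities(G, weight="weight")]
        if G.number_of_edges()
        else []
    )
    return G, df, communities
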