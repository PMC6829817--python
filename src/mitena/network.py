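"""Bipartite miRNA-target network construction and topological analysis.

The filtered enrichment output becomes a bipartite graph — miRNA-role nodes
on one side, gene-role nodes on the other, edges only across roles — and
each node gets the classical centrality panel: degree, betweenness,
closeness, average shortest path length, eccentricity and the (triangle-based)
clustering coefficient.  Because bipartite graphs are triangle-free, the
triangle-based clustering is identically 0 on every node; it is kept for
fidelity with the usual topology panel, and a square-clustering alternative
(4-cycle based, the bipartite analogue) is available behind a flag.

The degree distribution P(k) over the whole network is fitted with a power
law by ordinary least squares of log10 P(k) on log10 k — exactly what a
straight line on a log-log degree plot implies.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from mitena.interaction_db import InteractionDB


def build_network(db: InteractionDB, enriched_rows: pd.DataFrame, input_list=None) -> nx.Graph:
    """Assemble the regulatory network from filtered enrichment rows.

    Nodes are the surviving items plus their overlap partners; edges are the
    overlap interactions only.  Each node carries ``role`` (``mirna`` or
    ``gene``); with a validated DB, edges carry their evidence category.
    An empty ``enriched_rows`` yields an empty graph (not an error).
    """
    G = nx.Graph()
    if enriched_rows is None or len(enriched_rows) == 0:
        return G
    # item role depends on which direction produced the rows: items are
    # miRNAs when the partners are genes, and vice versa
    mirna_ids = set(db.records["mirna_id"])
    evidence = None
    if db.source == "validated":
        evidence = {
            (r.mirna_id, r.gene_symbol): r.evidence
            for r in db.records.itertuples()
        }
    for row in enriched_rows.itertuples():
        item_is_mirna = row.item in mirna_ids
        item_role = "mirna" if item_is_mirna else "gene"
        partner_role = "gene" if item_is_mirna else "mirna"
        G.add_node(row.item, role=item_role)
        for partner in row.overlap:
            G.add_node(partner, role=partner_role)
            pair = (row.item, partner) if item_is_mirna else (partner, row.item)
            attrs = {}
            if evidence is not None:
                attrs["evidence"] = evidence.get(pair)
            G.add_edge(*pair, **attrs)
    return G


@dataclass
class NodeTopologyRecord:
    node: str
    role: str
    degree: int
    betweenness: float
    closeness: float
    avg_shortest_path: float
    eccentricity: int
    clustering: float


def node_topology(net: nx.Graph, normalized_betweenness: bool = False,
                  square_clustering: bool = False) -> pd.DataFrame:
    """Per-node topology table.

    Distances are unweighted shortest paths *within each node's connected
    component* (enrichment networks are routinely disconnected).  Closeness
    uses the classical within-component definition, (n_c - 1) / Σ d(v, u)
    over the component; betweenness is unnormalized by default (flag for the
    2/((n-1)(n-2)) convention).  ``square_clustering`` swaps the triangle
    coefficient — identically 0 on a bipartite graph — for the 4-cycle one.
    """
    rows = []
    if net.number_of_nodes() == 0:
        return pd.DataFrame(columns=[f.name for f in NodeTopologyRecord.__dataclass_fields__.values()])
    betw = nx.betweenness_centrality(net, normalized=normalized_betweenness)
    clust = nx.square_clustering(net) if square_clustering else nx.clustering(net)
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        n_c = len(comp)
        ecc = nx.eccentricity(sub)
        for v in sorted(comp, key=str):
            dists = nx.single_source_shortest_path_length(sub, v)
            total = sum(dists.values())
            others = n_c - 1
            rows.append(NodeTopologyRecord(
                node=v,
                role=net.nodes[v].get("role", ""),
                degree=net.degree[v],
                betweenness=betw[v],
                closeness=(others / total) if total > 0 else 0.0,
                avg_shortest_path=(total / others) if others > 0 else 0.0,
                eccentricity=ecc[v],
                clustering=clust[v],
            ))
    df = pd.DataFrame(rows).sort_values("node", kind="mergesort").reset_index(drop=True)
    return df


def degree_distribution(net: nx.Graph) -> dict[int, float]:
    """Probability distribution of degrees over the whole network.

    Support is the observed degrees only; probabilities sum to 1.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("degree distribution of an empty network is undefined")
    degrees = [d for _, d in net.degree()]
    values, counts = np.unique(degrees, return_counts=True)
    n = len(degrees)
    return {int(k): float(c) / n for k, c in zip(values, counts)}


@dataclass
class PowerLawFit:
    """OLS fit of log10 P(k) = intercept - exponent * log10 k."""

    exponent: float
    intercept: float
    r_squared: float
    n_points: int


def fit_power_law(dist: dict[int, float]) -> PowerLawFit:
    """Fit P(k) ∝ k^-γ by least squares on the log-log degree distribution.

    Only nonzero-probability degrees enter the fit (log of zero is
    undefined); degree 0 is likewise excluded.  At least two distinct
    positive degrees are required — a regular network has a degenerate
    (single-point) distribution and raises ``ValueError``.
    """
    pts = [(k, p) for k, p in dist.items() if k > 0 and p > 0]
    if len(pts) < 2:
        raise ValueError("power-law fit needs >= 2 distinct degrees with nonzero probability")
    logk = np.log10([k for k, _ in pts])
    logp = np.log10([p for _, p in pts])
    slope, intercept = np.polyfit(logk, logp, 1)
    pred = slope * logk + intercept
    ss_res = float(np.sum((logp - pred) ** 2))
    ss_tot = float(np.sum((logp - logp.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(exponent=float(-slope), intercept=float(intercept),
                       r_squared=float(r2), n_points=len(pts))


def write_topology(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_edge_list(net: nx.Graph, path) -> None:
    """Edge list as TSV (mirna, gene, evidence), miRNA endpoint first."""
    rows = []
    for u, v, data in net.edges(data=True):
        if net.nodes[u].get("role") == "mirna":
            m, g = u, v
        else:
            m, g = v, u
        rows.append((m, g, data.get("evidence") or ""))
    pd.DataFrame(rows, columns=["mirna", "gene", "evidence"]).sort_values(
        ["mirna", "gene"], kind="mergesort"
    ).to_csv(path, sep="\t", index=False)


def write_degree_distribution(dist: dict[int, float], path) -> None:
    pd.DataFrame(sorted(dist.items()), columns=["degree", "probability"]).to_csv(
        path, sep="\t", index=False
    )


def plot_degree_distribution(dist: dict[int, float], path, fit: PowerLawFit | None = None) -> None:
    """Log-log degree distribution scatter with the straight-line fit."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ks = np.array(sorted(k for k in dist if k > 0))
    ps = np.array([dist[k] for k in ks])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ks, ps, s=25, zorder=3)
    if fit is not None:
        kk = np.linspace(np.log10(ks.min()), np.log10(ks.max()), 50)
        ax.plot(10 ** kk, 10 ** (fit.intercept - fit.exponent * kk), "-",
                label=f"P(k) ∝ k^-{fit.exponent:.2f} (R²={fit.r_squared:.2f})")
        ax.legend()
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("degree k")
    ax.set_ylabel("P(k)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
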