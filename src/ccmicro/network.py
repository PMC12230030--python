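"""Signed genus co-occurrence networks and their topological properties.

Edges are Pearson correlations across samples that survive both an absolute
threshold (|r| >= 0.7 by default) and a Benjamini-Hochberg significance cut
(q < 0.05), computed on relative abundances of taxa passing a mean-abundance
floor (0.1%). Modularity comes from Louvain communities on |r| weights.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceTable

__all__ = [
    "CorrelationNetwork",
    "NetworkTopology",
    "filter_taxa",
    "correlation_matrix",
    "adjust_bh",
    "build_network",
    "cooccurrence_network",
    "topology",
]


@dataclass
class CorrelationNetwork:
    """Thresholded signed co-occurrence graph with per-edge statistics."""

    graph: nx.Graph
    edges: pd.DataFrame  # taxon_a, taxon_b, r, p, q, sign
    group: str = ""
    r_min: float = 0.7
    alpha: float = 0.05

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class NetworkTopology:
    n_nodes: int
    n_edges: int
    avg_degree: float
    density: float
    modularity: float
    avg_clustering: float
    avg_path_length: float
    n_components: int
    pct_positive_edges: float
    pct_negative_edges: float
    avg_weighted_degree: float

    def to_series(self, name: str = "") -> pd.Series:
        return pd.Series(self.__dict__, name=name)


def filter_taxa(table: AbundanceTable, floor: float = 0.001,
                mode: str = "mean") -> AbundanceTable:
    """Keep taxa whose relative abundance exceeds ``floor``.

    ``mode="mean"`` (default) compares the mean relative abundance across
    samples against the floor; ``mode="sum"`` compares the raw sum of
    per-sample relative abundances instead.
    """
    if not (0 <= floor < 1):
        raise ValueError("floor must be in [0, 1)")
    rel = table.relative()
    if mode == "mean":
        stat = rel.values.mean(axis=1)
    elif mode == "sum":
        stat = rel.values.sum(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keep = [t for t, s in zip(table.taxon_ids, stat) if s > floor]
    if not keep:
        raise ValueError("no taxa pass the abundance floor")
    return table.subset_taxa(keep)


def correlation_matrix(table: AbundanceTable) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r over samples with t-distribution p-values.

    Zero-variance taxa get NaN rows/columns (undefined r; they can form no
    edges). Requires >= 4 samples so the t test has positive df.
    """
    n = table.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples for correlation p-values")
    x = table.values.astype(float)
    sd = x.std(axis=1)
    ok = sd > 0
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((xc ** 2).sum(axis=1))
    norm[~ok] = 1.0
    xn = xc / norm[:, None]
    r = xn @ xn.T
    np.clip(r, -1.0, 1.0, out=r)
    r[~ok, :] = np.nan
    r[:, ~ok] = np.nan
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    p[np.isnan(r)] = np.nan
    np.fill_diagonal(p, 0.0)
    return r, p


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def build_network(taxon_ids: list[str], r: np.ndarray, q: np.ndarray,
                  r_min: float = 0.7, alpha: float = 0.05,
                  keep_isolated: bool = True, group: str = "") -> CorrelationNetwork:
    """Assemble the thresholded graph: |r| >= r_min and q < alpha (strict).

    ``q`` is the matrix of BH-adjusted p-values aligned with ``r``. Taxa with
    undefined correlations (NaN) never form edges; isolated nodes are kept
    unless ``keep_isolated`` is false.
    """
    if not (0 <= r_min <= 1):
        raise ValueError("r_min must be in [0, 1]")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    g = nx.Graph()
    rows = []
    n = len(taxon_ids)
    if keep_isolated:
        # taxa with a defined correlation to at least one partner stay as nodes
        if n == 1:
            g.add_node(taxon_ids[0])
        else:
            g.add_nodes_from(
                taxon_ids[i] for i in range(n)
                if any(np.isfinite(r[i, j]) for j in range(n) if j != i))
    for i, j in itertools.combinations(range(n), 2):
        rij, qij = r[i, j], q[i, j]
        if np.isnan(rij) or np.isnan(qij):
            continue
        if abs(rij) >= r_min and qij < alpha:
            sign = "+" if rij > 0 else "-"
            g.add_edge(taxon_ids[i], taxon_ids[j],
                       r=float(rij), q=float(qij), abs_r=float(abs(rij)),
                       sign=sign)
            rows.append({"taxon_a": taxon_ids[i], "taxon_b": taxon_ids[j],
                         "r": float(rij), "q": float(qij), "sign": sign})
    edges = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "r", "q", "sign"])
    return CorrelationNetwork(graph=g, edges=edges, group=group,
                              r_min=r_min, alpha=alpha)


def cooccurrence_network(table: AbundanceTable, r_min: float = 0.7,
                         alpha: float = 0.05, floor: float = 0.001,
                         use_relative: bool = True, group: str = "",
                         keep_isolated: bool = True) -> CorrelationNetwork:
    """Full chain: abundance floor -> Pearson -> BH -> thresholded graph."""
    filtered = filter_taxa(table, floor=floor)
    data = filtered.relative() if use_relative else filtered
    r, p = correlation_matrix(data)
    iu = np.triu_indices(len(filtered.taxon_ids), k=1)
    praw = p[iu]
    finite = np.isfinite(praw)
    q = np.full_like(r, np.nan)
    qvec = np.full(praw.shape, np.nan)
    if finite.any():
        qvec[finite] = adjust_bh(praw[finite])
    q[iu] = qvec
    q.T[iu] = qvec
    return build_network(filtered.taxon_ids, r, q, r_min=r_min, alpha=alpha,
                         keep_isolated=keep_isolated, group=group)


def topology(net: CorrelationNetwork, seed: int = 0,
             resolution: float = 1.0) -> NetworkTopology:
    """Topological summary of a thresholded network.

    Modularity is computed from Louvain communities on |r| edge weights with
    a fixed seed (heuristic; agreement with other tools is approximate by
    nature). Average path length is over connected node pairs only, with the
    number of components reported alongside.
    """
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        nan = float("nan")
        return NetworkTopology(0, 0, nan, nan, nan, nan, nan, 0, nan, nan, nan)
    avg_degree = 2.0 * e / n
    density = nx.density(g)
    if e > 0:
        communities = nx.community.louvain_communities(
            g, weight="abs_r", seed=seed, resolution=resolution)
        q_mod = nx.community.modularity(g, communities, weight="abs_r",
                                        resolution=resolution)
        n_pos = sum(1 for _, _, d in g.edges(data=True) if d["sign"] == "+")
        pct_pos = 100.0 * n_pos / e
        pct_neg = 100.0 - pct_pos
        awd = sum(d["abs_r"] for _, _, d in g.edges(data=True)) * 2.0 / n
        clustering = nx.average_clustering(g)
    else:
        q_mod = float("nan")
        pct_pos = pct_neg = float("nan")
        awd = 0.0
        clustering = 0.0
    total_len = 0
    total_pairs = 0
    components = list(nx.connected_components(g))
    for comp in components:
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total_len += sum(lengths.values())
        total_pairs += len(comp) * (len(comp) - 1)
    apl = total_len / total_pairs if total_pairs else float("nan")
    return NetworkTopology(
        n_nodes=n, n_edges=e, avg_degree=avg_degree, density=density,
        modularity=float(q_mod), avg_clustering=float(clustering),
        avg_path_length=float(apl), n_components=len(components),
        pct_positive_edges=float(pct_pos), pct_negative_edges=float(pct_neg),
        avg_weighted_degree=float(awd),
    )
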