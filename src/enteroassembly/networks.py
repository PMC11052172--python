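"""Co-occurrence networks from Spearman correlations, and their topology.

Edges connect taxa whose abundance profiles across samples are strongly and
significantly rank-correlated: |rho| > 0.6 (strict) and BH-corrected q < 0.05
by default, with the sign of rho kept (positive and negative associations).
Topology is summarized by the six network-level features commonly reported
for microbial networks: diameter, modularity, clustering coefficient, graph
density, average degree, and average path length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diversity import benjamini_hochberg
from .io import AsvTable


@dataclass
class CooccurrenceNetwork:
    graph: nx.Graph
    edges: pd.DataFrame  # node_a, node_b, rho, p_value, q_value, sign
    rho_threshold: float
    fdr_alpha: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class NetworkStats:
    diameter: float
    modularity: float
    clustering_coefficient: float
    graph_density: float
    average_degree: float
    average_path_length: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def filter_for_network(table_rel: AsvTable, min_mean_rel: float = 1e-4) -> AsvTable:
    """Drop taxa whose mean relative abundance across samples is < ``min_mean_rel``.

    Strict "<": a taxon sitting exactly on the threshold is retained.
    """
    means = table_rel.counts.mean(axis=0)
    keep = means >= min_mean_rel
    return AsvTable(table_rel.counts.loc[:, keep])


def spearman_edges(table_rel: AsvTable, rho_threshold: float = 0.6,
                   fdr_alpha: float = 0.05, positive_only: bool = False,
                   ) -> CooccurrenceNetwork:
    """Build a co-occurrence network from all pairwise Spearman correlations.

    All taxon pairs are tested; BH correction runs across the full family of
    tested pairs.  An edge requires |rho| strictly above ``rho_threshold``
    AND q below ``fdr_alpha``.  Pairs involving a constant taxon vector are
    skipped with a warning (rho undefined).
    """
    x = table_rel.values().astype(float)
    n_samples, n_taxa = x.shape
    if n_samples < 4:
        raise ValueError("need at least 4 samples for correlation testing")
    taxa = table_rel.taxon_ids
    constant = np.ptp(x, axis=0) == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant taxa skipped in correlation tests",
                      stacklevel=2)
    usable = np.flatnonzero(~constant)
    if len(usable) < 2:
        g = nx.Graph()
        g.add_nodes_from(taxa)
        return CooccurrenceNetwork(g, _empty_edges(), rho_threshold, fdr_alpha)
    rho, p = stats.spearmanr(x[:, usable])
    rho = np.atleast_2d(rho)
    p = np.atleast_2d(p)
    iu, ju = np.triu_indices(len(usable), k=1)
    recs = pd.DataFrame({
        "node_a": [taxa[usable[i]] for i in iu],
        "node_b": [taxa[usable[j]] for j in ju],
        "rho": rho[iu, ju],
        "p_value": p[iu, ju],
    })
    recs["q_value"] = benjamini_hochberg(recs["p_value"])
    recs["sign"] = np.where(recs["rho"] >= 0, "positive", "negative")
    strength = recs["rho"] if positive_only else recs["rho"].abs()
    keep = (strength > rho_threshold) & (recs["q_value"] < fdr_alpha)
    edges = recs.loc[keep].reset_index(drop=True)
    g = nx.Graph()
    g.add_nodes_from(taxa)
    for row in edges.itertuples(index=False):
        g.add_edge(row.node_a, row.node_b, rho=row.rho, q=row.q_value, sign=row.sign)
    return CooccurrenceNetwork(g, edges, rho_threshold, fdr_alpha)


def _empty_edges() -> pd.DataFrame:
    return pd.DataFrame(columns=["node_a", "node_b", "rho", "p_value", "q_value", "sign"])


def network_metrics(network: CooccurrenceNetwork | nx.Graph) -> NetworkStats:
    """Six network-level topological features.

    Conventions: density = 2E/(N(N-1)); average degree = 2E/N; clustering is
    the mean local clustering coefficient with degree<2 nodes contributing 0;
    diameter and average path length are computed on the largest connected
    component; modularity is the best greedy (Clauset-Newman-Moore) partition
    score on the unweighted graph.  An empty or edgeless graph reports all
    zeros with a warning.
    """
    g = network.graph if isinstance(network, CooccurrenceNetwork) else network
    n = g.number_of_nodes()
    e = g.number_of_edges()
    if n == 0 or e == 0:
        warnings.warn("empty network: all topology metrics reported as 0", stacklevel=2)
        return NetworkStats(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    avg_degree = 2.0 * e / n
    clustering = nx.average_clustering(g)  # counts degree<2 nodes as 0
    comms = nx.algorithms.community.greedy_modularity_communities(g)
    modularity = nx.algorithms.community.modularity(g, comms)
    giant = g.subgraph(max(nx.connected_components(g), key=len))
    if giant.number_of_nodes() > 1:
        diameter = float(nx.diameter(giant))
        apl = float(nx.average_shortest_path_length(giant))
    else:
        diameter, apl = 0.0, 0.0
    return NetworkStats(diameter, float(modularity), float(clustering),
                        float(density), float(avg_degree), apl)
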