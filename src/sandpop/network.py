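"""Shared-allele (1 - IBS) distances and mutual k-nearest-neighbour networks.

The Netview-style construction: an individual-by-individual identity-by-
state distance matrix feeds a mutual kNN graph — an edge joins i and j only
when each is among the other's k nearest neighbours.  Cluster structure in
the graph visualises fine-scale population stratification.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

__all__ = ["one_minus_ibs", "mutual_knn_graph", "IBSNetwork"]


def one_minus_ibs(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise 1 - IBS distance matrix from dosage calls.

    Per locus the pair shares ``2 - |d1 - d2|`` of 2 alleles by state; the
    distance is one minus the shared fraction over mutually typed loci.
    Pairs with no mutually typed locus get NaN.
    """
    calls = matrix.calls
    T = (calls != MISSING).astype(float)
    # |d_i - d_j| summed over loci via genotype-class indicator products
    G = [((calls == d) & (calls != MISSING)).astype(float) for d in (0, 1, 2)]
    diff1 = G[0] @ G[1].T + G[1] @ G[0].T + G[1] @ G[2].T + G[2] @ G[1].T
    diff2 = G[0] @ G[2].T + G[2] @ G[0].T
    absdiff = diff1 + 2.0 * diff2
    shared_loci = T @ T.T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = absdiff / (2.0 * shared_loci)
    dist[shared_loci == 0] = np.nan
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=matrix.individual_ids, columns=matrix.individual_ids)


@dataclass
class IBSNetwork:
    graph: nx.Graph
    distances: pd.DataFrame
    k: int

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "distance": d.get("weight", np.nan)}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "distance"])

    def neighbourhood_connectivity(self) -> pd.Series:
        """Mean degree of each node's neighbours (used for node sizing)."""
        deg = dict(self.graph.degree())
        out = {}
        for node in self.graph.nodes:
            nbrs = list(self.graph.neighbors(node))
            out[node] = float(np.mean([deg[n] for n in nbrs])) if nbrs else 0.0
        return pd.Series(out, name="neighbourhood_connectivity")

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def mutual_knn_graph(
    distances: pd.DataFrame,
    k: int,
    mutual: bool = True,
) -> IBSNetwork:
    """Mutual (default) or union kNN graph from a distance matrix.

    Distance ties are broken by node order in the matrix so the graph is
    deterministic.  Pairs with missing distances are ineligible for edges.
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must lie in [1, {n - 1}]")
    labels = list(distances.index)
    neigh: list[set[int]] = []
    order_idx = np.arange(n)
    for i in range(n):
        d = D[i].copy()
        d[i] = np.inf
        d[np.isnan(d)] = np.inf
        order = np.lexsort((order_idx, d))
        valid = [j for j in order if np.isfinite(d[j])]
        neigh.append(set(valid[:k]))
    g = nx.Graph()
    g.add_nodes_from(labels)
    for i in range(n):
        for j in range(i + 1, n):
            forward, backward = j in neigh[i], i in neigh[j]
            if (forward and backward) if mutual else (forward or backward):
                g.add_edge(labels[i], labels[j], weight=float(D[i, j]))
    net = IBSNetwork(graph=g, distances=distances, k=k)
    for node, val in net.neighbourhood_connectivity().items():
        g.nodes[node]["neighbourhood_connectivity"] = val
    return net
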