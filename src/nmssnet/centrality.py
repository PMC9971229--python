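"""Node centrality (strength) and the force-directed network layout."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import PcorNetwork

__all__ = ["CentralityTable", "LayoutCoordinates", "strength", "fruchterman_reingold"]


@dataclass
class CentralityTable:
    """Per-node raw strength, z-standardized strength and descending rank."""

    node_ids: tuple[str, ...]
    raw: np.ndarray
    normalized: np.ndarray
    rank: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"strength": self.raw, "z": self.normalized, "rank": self.rank},
            index=list(self.node_ids),
        )


@dataclass
class LayoutCoordinates:
    node_ids: tuple[str, ...]
    xy: np.ndarray
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.xy, index=list(self.node_ids), columns=["x", "y"])


def strength(network: PcorNetwork) -> CentralityTable:
    """Strength s_i = sum_j |w_ij|; normalized = z-score across nodes."""
    w = np.abs(network.weights)
    s = w.sum(axis=1)
    if network.n_nodes < 2 or s.std() == 0:
        z = np.full_like(s, np.nan)
        if network.n_nodes < 2:
            import warnings

            warnings.warn("single-node network: normalization undefined", stacklevel=2)
    else:
        z = (s - s.mean()) / s.std(ddof=0)
    order = np.argsort(-s, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(s) + 1)
    return CentralityTable(node_ids=network.node_ids, raw=s, normalized=z, rank=rank)


def to_graph(network: PcorNetwork) -> nx.Graph:
    """networkx graph with signed ``weight`` and absolute ``abs_weight``."""
    g = nx.Graph()
    g.add_nodes_from(network.node_ids)
    for _, row in network.edge_list().iterrows():
        g.add_edge(
            row.node_i, row.node_j, weight=float(row.weight),
            abs_weight=abs(float(row.weight)),
        )
    return g


def fruchterman_reingold(
    network: PcorNetwork, seed: int = 0, iterations: int = 100
) -> LayoutCoordinates:
    """Weighted Fruchterman-Reingold layout (absolute weights attract);
    deterministic for a fixed seed and iteration count."""
    if network.n_nodes < 2:
        raise ValueError("layout needs at least 2 nodes")
    g = to_graph(network)
    # scale=None keeps raw force-directed distances (no unit-box rescale),
    # so stronger edges measurably pull their endpoints together
    pos = nx.spring_layout(
        g, weight="abs_weight", seed=seed, iterations=iterations, scale=None
    )
    xy = np.array([pos[n] for n in network.node_ids], dtype=float)
    if not np.all(np.isfinite(xy)):
        raise RuntimeError("layout produced non-finite coordinates")
    return LayoutCoordinates(node_ids=network.node_ids, xy=xy, seed=seed)
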