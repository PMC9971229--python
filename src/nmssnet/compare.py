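"""Permutation-based network comparison test (NCT).

Compares two networks re-estimated under identical settings: structure
invariance M (maximum absolute pairwise edge difference), global strength
invariance S (absolute difference of the summed absolute edge weights) and
per-edge invariance, with permutation p-values using the add-one
convention p = (1 + #{perm >= obs}) / (1 + n_perm).

Two permutation schemes are provided and the choice is a mandatory
argument: ``paired`` swaps each subject's two observations between groups
(longitudinal design, preserves subject-level dependence); ``independent``
reshuffles group labels over the pooled rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import EstimatorSettings, PcorNetwork, estimate_network

__all__ = ["NctResult", "nct_statistics", "network_comparison_test"]


@dataclass
class NctResult:
    node_ids: tuple[str, ...]
    m_observed: float
    s_observed: float
    p_m: float
    p_s: float
    edge_table: pd.DataFrame  # node_i, node_j, diff, p_raw, p_holm
    n_permutations: int
    scheme: str
    seed: int

    @property
    def n_edges_significant_raw(self) -> int:
        return int((self.edge_table.p_raw <= 0.05).sum())

    @property
    def n_edges_significant_holm(self) -> int:
        return int((self.edge_table.p_holm <= 0.05).sum())


def _check_nodes(a: PcorNetwork, b: PcorNetwork) -> None:
    if a.node_ids != b.node_ids:
        raise ValueError("networks have different node sets/order")


def nct_statistics(
    net_a: PcorNetwork, net_b: PcorNetwork
) -> tuple[float, float, np.ndarray]:
    """(M, S, per-edge differences d_ij = w_ij^A - w_ij^B over i < j)."""
    _check_nodes(net_a, net_b)
    iu = np.triu_indices(net_a.n_nodes, 1)
    wa, wb = net_a.weights[iu], net_b.weights[iu]
    d = wa - wb
    m = float(np.abs(d).max()) if d.size else 0.0
    s = float(abs(np.abs(wa).sum() - np.abs(wb).sum()))
    return m, s, d


def _stats_from_data(Xa, Xb, settings) -> tuple[float, float, np.ndarray]:
    na, _ = estimate_network(Xa, settings)
    nb, _ = estimate_network(Xb, settings)
    return nct_statistics(na, nb)


def _holm(p: np.ndarray) -> np.ndarray:
    k = len(p)
    order = np.argsort(p)
    adj = np.empty(k)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (k - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def network_comparison_test(
    data_a,
    data_b,
    settings: EstimatorSettings = EstimatorSettings(),
    n_perm: int = 1000,
    scheme: str = "",
    seed: int = 0,
    edges: str = "all",
) -> NctResult:
    """Permutation NCT between two datasets.

    ``scheme`` must be 'paired' (identical subject_ids in both matrices;
    permutation swaps each subject's two visits) or 'independent' (disjoint
    row sets; permutation reshuffles group labels).  ``edges`` selects the
    per-edge test set: 'all' tests every node pair, 'union' only the pairs
    non-zero in either observed network.
    """
    from .network import _coerce_data
    from .scale import ItemMatrix

    if n_perm < 20:
        raise ValueError("n_perm < 20 gives too coarse a p-value resolution")
    if scheme not in ("paired", "independent"):
        raise ValueError("scheme must be 'paired' or 'independent'")
    if edges not in ("all", "union"):
        raise ValueError("edges must be 'all' or 'union'")
    if scheme == "paired" and isinstance(data_a, ItemMatrix) and isinstance(data_b, ItemMatrix):
        if data_a.subject_ids != data_b.subject_ids:
            raise ValueError("paired scheme requires identical subject_ids")
    Xa, nodes = _coerce_data(data_a, None)
    Xb, nodes_b = _coerce_data(data_b, None)
    if nodes != nodes_b or Xa.shape[1] != Xb.shape[1]:
        raise ValueError("the two datasets must share the same variables")
    if scheme == "paired" and Xa.shape[0] != Xb.shape[0]:
        raise ValueError("paired scheme requires equal row counts")

    net_a, _ = estimate_network(Xa, settings)
    net_b, _ = estimate_network(Xb, settings)
    m_obs, s_obs, d_obs = nct_statistics(net_a, net_b)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7001]))
    ge_m = 0
    ge_s = 0
    ge_edge = np.zeros_like(d_obs, dtype=int)
    n_done = 0
    if scheme == "independent":
        pool = np.vstack([Xa, Xb])
        na = Xa.shape[0]
    for _ in range(n_perm):
        if scheme == "paired":
            flip = rng.random(Xa.shape[0]) < 0.5
            Pa = np.where(flip[:, None], Xb, Xa)
            Pb = np.where(flip[:, None], Xa, Xb)
        else:
            perm = rng.permutation(pool.shape[0])
            Pa, Pb = pool[perm[:na]], pool[perm[na:]]
        try:
            m_p, s_p, d_p = _stats_from_data(Pa, Pb, settings)
        except Exception:  # noqa: BLE001 - degenerate permutation sample
            continue
        n_done += 1
        ge_m += m_p >= m_obs
        ge_s += s_p >= s_obs
        ge_edge += np.abs(d_p) >= np.abs(d_obs)
    if n_done == 0:
        raise RuntimeError("every permutation replicate failed")
    p_m = (1.0 + ge_m) / (1.0 + n_done)
    p_s = (1.0 + ge_s) / (1.0 + n_done)
    p_edge = (1.0 + ge_edge) / (1.0 + n_done)

    iu = np.triu_indices(len(nodes), 1)
    table = pd.DataFrame(
        {
            "node_i": [nodes[i] for i in iu[0]],
            "node_j": [nodes[j] for j in iu[1]],
            "diff": d_obs,
            "p_raw": p_edge,
        }
    )
    if edges == "union":
        keep = (np.abs(net_a.weights[iu]) > 0) | (np.abs(net_b.weights[iu]) > 0)
        table = table[keep].reset_index(drop=True)
    table["p_holm"] = _holm(table.p_raw.to_numpy())
    return NctResult(
        node_ids=nodes,
        m_observed=m_obs,
        s_observed=s_obs,
        p_m=float(p_m),
        p_s=float(p_s),
        edge_table=table,
        n_permutations=n_done,
        scheme=scheme,
        seed=seed,
    )
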