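"""Spectral robustness, efficiency-based vulnerability, keystone redundancy
and the composite per-network stability report.

Natural connectivity is ln of the mean eigenvalue exponential of the
unweighted adjacency matrix, a spectral measure of how many closed walks
(alternative routes) the graph retains; it is evaluated with a log-sum-exp
so dense, large-eigenvalue graphs cannot overflow. Robustness is the mean
retained natural-connectivity fraction after removing a random 10% of the
nodes; vulnerability is the worst single-node relative drop in global
efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import shortest_path
from scipy.special import logsumexp

from .containers import CoNetwork, ValidationError


def _natural_connectivity_adj(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n == 0:
        raise ValidationError("natural connectivity needs at least 1 node")
    eigenvalues = np.linalg.eigvalsh(adj)
    return float(logsumexp(eigenvalues) - np.log(n))


def natural_connectivity(network: CoNetwork,
                         largest_component: bool = True) -> float:
    """ln((1/N) sum_j exp(lambda_j)) over adjacency eigenvalues.

    By default evaluated on the largest connected component, since the
    spectrum of a disconnected graph mixes component contributions.
    Edgeless graphs give exactly 0.
    """
    net = network.largest_component() if largest_component else network
    return _natural_connectivity_adj(net.adjacency())


def _efficiency_from_adj(adj: sparse.csr_matrix | np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = shortest_path(sparse.csr_matrix(adj), method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(network: CoNetwork) -> float:
    """Mean inverse shortest-path length; unreachable pairs contribute 0."""
    if network.n_nodes < 2:
        raise ValidationError("global efficiency needs at least 2 nodes")
    return _efficiency_from_adj(network.adjacency())


@dataclass
class RemovalTrace:
    """One random-removal replicate: which nodes fell and what remained."""

    removed: list
    before: float
    after: float

    @property
    def retained_fraction(self) -> float:
        return self.after / self.before


def robustness(network: CoNetwork, fraction: float = 0.10,
               replicates: int = 100,
               seed: int | np.random.Generator = 0,
               largest_component: bool = True) -> dict:
    """Retained natural connectivity after random removal of ceil(f*N) nodes.

    Per replicate, nodes are removed uniformly without replacement and the
    retained fraction is lambda_after / lambda_before. Requires a graph
    with positive natural connectivity (i.e. at least one edge).
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    net = network.largest_component() if largest_component else network
    nodes = list(net.graph.nodes)
    n = len(nodes)
    n_remove = int(np.ceil(fraction * n))
    if n_remove >= n:
        raise ValidationError("removal fraction leaves no nodes")
    before = _natural_connectivity_adj(net.adjacency(nodes))
    if before <= 0:
        raise ValidationError(
            "natural connectivity of the intact network is not positive "
            "(edgeless graph); robustness is undefined")
    adj = net.adjacency(nodes)
    rng = np.random.default_rng(seed)
    traces = []
    for _ in range(replicates):
        drop = rng.choice(n, size=n_remove, replace=False)
        keep = np.setdiff1d(np.arange(n), drop)
        after = _natural_connectivity_adj(adj[np.ix_(keep, keep)])
        traces.append(RemovalTrace(removed=[nodes[i] for i in drop],
                                   before=before, after=after))
    fractions = np.array([t.retained_fraction for t in traces])
    return {
        "natural_connectivity": before,
        "robustness_mean": float(fractions.mean()),
        "robustness_sd": float(fractions.std(ddof=1)) if replicates > 1 else 0.0,
        "n_removed": n_remove,
        "replicates": replicates,
        "traces": traces,
    }


def vulnerability(network: CoNetwork) -> tuple[float, pd.DataFrame]:
    """Worst-case relative efficiency loss under single-node deletion.

    V_i = (E - E_-i) / E where E_-i is the global efficiency of the graph
    without node i; the network's vulnerability is max_i V_i.
    """
    if network.n_nodes < 3:
        raise ValidationError("vulnerability needs at least 3 nodes")
    nodes = list(network.graph.nodes)
    adj = network.adjacency(nodes)
    e_full = _efficiency_from_adj(adj)
    if e_full == 0:
        raise ValidationError(
            "global efficiency is 0 (edgeless graph); vulnerability undefined")
    rows = []
    idx = np.arange(len(nodes))
    for i, node in enumerate(nodes):
        keep = idx[idx != i]
        e_i = _efficiency_from_adj(adj[np.ix_(keep, keep)])
        rows.append({"node": node, "efficiency_without": e_i,
                     "vulnerability": (e_full - e_i) / e_full})
    table = pd.DataFrame(rows).set_index("node")
    return float(table["vulnerability"].max()), table


def keystone_redundancy(network: CoNetwork, roles: pd.DataFrame,
                        largest_component: bool = True) -> dict:
    """Connectivity redundancy of the keystone (hub/connector) taxa.

    Keystones are all nodes classified module hub, connector or network
    hub. The impact of a keystone is the relative natural-connectivity
    loss when it alone is removed; redundancy = 1 - mean impact, so a
    community whose keystones are individually dispensable scores near 1.
    An empty keystone set is reported as redundancy 1 with a flag.
    """
    keystones = [n for n, role in roles["role"].items()
                 if role in ("module hub", "connector", "network hub")]
    net = network.largest_component() if largest_component else network
    nodes = list(net.graph.nodes)
    adj = net.adjacency(nodes)
    base = _natural_connectivity_adj(adj)
    present = [k for k in keystones if k in set(nodes)]
    if not present or base <= 0:
        return {"redundancy": 1.0, "n_keystones": len(present),
                "impacts": pd.Series(dtype=float), "empty_keystones": True}
    idx = {node: i for i, node in enumerate(nodes)}
    impacts = {}
    all_idx = np.arange(len(nodes))
    for k in present:
        keep = all_idx[all_idx != idx[k]]
        after = _natural_connectivity_adj(adj[np.ix_(keep, keep)])
        impacts[k] = 1.0 - after / base
    impacts = pd.Series(impacts, name="impact")
    return {"redundancy": float(1.0 - impacts.mean()),
            "n_keystones": len(present), "impacts": impacts,
            "empty_keystones": False}


def stability_report(network: CoNetwork, roles: pd.DataFrame | None = None,
                     modularity_q: float | None = None,
                     fraction: float = 0.10, replicates: int = 100,
                     seed: int | np.random.Generator = 0) -> dict:
    """Assemble all stability metrics for one network into a flat record."""
    if network.n_nodes == 0:
        raise ValidationError("stability report of an empty network")
    rob = robustness(network, fraction=fraction, replicates=replicates,
                     seed=seed)
    vuln, _ = vulnerability(network)
    record = {
        "group": network.group,
        "nodes": network.n_nodes,
        "edges": network.n_edges,
        "natural_connectivity": rob["natural_connectivity"],
        "robustness_mean": rob["robustness_mean"],
        "robustness_sd": rob["robustness_sd"],
        "vulnerability": vuln,
        "modularity": modularity_q if modularity_q is not None else np.nan,
        "removal_fraction": fraction,
        "replicates": replicates,
    }
    if roles is not None:
        red = keystone_redundancy(network, roles)
        record["keystone_redundancy"] = red["redundancy"]
        record["n_keystones"] = red["n_keystones"]
    return record
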