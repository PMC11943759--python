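"""Co-occurrence network construction and analysis.

A network is built per sample group from the group's dominant OTUs: pairwise
rank (or product-moment) correlations on relative abundances are
thresholded on |r| and (optionally BH-adjusted) p, giving an undirected
signed graph. Topology metrics, Newman (CNM) modularity and the
Guimera-Amaral Zi-Pi node-role classification are computed on the
unweighted graph; the correlation sign is kept as an edge attribute.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CoNetwork, OtuTable, TaxonomyMap, ValidationError


def filter_dominant(otu: OtuTable, min_mean_rel_abund: float = 1e-4,
                    min_prevalence: float = 1.0 / 3.0) -> OtuTable:
    """Keep OTUs abundant and prevalent enough to support correlation.

    An OTU is retained iff its mean relative abundance is >= the abundance
    threshold AND it is nonzero in at least ``min_prevalence`` of samples.
    Kept/dropped counts are recorded in the result's flags.
    """
    if not (0 <= min_mean_rel_abund <= 1 and 0 <= min_prevalence <= 1):
        raise ValidationError("thresholds must be in [0, 1]")
    rel = otu.relative_abundance()
    mean_rel = rel.mean(axis=0)
    prevalence = (otu.counts > 0).mean(axis=0)
    keep = (mean_rel >= min_mean_rel_abund) & (prevalence >= min_prevalence)
    kept = list(keep.index[keep])
    if not kept:
        raise ValidationError(
            f"no OTU passes min_mean_rel_abund={min_mean_rel_abund}, "
            f"min_prevalence={min_prevalence}; relax the thresholds")
    out = otu.select_otus(kept)
    out.flags["dominance_filter"] = {
        "kept": len(kept), "dropped": otu.n_otus - len(kept),
        "min_mean_rel_abund": min_mean_rel_abund,
        "min_prevalence": min_prevalence,
    }
    return out


def correlation_matrix(otu: OtuTable, method: str = "spearman"
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs correlation of OTU relative abundances with two-sided p.

    p-values come from the t approximation ``t = r sqrt((n-2)/(1-r^2))``.
    Constant OTU vectors give NaN against every partner.
    """
    if method not in ("spearman", "pearson"):
        raise ValidationError(f"unknown method {method!r}")
    n = otu.n_samples
    if n < 5:
        raise ValidationError(
            f"need at least 5 samples for a correlation network, got {n}")
    x = otu.relative_abundance().to_numpy(dtype=float)
    if method == "spearman":
        x = stats.rankdata(x, axis=0)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.asarray(r, dtype=float)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.clip(r, -1.0, 1.0, out=r)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    p[np.isnan(r)] = np.nan
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    ids = otu.otu_ids
    return (pd.DataFrame(r, index=ids, columns=ids),
            pd.DataFrame(p, index=ids, columns=ids))


def build_network(r: pd.DataFrame, p: pd.DataFrame, r_min: float = 0.7,
                  p_max: float = 0.05, adjust: str = "BH",
                  keep_isolated: bool = False,
                  otu: OtuTable | None = None,
                  tax: TaxonomyMap | None = None,
                  group: str | None = None) -> CoNetwork:
    """Threshold the correlation matrices into an undirected signed graph.

    An edge exists iff |r| >= r_min and the (optionally BH-adjusted, over
    the upper triangle) p <= p_max. Isolated nodes are dropped unless
    ``keep_isolated``. An empty result is returned with a warning, never an
    error, so parameter sweeps stay scriptable.
    """
    if list(r.index) != list(p.index) or list(r.columns) != list(p.columns):
        raise ValidationError("r and p matrices must share identifiers")
    if adjust not in ("none", "BH"):
        raise ValidationError(f"unknown adjustment {adjust!r}")
    ids = list(r.index)
    rv = r.to_numpy(dtype=float)
    pv = p.to_numpy(dtype=float).copy()
    iu = np.triu_indices(len(ids), k=1)
    if adjust == "BH":
        flat = pv[iu]
        ok = np.isfinite(flat)
        if ok.any():
            flat[ok] = multipletests(flat[ok], method="fdr_bh")[1]
        pv[iu] = flat
        pv.T[iu] = flat
    mask = (np.abs(rv) >= r_min) & (pv <= p_max)
    mask &= np.isfinite(rv) & np.isfinite(pv)
    graph = nx.Graph()
    if keep_isolated or otu is not None:
        graph.add_nodes_from(ids)
    for i, j in zip(*iu):
        if mask[i, j]:
            graph.add_edge(ids[i], ids[j], r=float(rv[i, j]),
                           p=float(pv[i, j]), sign=int(np.sign(rv[i, j])))
    if not keep_isolated:
        graph.remove_nodes_from([n for n in list(graph.nodes)
                                 if graph.degree(n) == 0])
    if graph.number_of_edges() == 0:
        warnings.warn(
            f"no edge passed |r| >= {r_min}, p <= {p_max} (adjust={adjust})",
            stacklevel=2)
    if otu is not None:
        mean_rel = otu.relative_abundance().mean(axis=0)
        for node in graph.nodes:
            graph.nodes[node]["mean_rel_abund"] = float(mean_rel.get(node, np.nan))
    if tax is not None:
        for node in graph.nodes:
            graph.nodes[node]["taxonomy"] = tax.lineage_of(node, "phylum")
    params = {"r_min": r_min, "p_max": p_max, "adjust": adjust}
    return CoNetwork(graph, group=group, params=params)


def topology(network: CoNetwork) -> dict:
    """Classical whole-network topology metrics.

    Characteristic path length is the mean shortest-path length over the
    largest connected component; clustering is the mean local clustering
    coefficient with degree < 2 nodes contributing 0; density is
    2E/(N(N-1)) and average connectivity the mean degree 2E/N.
    """
    g = network.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValidationError("topology of an empty network is undefined")
    if n > 1:
        comp = max(nx.connected_components(g), key=len)
        cpl = (nx.average_shortest_path_length(g.subgraph(comp))
               if len(comp) > 1 else np.nan)
        density = 2.0 * e / (n * (n - 1))
    else:
        cpl, density = np.nan, np.nan
    clustering = float(np.mean(list(nx.clustering(g).values()))) if n else np.nan
    modules = network.modules
    q = (modularity(network, modules) if len(modules) == n and n > 0 and e > 0
         else np.nan)
    return {
        "nodes": n,
        "edges": e,
        "path_length": float(cpl) if cpl == cpl else np.nan,
        "clustering": clustering,
        "density": float(density) if density == density else np.nan,
        "mean_degree": 2.0 * e / n,
        "modularity": q,
    }


def modularity(network: CoNetwork, assignment: dict) -> float:
    """Newman modularity Q = sum_i (e_ii - a_i^2) of a node partition."""
    g = network.graph
    if g.number_of_edges() == 0:
        raise ValidationError("modularity of an edgeless graph is undefined")
    communities: dict[int, set] = {}
    for node, mod in assignment.items():
        communities.setdefault(mod, set()).add(node)
    return float(nx.community.modularity(g, communities.values(), weight=None))


def detect_modules(network: CoNetwork, seed: int | None = None
                   ) -> tuple[dict, float]:
    """Greedy agglomerative (CNM) modularity maximisation.

    The algorithm is deterministic for a given graph; ``seed`` is accepted
    for interface symmetry with the stochastic stages. Module ids are
    assigned in decreasing community size, ties broken by smallest member,
    and written onto the network's nodes.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValidationError("cannot detect modules in an empty network")
    if g.number_of_edges() == 0:
        assignment = {n: i for i, n in enumerate(sorted(g.nodes, key=str))}
        network.set_modules(assignment)
        return assignment, np.nan
    comms = nx.community.greedy_modularity_communities(g, weight=None)
    comms = sorted((sorted(c, key=str) for c in comms),
                   key=lambda c: (-len(c), c))
    assignment = {node: i for i, members in enumerate(comms) for node in members}
    q = modularity(network, assignment)
    network.set_modules(assignment)
    return assignment, q


def zi_pi(network: CoNetwork, modules: dict | None = None,
          zi_hub: float = 2.5, pi_connector: float = 0.62) -> pd.DataFrame:
    """Within-module degree z-score and participation coefficient per node.

    Zi = (k_within - mean_module) / sd_module (0 when sd is 0);
    Pi = 1 - sum_m (k_im / k_i)^2. Roles follow the usual cutoffs:
    module hub (Zi > zi_hub), connector (Pi > pi_connector), network hub
    (both), else peripheral. Isolated nodes have undefined Pi and are
    flagged peripheral.
    """
    g = network.graph
    modules = network.modules if modules is None else modules
    missing = set(g.nodes) - set(modules)
    if missing:
        raise ValidationError(f"modules missing for nodes: {sorted(missing)}")
    nodes = list(g.nodes)
    within = {}
    per_module_links = {}
    for node in nodes:
        counts: dict[int, int] = {}
        for nb in g.neighbors(node):
            counts[modules[nb]] = counts.get(modules[nb], 0) + 1
        per_module_links[node] = counts
        within[node] = counts.get(modules[node], 0)
    by_module: dict[int, list] = {}
    for node in nodes:
        by_module.setdefault(modules[node], []).append(within[node])
    mod_stats = {m: (float(np.mean(v)), float(np.std(v, ddof=0)))
                 for m, v in by_module.items()}
    rows = []
    for node in nodes:
        k = g.degree(node)
        mean_w, sd_w = mod_stats[modules[node]]
        zi = 0.0 if sd_w == 0 else (within[node] - mean_w) / sd_w
        if k == 0:
            pi, isolated = np.nan, True
        else:
            pi = 1.0 - sum((c / k) ** 2 for c in per_module_links[node].values())
            isolated = False
        if isolated:
            role = "peripheral"
        elif zi > zi_hub and pi > pi_connector:
            role = "network hub"
        elif zi > zi_hub:
            role = "module hub"
        elif pi > pi_connector:
            role = "connector"
        else:
            role = "peripheral"
        rows.append({"node": node, "module": modules[node], "degree": k,
                     "zi": zi, "pi": pi, "role": role, "isolated": isolated})
    return pd.DataFrame(rows).set_index("node")
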