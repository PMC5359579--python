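"""Spearman co-occurrence networks, topology indices, Louvain modularity
and module-habitat association tests.

Edges connect OTU pairs whose site-abundance profiles are strongly and
significantly rank-correlated (rho > 0.6, p < 0.01 by default, positive
correlations only).  The Louvain algorithm implemented here alternates its
two classic phases -- local modularity-maximising node moves, then
aggregation of communities into super-nodes -- until modularity can no
longer be increased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import OtuTable, SampleMetadata


@dataclass
class CorrMatrix:
    ids: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame


@dataclass
class TopologyResult:
    graph: pd.Series      # diameter, average_path_length, n_shortest_paths, ...
    nodes: pd.DataFrame   # degree, closeness, closeness_recip_farness, betweenness


def spearman_matrix(table: OtuTable, min_total: int = 5,
                    use_relative: bool = True) -> CorrMatrix:
    """All-pairs Spearman rank correlation between OTU abundance profiles.

    OTUs with total count <= ``min_total`` (the strict "more than 5"
    criterion) are excluded first.  By default profiles are per-site
    relative abundances: correlating raw counts across libraries of very
    unequal depth makes every pair look positively associated through
    sequencing effort alone (``use_relative=False`` restores raw counts).
    Two-sided p-values use the t-distribution approximation with midrank
    ties.
    """
    counts = table.counts
    if len(counts) < 4:
        raise ValueError("need >= 4 sites for meaningful correlation p-values")
    keep = counts.columns[counts.sum(axis=0) > min_total]
    if len(keep) < 2:
        raise ValueError("fewer than 2 OTUs survive the abundance filter")
    arr = counts[keep].to_numpy(float)
    if use_relative:
        totals = counts.sum(axis=1).to_numpy(float)
        arr = arr / np.where(totals > 0, totals, 1.0)[:, None]
    rho, p = stats.spearmanr(arr, axis=0)
    if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    ids = list(keep)
    return CorrMatrix(ids, pd.DataFrame(rho, index=ids, columns=ids),
                      pd.DataFrame(p, index=ids, columns=ids))


def build_network(corr: CorrMatrix, rho_min: float = 0.6, p_max: float = 0.01,
                  table: OtuTable | None = None, keep_isolated: bool = False,
                  signed: bool = False, bh_correct: bool = False) -> nx.Graph:
    """Threshold the correlation matrix into an undirected network.

    An edge joins i and j iff rho_ij > rho_min and p_ij < p_max (with
    ``signed=True``, |rho_ij| > rho_min).  ``bh_correct`` applies
    Benjamini-Hochberg to the pairwise p-values first (off by default).
    Isolated nodes are dropped unless ``keep_isolated``.
    """
    ids = corr.ids
    rho = corr.rho.to_numpy()
    p = corr.p.to_numpy().copy()
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    if bh_correct:
        raw = p[iu]
        order = np.argsort(raw)
        m = len(raw)
        adj = np.empty(m)
        adj[order] = np.minimum.accumulate((raw[order] * m /
                                            np.arange(1, m + 1))[::-1])[::-1]
        p[iu] = np.clip(adj, 0, 1)
        p.T[iu] = p[iu]
    G = nx.Graph()
    G.add_nodes_from(ids)
    strength = np.abs(rho) if signed else rho
    for i, j in zip(*iu):
        if np.isfinite(strength[i, j]) and strength[i, j] > rho_min \
                and p[i, j] < p_max:
            G.add_edge(ids[i], ids[j], rho=float(rho[i, j]),
                       p=float(p[i, j]))
    if not keep_isolated:
        G.remove_nodes_from([v for v in list(G) if G.degree(v) == 0])
    if table is not None:
        lineage = table.lineage
        totals = table.counts.sum(axis=0)
        for v in G:
            G.nodes[v]["lineage"] = str(lineage.get(v, "U"))
            G.nodes[v]["total_count"] = int(totals.get(v, 0))
    return G


def topology(net: nx.Graph) -> TopologyResult:
    """Unweighted topology indices, graph-level and per-node.

    Path statistics are computed within connected components; the
    graph-level diameter/average path length are reported both for the
    largest component and as component-size-weighted means.
    ``n_shortest_paths`` counts unordered connected node pairs (each pair
    contributes one geodesic).
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comps = [net.subgraph(c) for c in nx.connected_components(net)]
    comps.sort(key=lambda c: -c.number_of_nodes())
    diam, apl, weights, n_pairs = [], [], [], 0
    for c in comps:
        nc = c.number_of_nodes()
        if nc > 1:
            e = nx.eccentricity(c)
            diam.append(max(e.values()))
            apl.append(nx.average_shortest_path_length(c))
            weights.append(nc)
            n_pairs += nc * (nc - 1) // 2
    largest = comps[0]
    graph = pd.Series({
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "n_components": len(comps),
        "diameter_largest": (nx.diameter(largest)
                             if largest.number_of_nodes() > 1 else 0),
        "diameter_weighted": (float(np.average(diam, weights=weights))
                              if diam else 0.0),
        "average_path_length_largest": (
            nx.average_shortest_path_length(largest)
            if largest.number_of_nodes() > 1 else 0.0),
        "average_path_length_weighted": (
            float(np.average(apl, weights=weights)) if apl else 0.0),
        "n_shortest_paths": n_pairs,
    })
    closeness = nx.closeness_centrality(net, wf_improved=False)
    betweenness = nx.betweenness_centrality(net, normalized=False)
    recip = {}
    for c in comps:
        if c.number_of_nodes() == 1:
            recip[next(iter(c))] = 0.0
            continue
        for v in c:
            far = sum(nx.single_source_shortest_path_length(c, v).values())
            recip[v] = 1.0 / far if far > 0 else 0.0
    nodes = pd.DataFrame({
        "degree": pd.Series(dict(net.degree())),
        "closeness": pd.Series(closeness),
        "closeness_recip_farness": pd.Series(recip),
        "betweenness": pd.Series(betweenness),
    })
    return TopologyResult(graph, nodes.sort_index())


def modularity(net: nx.Graph, partition: dict) -> float:
    """Q = sum_c (e_c/m - (d_c/2m)^2) for an unweighted partition."""
    m = net.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    intra: dict = {}
    deg: dict = {}
    for u, v in net.edges():
        if partition[u] == partition[v]:
            intra[partition[u]] = intra.get(partition[u], 0) + 1
    for v, d in net.degree():
        deg[partition[v]] = deg.get(partition[v], 0) + d
    return float(sum(intra.get(c, 0) / m - (deg[c] / (2 * m)) ** 2
                     for c in deg))


def _louvain_level(adj: dict, degree: dict, m: float, rng):
    """One Louvain level: local moves until no gain.  Returns node->community."""
    nodes = list(adj)
    comm = {v: v for v in nodes}
    tot = {v: degree[v] for v in nodes}          # total degree per community
    improved_any = True
    while improved_any:
        improved_any = False
        order = list(nodes)
        rng.shuffle(order)
        for v in order:
            cv = comm[v]
            kv = degree[v]
            # weights to neighbouring communities (excluding self-loop)
            links: dict = {}
            for u, w in adj[v].items():
                if u != v:
                    links[comm[u]] = links.get(comm[u], 0.0) + w
            tot[cv] -= kv
            comm[v] = None
            best_c, best_gain = cv, links.get(cv, 0.0) - tot[cv] * kv / (2 * m)
            for c, w in links.items():
                gain = w - tot[c] * kv / (2 * m)
                if gain > best_gain + 1e-12:
                    best_gain, best_c = gain, c
            comm[v] = best_c
            tot[best_c] += kv
            if best_c != cv:
                improved_any = True
    return comm


def louvain(net: nx.Graph, seed=None) -> tuple[dict, float]:
    """Louvain community detection; returns (node -> module id, Q).

    Module ids are dense integers from 1.  Node visit order within each
    pass is shuffled by the seeded generator; aggregation repeats until Q
    stops increasing.
    """
    if net.number_of_edges() == 0:
        raise ValueError("Louvain requires at least one edge")
    rng = np.random.default_rng(seed)
    m = float(net.number_of_edges())
    # current aggregated graph: adjacency dict with weights, self-loop weights
    adj = {v: {} for v in net.nodes}
    for u, v in net.edges():
        adj[u][v] = adj[u].get(v, 0.0) + 1.0
        if u != v:
            adj[v][u] = adj[v].get(u, 0.0) + 1.0
    membership = {v: v for v in net.nodes}       # original node -> super-node
    q_prev = None
    while True:
        degree = {v: sum(w for w in nb.values()) + nb.get(v, 0.0)
                  for v, nb in adj.items()}      # self-loops count twice
        comm = _louvain_level(adj, degree, m, rng)
        membership = {orig: comm[sup] for orig, sup in membership.items()}
        part = {v: membership[v] for v in net.nodes}
        q = modularity(net, part)
        if q_prev is not None and q <= q_prev + 1e-12:
            break
        q_prev = q
        # aggregate communities into super-nodes; cross weights sum the
        # inter-community edges, the self-loop sums intra edges + old loops
        new_adj: dict = {}
        for v, nb in adj.items():
            cv = comm[v]
            row = new_adj.setdefault(cv, {})
            for u, w in nb.items():
                cu = comm[u]
                if u == v:
                    row[cv] = row.get(cv, 0.0) + w
                elif cu == cv:
                    row[cv] = row.get(cv, 0.0) + w / 2.0
                else:
                    row[cu] = row.get(cu, 0.0) + w
        adj = new_adj
        if len(adj) == 1:
            break
    # dense module ids from 1, ordered by first appearance over sorted nodes
    final = {v: membership[v] for v in net.nodes}
    relabel: dict = {}
    for v in sorted(final, key=str):
        c = final[v]
        if c not in relabel:
            relabel[c] = len(relabel) + 1
    part = {v: relabel[final[v]] for v in final}
    return part, modularity(net, part)


def module_habitat_fisher(partition: dict, table: OtuTable,
                          metadata: SampleMetadata) -> pd.DataFrame:
    """Two-sided Fisher's exact test of module-habitat association.

    For each (module, habitat): a 2x2 table of network OTUs cross-
    classified as in/out of the module versus detected/undetected in the
    habitat's pooled sites.
    """
    otus = [o for o in partition if o in table.counts.columns]
    hab = metadata.habitat.reindex(table.counts.index)
    rows = []
    for habitat in pd.unique(hab):
        sites = hab.index[hab == habitat]
        detected = table.counts.loc[sites, otus].sum(axis=0) > 0
        if not detected.any():
            warnings.warn(f"habitat {habitat!r} has no detected network OTUs")
            continue
        for module in sorted(set(partition.values())):
            in_mod = pd.Series({o: partition[o] == module for o in otus})
            a = int((in_mod & detected).sum())
            b = int((in_mod & ~detected).sum())
            c = int((~in_mod & detected).sum())
            d = int((~in_mod & ~detected).sum())
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append({"module": module, "habitat": habitat,
                         "n_in_module_detected": a, "n_in_module": a + b,
                         "p": float(p)})
    return pd.DataFrame(rows)
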