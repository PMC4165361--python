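"""Thresholded phenotypic drug-disease network, communities, class enrichment.

Scored pairs at or above a similarity threshold form a bipartite network of
drug and disease nodes. Communities are found by greedy multi-level
modularity optimization (Louvain-style: local node moves followed by
community aggregation, repeated until modularity stops improving), with no
constraint on community number or size. Class enrichment inside communities
(disease classes on disease nodes, drug classes on drug nodes) and
disease-class x drug-class combination enrichment of network edges against
the full pair universe are tested with one-sided Fisher's exact tests under
Benjamini-Hochberg control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PhenoNetwork",
    "CommunityPartition",
    "build_network",
    "detect_communities",
    "modularity",
    "community_class_enrichment",
    "class_combination_enrichment",
    "load_class_map",
    "write_network",
]

log = logging.getLogger(__name__)


@dataclass
class PhenoNetwork:
    """Bipartite drug-disease network of high-similarity pairs.

    Node ids are namespaced as ``drug:<id>`` / ``disease:<id>`` so a shared
    identifier cannot collide across the two sides.
    """

    edges: list[tuple[str, str, float]]  # (drug node, disease node, similarity)
    threshold: float

    @property
    def nodes(self) -> set[str]:
        return {n for d, s, _ in self.edges for n in (d, s)}

    @property
    def drugs(self) -> set[str]:
        return {d for d, _, _ in self.edges}

    @property
    def diseases(self) -> set[str]:
        return {s for _, s, _ in self.edges}

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict[str, dict[str, float]]:
        adj: dict[str, dict[str, float]] = {}
        for d, s, _ in self.edges:
            adj.setdefault(d, {})[s] = adj.setdefault(d, {}).get(s, 0.0) + 1.0
            adj.setdefault(s, {})[d] = adj.setdefault(s, {}).get(d, 0.0) + 1.0
        return adj


@dataclass
class CommunityPartition:
    assignment: dict[str, int]
    modularity: float


def drug_node(entity: str) -> str:
    return f"drug:{entity}"


def disease_node(entity: str) -> str:
    return f"disease:{entity}"


def build_network(scored: pd.DataFrame, threshold: float) -> PhenoNetwork:
    """Keep pairs with similarity >= threshold; isolated entities never enter."""
    keep = scored[scored["similarity"] >= threshold]
    if keep.empty:
        log.warning("threshold %.6g exceeds the maximum score; network is empty", threshold)
    edges = [
        (drug_node(d), disease_node(s), float(v))
        for d, s, v in zip(keep["drug_id"], keep["disease_id"], keep["similarity"])
    ]
    return PhenoNetwork(edges=edges, threshold=float(threshold))


# ---------------------------------------------------------------------------
# Greedy multi-level modularity optimization
# ---------------------------------------------------------------------------

def modularity(adj: Mapping[str, Mapping[str, float]], assignment: Mapping[str, int]) -> float:
    """Q = sum_c (e_c/m - (d_c/2m)^2) recomputed directly from a partition.

    ``e_c`` is the intra-community edge weight (each edge once, self-loops
    once), ``d_c`` the summed degrees (self-loops counted twice), ``m`` the
    total edge weight.
    """
    m = 0.0
    deg: dict[str, float] = {}
    for u, nbrs in adj.items():
        d = 0.0
        for v, w in nbrs.items():
            d += w if u != v else 2 * w
            if u <= v:
                m += w
        deg[u] = d
    if m == 0:
        raise ValueError("modularity undefined for an empty graph")
    e_c: dict[int, float] = {}
    d_c: dict[int, float] = {}
    for u, nbrs in adj.items():
        cu = assignment[u]
        d_c[cu] = d_c.get(cu, 0.0) + deg[u]
        for v, w in nbrs.items():
            if u < v and assignment[v] == cu:
                e_c[cu] = e_c.get(cu, 0.0) + w
            elif u == v:
                e_c[cu] = e_c.get(cu, 0.0) + w
    return sum(
        e_c.get(c, 0.0) / m - (d_c[c] / (2 * m)) ** 2 for c in d_c
    )


def _one_level(
    adj: list[dict[int, float]],
    deg: list[float],
    m: float,
    rng: np.random.Generator,
) -> tuple[list[int], bool]:
    """Local-moving phase: greedily reassign nodes until no move improves Q."""
    n = len(adj)
    comm = list(range(n))
    comm_deg = deg[:]  # total degree per community
    improved = False
    order = list(range(n))
    rng.shuffle(order)
    moved = True
    while moved:
        moved = False
        for i in order:
            ci = comm[i]
            ki = deg[i]
            # weight from i to each neighbouring community (self-loops excluded)
            links: dict[int, float] = {}
            for j, w in adj[i].items():
                if j != i:
                    links[comm[j]] = links.get(comm[j], 0.0) + w
            comm_deg[ci] -= ki
            best_c, best_gain = ci, links.get(ci, 0.0) - comm_deg[ci] * ki / (2 * m)
            for c in sorted(links):
                gain = links[c] - comm_deg[c] * ki / (2 * m)
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
            comm_deg[best_c] += ki
            if best_c != ci:
                comm[i] = best_c
                moved = True
                improved = True
    return comm, improved


def _aggregate(
    adj: list[dict[int, float]], comm: list[int]
) -> tuple[list[dict[int, float]], list[int]]:
    """Collapse communities into super-nodes; intra edges become self-loops."""
    labels = sorted(set(comm))
    remap = {c: i for i, c in enumerate(labels)}
    new_adj: list[dict[int, float]] = [dict() for _ in labels]
    for i, nbrs in enumerate(adj):
        ci = remap[comm[i]]
        for j, w in nbrs.items():
            cj = remap[comm[j]]
            if i < j or i == j:
                if ci == cj:
                    new_adj[ci][ci] = new_adj[ci].get(ci, 0.0) + w
                else:
                    new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
                    new_adj[cj][ci] = new_adj[cj].get(ci, 0.0) + w
    return new_adj, [remap[c] for c in comm]


def detect_communities(net: PhenoNetwork, seed: int = 0) -> CommunityPartition:
    """Louvain-style greedy multi-level modularity optimization.

    Deterministic for a fixed seed and node set: node visiting order within
    each level is a seeded shuffle and community ties break toward the lowest
    community index. The resulting modularity is never below that of the
    all-singleton partition (the algorithm only accepts improving moves).
    """
    if net.n_edges == 0:
        raise ValueError("cannot detect communities in an empty network")
    nodes = sorted(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj: list[dict[int, float]] = [dict() for _ in nodes]
    for d, s, _ in net.edges:
        i, j = index[d], index[s]
        adj[i][j] = adj[i].get(j, 0.0) + 1.0
        adj[j][i] = adj[j].get(i, 0.0) + 1.0
    rng = np.random.default_rng(seed)
    # membership of each original node through the levels
    member = list(range(len(nodes)))
    while True:
        deg = [
            sum(w if j != i else 2 * w for j, w in nbrs.items())
            for i, nbrs in enumerate(adj)
        ]
        m = sum(deg) / 2
        comm, improved = _one_level(adj, deg, m, rng)
        if not improved:
            break
        adj, comm = _aggregate(adj, comm)
        member = [comm[c] for c in member]
    # relabel communities 0..k-1 in order of first appearance over sorted nodes
    relabel: dict[int, int] = {}
    assignment = {}
    for v in nodes:
        c = member[index[v]]
        if c not in relabel:
            relabel[c] = len(relabel)
        assignment[v] = relabel[c]
    q = modularity(net.adjacency(), assignment)
    return CommunityPartition(assignment=assignment, modularity=q)


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------

def load_class_map(path: str | Path) -> dict[str, set[str]]:
    """Read ``entity_id<TAB>class_id`` (header required) into a multimap."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = ["entity_id", "class_id"]
    return {e: set(g["class_id"]) for e, g in df.groupby("entity_id")}


def community_class_enrichment(
    net: PhenoNetwork,
    partition: CommunityPartition,
    classes: Mapping[str, set[str]],
    side: str = "disease",
    fdr_cutoff: float = 0.01,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-(community, class) over-representation among one side's nodes.

    For each community and class, a 2x2 table of (inside vs outside the
    community) x (class member vs not) is built over the classified nodes of
    the chosen side and tested one-sided. Entities with several classes count
    once per class. BH correction spans every tested cell of this side.
    """
    if side not in ("disease", "drug"):
        raise ValueError("side must be 'disease' or 'drug'")
    prefix = f"{side}:"
    side_nodes = [n for n in sorted(net.nodes) if n.startswith(prefix)]
    node_classes = {
        n: classes.get(n[len(prefix):], set()) for n in side_nodes
    }
    classified = [n for n in side_nodes if node_classes[n]]
    if not classified:
        raise ValueError(f"no classified {side} node in the network")
    communities = sorted({partition.assignment[n] for n in classified})
    all_classes = sorted({c for n in classified for c in node_classes[n]})
    rows = []
    for comm in communities:
        inside = [n for n in classified if partition.assignment[n] == comm]
        outside_n = len(classified) - len(inside)
        if outside_n == 0:
            log.warning(
                "community %d contains every classified %s node; no rest to compare, skipped",
                comm, side,
            )
            continue
        for cls in all_classes:
            a = sum(1 for n in inside if cls in node_classes[n])
            if a == 0:
                continue  # class absent from community: cannot be over-represented
            b = len(inside) - a
            c = sum(
                1
                for n in classified
                if cls in node_classes[n] and partition.assignment[n] != comm
            )
            d = outside_n - c
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
            rows.append(
                {
                    "community": comm,
                    "class_id": cls,
                    "in_class": a,
                    "in_total": len(inside),
                    "out_class": c,
                    "out_total": outside_n,
                    "odds_ratio": float(odds),
                    "p_value": float(p),
                }
            )
    columns = [
        "community", "class_id", "in_class", "in_total", "out_class",
        "out_total", "odds_ratio", "p_value",
    ]
    df = pd.DataFrame(rows, columns=columns)
    if df.empty:
        df["fdr"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df["significant"] = df["fdr"] <= fdr_cutoff
    return df.sort_values(["fdr", "community", "class_id"]).reset_index(drop=True)


def class_combination_enrichment(
    net: PhenoNetwork,
    scored: pd.DataFrame,
    disease_classes: Mapping[str, set[str]],
    drug_classes: Mapping[str, set[str]],
    fdr_cutoff: float = 0.05,
    alternative: str = "greater",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Disease-class x drug-class combinations over-represented in the network.

    Each scored pair belongs to combination (C, A) when its disease carries
    class C and its drug carries class A. The 2x2 table contrasts network
    membership with combination membership over the full scored universe.
    Returns the per-combination table and a summary with the number and
    fraction of network edges covered by significant combinations.
    """
    net_pairs = {
        (d.split(":", 1)[1], s.split(":", 1)[1]) for d, s, _ in net.edges
    }
    universe = list(zip(scored["drug_id"], scored["disease_id"]))
    n_total = len(universe)
    n_net = len(net_pairs)
    combos: dict[tuple[str, str], list[int]] = {}
    # counts per combo: [in-network pairs, universe pairs]
    for pair in universe:
        drug, disease = pair
        in_net = pair in net_pairs
        for dc in disease_classes.get(disease, set()):
            for ac in drug_classes.get(drug, set()):
                rec = combos.setdefault((dc, ac), [0, 0])
                rec[1] += 1
                if in_net:
                    rec[0] += 1
    rows = []
    for (dc, ac), (k_net, k_all) in sorted(combos.items()):
        if k_net == 0:
            continue
        a = k_net
        b = n_net - k_net
        c = k_all - k_net
        d = (n_total - n_net) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        rows.append(
            {
                "disease_class": dc,
                "drug_class": ac,
                "network_pairs": a,
                "universe_pairs": k_all,
                "odds_ratio": float(odds),
                "p_value": float(p),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df, {"n_significant": 0, "edges_covered": 0, "fraction_covered": 0.0}
    df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df["significant"] = df["fdr"] <= fdr_cutoff
    df = df.sort_values(["fdr", "disease_class", "drug_class"]).reset_index(drop=True)
    sig = df[df["significant"]]
    covered = set()
    sig_combos = set(zip(sig["disease_class"], sig["drug_class"]))
    for drug, disease in net_pairs:
        for dc in disease_classes.get(disease, set()):
            for ac in drug_classes.get(drug, set()):
                if (dc, ac) in sig_combos:
                    covered.add((drug, disease))
                    break
            else:
                continue
            break
    summary = {
        "n_significant": int(len(sig)),
        "edges_covered": len(covered),
        "fraction_covered": len(covered) / n_net if n_net else 0.0,
    }
    return df, summary


def write_network(
    net: PhenoNetwork,
    path_edges: str | Path,
    path_graphml: str | Path | None = None,
    partition: CommunityPartition | None = None,
    disease_classes: Mapping[str, set[str]] | None = None,
    drug_classes: Mapping[str, set[str]] | None = None,
) -> None:
    """Export the network as edge-list TSV and optionally annotated GraphML."""
    with open(path_edges, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tdisease_id\tsimilarity\n")
        for d, s, v in sorted(net.edges):
            fh.write(f"{d.split(':', 1)[1]}\t{s.split(':', 1)[1]}\t{v:.6f}\n")
    if path_graphml is not None:
        import networkx as nx

        g = nx.Graph()
        for d, s, v in net.edges:
            g.add_edge(d, s, similarity=v)
        for n in g.nodes:
            kind, ent = n.split(":", 1)
            g.nodes[n]["kind"] = kind
            cls = (drug_classes if kind == "drug" else disease_classes) or {}
            g.nodes[n]["classes"] = ";".join(sorted(cls.get(ent, set())))
            if partition is not None:
                g.nodes[n]["community"] = partition.assignment[n]
        nx.write_graphml(g, path_graphml)
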