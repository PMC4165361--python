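"""Shortest-path distances between drug targets and disease genes in a PPI net.

For a drug-disease pair the molecular distance is the minimum shortest-path
length in an undirected, unweighted protein-protein interaction network over
all (target, gene) combinations; 0 means a shared protein. Distances are
binned into five exhaustive categories — 0, 1, 2, 3 and ">3" — with
unreachable pairs assigned to ">3" so category totals always partition the
pair set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "PPINetwork",
    "MolecularLink",
    "CATEGORIES",
    "load_ppi",
    "load_protein_map",
    "set_distance",
    "distance_category",
    "molecular_links",
    "categorize_pairs",
]

log = logging.getLogger(__name__)

CATEGORIES = ("0", "1", "2", "3", ">3")

UNREACHABLE = -1  # sentinel distance for no path


@dataclass
class PPINetwork:
    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def load_ppi(path: str | Path) -> PPINetwork:
    """Read a ``protein_a<TAB>protein_b`` edge list into an undirected graph.

    Reversed duplicates collapse; self-loop rows are dropped with a warning.
    An empty file yields an empty network (warned, not fatal).
    """
    g = nx.Graph()
    n_self = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields")
            a, b = fields[0], fields[1]
            if lineno == 1 and a.lower().startswith("protein"):
                continue
            if a == b:
                n_self += 1
                continue
            g.add_edge(a, b)
    if n_self:
        log.warning("dropped %d self-loop rows from %s", n_self, path)
    if g.number_of_edges() == 0:
        log.warning("PPI network from %s is empty", path)
    return PPINetwork(graph=g)


def load_protein_map(path: str | Path) -> dict[str, set[str]]:
    """Read ``entity_id<TAB>protein_id`` (header optional) into a multimap."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    if str(df.iloc[0, 1]).lower().startswith("protein"):
        df = df.iloc[1:]
    return {e: set(g.iloc[:, 1]) for e, g in df.groupby(df.columns[0])}


def set_distance(
    ppi: PPINetwork, targets: Iterable[str], genes: Iterable[str]
) -> int:
    """Minimum shortest-path length between two protein sets.

    Proteins absent from the network are ignored; if an entire set is absent
    the distance is undefined and an error is raised. Returns 0 on overlap and
    the ``UNREACHABLE`` sentinel when no path connects the sets. Implemented
    as one multi-source BFS from the smaller set.
    """
    t = set(targets) & ppi.nodes
    g = set(genes) & ppi.nodes
    if not t:
        raise ValueError("no drug target is present in the PPI network")
    if not g:
        raise ValueError("no disease gene is present in the PPI network")
    if t & g:
        return 0
    src, dst = (t, g) if len(t) <= len(g) else (g, t)
    best = None
    lengths = _multi_source_bfs(ppi.graph, src, stop_at=dst)
    for node in dst:
        d = lengths.get(node)
        if d is not None and (best is None or d < best):
            best = d
    return best if best is not None else UNREACHABLE


def _multi_source_bfs(
    graph: nx.Graph, sources: set[str], stop_at: set[str] | None = None
) -> dict[str, int]:
    """BFS layer expansion from a source set; early exit once a target layer hit."""
    seen = {s: 0 for s in sources}
    frontier = list(sources)
    depth = 0
    while frontier:
        if stop_at is not None and any(n in stop_at for n in frontier):
            break
        depth += 1
        nxt = []
        for n in frontier:
            for nb in graph.adj[n]:
                if nb not in seen:
                    seen[nb] = depth
                    nxt.append(nb)
        frontier = nxt
    return seen


def distance_category(distance: int) -> str:
    """Bin a distance into {0, 1, 2, 3, ">3"}; unreachable counts as ">3"."""
    if distance == UNREACHABLE or distance > 3:
        return ">3"
    if distance < 0:
        raise ValueError(f"invalid distance {distance}")
    return str(distance)


@dataclass(frozen=True)
class MolecularLink:
    drug: str
    disease: str
    distance: int  # UNREACHABLE sentinel when no path
    category: str


def molecular_links(
    ppi: PPINetwork,
    targets: Mapping[str, set[str]],
    genes: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Distance and category for every covered drug x disease combination.

    Entities with no protein in the network are skipped (they have no
    molecular information). One BFS per drug covers all diseases.
    """
    covered_drugs = {
        d: ts & ppi.nodes for d, ts in targets.items() if ts & ppi.nodes
    }
    covered_dis = {
        d: gs & ppi.nodes for d, gs in genes.items() if gs & ppi.nodes
    }
    records = []
    for drug in sorted(covered_drugs):
        lengths = _multi_source_bfs(ppi.graph, covered_drugs[drug])
        for disease in sorted(covered_dis):
            ds = [lengths[g] for g in covered_dis[disease] if g in lengths]
            dist = min(ds) if ds else UNREACHABLE
            records.append((drug, disease, dist, distance_category(dist)))
    return pd.DataFrame(
        records, columns=["drug_id", "disease_id", "distance", "category"]
    )


def categorize_pairs(links: pd.DataFrame) -> dict[str, int]:
    """Count links per distance category; every category key is present."""
    counts = links["category"].value_counts().to_dict()
    return {c: int(counts.get(c, 0)) for c in CATEGORIES}
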