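"""Phenotype term ontology: a rooted DAG with hyponym-count information content.

The ontology is a MedDRA-like hierarchy of phenotype terms (most general at
the root, most specific at the leaves) in which a term may have several
parents and cross-hierarchy bridge edges are ordinary parent edges. Term
specificity is measured by an information content (IC) derived from the
hierarchy itself rather than from corpus annotation frequencies:

    IC(term) = 1 - log(hypo(term) + 1) / log(N)

where ``hypo(term)`` is the number of distinct descendant terms and ``N`` the
total number of terms. Leaves get IC 1, the root gets IC 0, and IC never
increases when moving from a term to one of its ancestors. The similarity
between two terms is the IC of their most informative common ancestor (MICA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx

__all__ = [
    "Ontology",
    "TermIC",
    "OntologyStructureError",
    "load_ontology",
    "hyponym_counts",
    "information_content",
    "ancestors",
    "mica",
    "write_ic_table",
]


class OntologyStructureError(ValueError):
    """Raised when parsed edges do not form a single-rooted DAG."""


@dataclass(frozen=True)
class TermIC:
    """Per-term hyponym count and information content."""

    term: str
    hypo: int
    ic: float


@dataclass
class Ontology:
    """A rooted DAG of phenotype terms.

    Parameters
    ----------
    parent_edges
        Mapping from each child term to the set of its parent terms. The root
        is the unique term that appears only as a parent.

    The internal graph stores edges child -> parent, so graph-theoretic
    descendants of a term are its ancestors in the ontology sense.
    """

    parent_edges: Mapping[str, set[str]]
    graph: nx.DiGraph = field(init=False, repr=False)
    root: str = field(init=False)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        for child, parents in self.parent_edges.items():
            g.add_node(child)
            for p in parents:
                g.add_edge(child, p)
        if g.number_of_nodes() == 0:
            raise OntologyStructureError("empty ontology")
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise OntologyStructureError(
                f"cycle detected in ontology, e.g. edge {cyc[0][0]!r} -> {cyc[0][1]!r}"
            )
        roots = [n for n in g.nodes if g.out_degree(n) == 0]
        if len(roots) != 1:
            raise OntologyStructureError(
                f"ontology must have exactly one root, found {len(roots)}: "
                f"{sorted(roots)[:5]}"
            )
        self.graph = g
        self.root = roots[0]

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_terms(self) -> int:
        """Total number of terms N, the normalizer of the IC formula."""
        return self.graph.number_of_nodes()

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def children(self, term: str) -> set[str]:
        """Direct hyponyms (children in the hierarchy) of *term*."""
        self._check(term)
        return set(self.graph.predecessors(term))

    def parents(self, term: str) -> set[str]:
        self._check(term)
        return set(self.graph.successors(term))

    def leaves(self) -> set[str]:
        """Terms with no hyponyms (the most specific level)."""
        return {n for n in self.graph.nodes if self.graph.in_degree(n) == 0}

    def _check(self, term: str) -> None:
        if term not in self.graph:
            raise KeyError(f"unknown ontology term: {term!r}")


def load_ontology(path: str | Path, format: str = "edge_tsv") -> Ontology:
    """Read an ontology from an edge-list TSV (``child<TAB>parent``) or OBO file.

    The TSV may carry an optional header line; any line whose two fields are
    ``child``/``parent`` (case-insensitive) is skipped. OBO files are parsed
    with :mod:`obonet` and ``is_a`` relations become parent edges.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    edges: dict[str, set[str]] = {}
    if format == "edge_tsv":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise OntologyStructureError(
                        f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                    )
                child, parent = fields
                if lineno == 1 and child.lower() == "child" and parent.lower() == "parent":
                    continue
                edges.setdefault(child, set()).add(parent)
                edges.setdefault(parent, set())
    elif format == "obo":
        import obonet

        g = obonet.read_obo(path)
        # obonet edges run child -> parent for is_a
        for child, parent, key in g.edges(keys=True):
            if key == "is_a":
                edges.setdefault(child, set()).add(parent)
                edges.setdefault(parent, set())
    else:
        raise ValueError(f"unknown ontology format: {format!r}")
    if not edges:
        raise OntologyStructureError(f"no edges parsed from {path}")
    return Ontology(edges)


def hyponym_counts(onto: Ontology) -> dict[str, int]:
    """Count distinct descendant terms (hyponyms) of every term.

    Multi-parent descendants are counted once (set semantics). Computed in a
    single topological sweep propagating descendant bitsets child -> parent.
    """
    order = list(nx.topological_sort(onto.graph))  # children before parents
    idx = {t: i for i, t in enumerate(order)}
    n = len(order)
    desc = [0] * n  # python ints as bitsets over term indices
    for t in order:
        i = idx[t]
        acc = desc[i]
        for child in onto.graph.predecessors(t):
            j = idx[child]
            acc |= desc[j] | (1 << j)
        desc[i] = acc
    return {t: desc[idx[t]].bit_count() for t in order}


def information_content(onto: Ontology) -> dict[str, TermIC]:
    """Assign each term the hyponym-count IC: 1 - log(hypo+1)/log(N).

    The ratio of logarithms makes the value base-independent; natural log is
    used. A single-term ontology has log(N) = 0 and is rejected.
    """
    n = onto.n_terms
    if n < 2:
        raise OntologyStructureError(
            "information content is undefined for a single-term ontology (log N = 0)"
        )
    log_n = math.log(n)
    out = {}
    for term, hypo in hyponym_counts(onto).items():
        out[term] = TermIC(term=term, hypo=hypo, ic=1.0 - math.log(hypo + 1) / log_n)
    return out


def ancestors(onto: Ontology, term: str) -> set[str]:
    """Transitive parent closure of *term*, including the term itself."""
    onto._check(term)
    return nx.descendants(onto.graph, term) | {term}


def mica(
    onto: Ontology, ic: Mapping[str, TermIC], t1: str, t2: str
) -> tuple[str, float]:
    """Most informative common ancestor of two terms and its IC.

    Ties on IC are broken by term id for reproducibility; only the IC value is
    consumed downstream.
    """
    common = ancestors(onto, t1) & ancestors(onto, t2)
    best = max(common, key=lambda t: (ic[t].ic, t))
    return best, ic[best].ic


def write_ic_table(ic: Mapping[str, TermIC], path: str | Path) -> None:
    """Export ``term<TAB>hypo<TAB>ic`` with IC printed to 6 decimals."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\thypo\tic\n")
        for term in sorted(ic):
            rec = ic[term]
            fh.write(f"{rec.term}\t{rec.hypo}\t{rec.ic:.6f}\n")
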