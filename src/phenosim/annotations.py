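"""Drug side-effect and disease symptom annotations and their term weights.

Each annotation table maps entities (drugs or diseases) to sets of ontology
terms. Two per-term weights temper the influence of frequent and redundant
terms when term pairs are scored:

* frequency weight ``f(t) = -ln(n_t / M)`` where ``n_t`` is the number of
  entities annotated with term *t* and ``M`` the number of entities — a term
  carried by every entity is worthless (f = 0);
* co-occurrence weight ``c(t)`` = mean of ``-ln J(A_t, A_u)`` over the other
  terms *u* whose entity sets overlap ``A_t`` (Jaccard index J > 0) — terms
  that always travel together are down-weighted.

Weights are computed within a table's own kind: side-effect terms against the
drug universe, symptom terms against the disease universe.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .ontology import Ontology

__all__ = [
    "AnnotationTable",
    "TermWeights",
    "AnnotationError",
    "load_annotations",
    "jaccard",
    "frequency_weights",
    "cooccurrence_weights",
    "combined_weights",
    "write_weight_table",
]

log = logging.getLogger(__name__)


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class TermWeights:
    term: str
    f: float
    c: float

    @property
    def combined(self) -> float:
        return self.f * self.c


class AnnotationTable:
    """Entity -> term-set map for one side (drugs or diseases) of the analysis."""

    def __init__(self, kind: str, annot: Mapping[str, set[str]]):
        if kind not in ("drug", "disease"):
            raise ValueError(f"kind must be 'drug' or 'disease', got {kind!r}")
        if not annot:
            raise AnnotationError("no annotations")
        for ent, terms in annot.items():
            if not terms:
                raise AnnotationError(f"entity {ent!r} has no terms")
        self.kind = kind
        self.annot: dict[str, set[str]] = {e: set(t) for e, t in annot.items()}
        # entity sets per term: A_t = entities annotated with t
        self._by_term: dict[str, set[str]] = {}
        for ent, terms in self.annot.items():
            for t in terms:
                self._by_term.setdefault(t, set()).add(ent)
        self._weights: dict[str, TermWeights] | None = None

    @property
    def entities(self) -> set[str]:
        return set(self.annot)

    @property
    def M(self) -> int:
        return len(self.annot)

    @property
    def terms(self) -> set[str]:
        return set(self._by_term)

    def entities_with(self, term: str) -> set[str]:
        """The set of entities a term is annotated to (A in the Jaccard index)."""
        return set(self._by_term.get(term, set()))

    def weights(self) -> dict[str, TermWeights]:
        """Combined per-term weights, computed once and cached."""
        if self._weights is None:
            f = frequency_weights(self)
            c = cooccurrence_weights(self)
            self._weights = {
                t: TermWeights(term=t, f=f[t], c=c[t]) for t in self._by_term
            }
        return self._weights


def load_annotations(
    path: str | Path, kind: str, ontology: Ontology | None = None
) -> AnnotationTable:
    """Read an ``entity_id<TAB>term_id`` TSV (header required) into a table.

    Duplicate rows collapse; rows with terms missing from *ontology* raise a
    validation error listing the offending rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise AnnotationError(f"{path}: expected columns entity_id, term_id")
    df = df.iloc[:, :2]
    df.columns = ["entity_id", "term_id"]
    df = df.dropna().drop_duplicates()
    if df.empty:
        raise AnnotationError(f"{path}: no annotations")
    if ontology is not None:
        bad = df[~df["term_id"].isin(ontology.terms)]
        if not bad.empty:
            rows = ", ".join(
                f"({r.entity_id}, {r.term_id})" for r in bad.head(10).itertuples()
            )
            raise AnnotationError(
                f"{path}: {len(bad)} rows reference terms absent from the ontology: {rows}"
            )
    annot = {e: set(g["term_id"]) for e, g in df.groupby("entity_id")}
    dropped = [e for e, terms in annot.items() if not terms]
    for e in dropped:
        log.warning("entity %s has no valid terms; dropped", e)
        del annot[e]
    return AnnotationTable(kind=kind, annot=annot)


def jaccard(a: set, b: set) -> float:
    """|A ∩ B| / |A ∪ B|; undefined (error) when both sets are empty."""
    union = len(a | b)
    if union == 0:
        raise ValueError("Jaccard index undefined for two empty sets")
    return len(a & b) / union


def frequency_weights(tab: AnnotationTable) -> dict[str, float]:
    """f(t) = -ln(n_t / M); finite because every stored term has n_t >= 1."""
    m = tab.M
    return {t: -math.log(len(ents) / m) for t, ents in tab._by_term.items()}


def cooccurrence_weights(tab: AnnotationTable) -> dict[str, float]:
    """Mean -ln J(A_t, A_u) over partner terms u != t with positive Jaccard.

    Zero-Jaccard partners are excluded (-ln 0 diverges) and so are self
    pairs (J = 1 contributes nothing but shrinks the mean). A term sharing no
    entity with any partner falls back to the maximum computed weight, the
    harshest observed redundancy penalty inverted: such a term is maximally
    non-redundant, and the fallback keeps it competitive without an infinity.
    """
    terms = sorted(tab._by_term)
    if len(terms) < 2:
        raise AnnotationError(
            "co-occurrence weights need at least two distinct terms"
        )
    c: dict[str, float] = {}
    orphans: list[str] = []
    for t in terms:
        a = tab._by_term[t]
        vals = []
        for u in terms:
            if u == t:
                continue
            j = jaccard(a, tab._by_term[u])
            if j > 0.0:
                vals.append(-math.log(j))
        if vals:
            c[t] = sum(vals) / len(vals)
        else:
            orphans.append(t)
    fallback = max(c.values()) if c else 0.0
    for t in orphans:
        c[t] = fallback
    return c


def combined_weights(tab: AnnotationTable) -> dict[str, float]:
    """f·c per term, the overall weight entering the term-pair score."""
    return {t: w.combined for t, w in tab.weights().items()}


def write_weight_table(tab: AnnotationTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tf\tc\n")
        for t in sorted(tab.terms):
            w = tab.weights()[t]
            fh.write(f"{t}\t{w.f:.6f}\t{w.c:.6f}\n")
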