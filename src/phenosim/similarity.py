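"""Weighted best-match semantic similarity between drug and disease profiles.

A drug is a bag of side-effect terms, a disease a bag of symptom terms, both
drawn from one phenotype ontology. A side effect / symptom pair is scored by

    s(adr, sym) = IC(MICA(adr, sym)) * min(f_adr * c_adr, f_sym * c_sym)

— the specificity of the deepest shared ancestor, damped by the *less*
informative of the two term weights so that only phenotypes specific on both
sides score highly. The drug-disease similarity is the best-match average:
every side effect is matched to its best-scoring symptom and vice versa, and
the best-match scores are summed and divided by n + m (the two profile
sizes). The normalization removes the advantage of profusely annotated
entities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotations import AnnotationTable
from .ontology import Ontology, TermIC, mica

__all__ = [
    "TermPairScore",
    "ScoredPair",
    "TermPairScorer",
    "term_pair_score",
    "best_matches",
    "pair_similarity",
    "score_all_pairs",
    "write_scores",
]


@dataclass(frozen=True)
class TermPairScore:
    adr: str
    symptom: str
    s: float


@dataclass(frozen=True)
class ScoredPair:
    drug: str
    disease: str
    similarity: float
    n: int  # side-effect count
    m: int  # symptom count


class TermPairScorer:
    """Memoized side-effect x symptom scorer.

    Term weights do not depend on which profiles the terms appear in, so a
    pair score computed once serves every drug-disease combination. Ancestor
    sets are cached per term as frozensets for fast MICA intersection.
    """

    def __init__(
        self,
        onto: Ontology,
        ic: Mapping[str, TermIC],
        drug_weights: Mapping[str, float],
        disease_weights: Mapping[str, float],
    ):
        self.onto = onto
        self.ic = ic
        self.wdrug = drug_weights
        self.wdis = disease_weights
        self._anc: dict[str, frozenset[str]] = {}
        self._cache: dict[tuple[str, str], float] = {}

    def _ancestors(self, term: str) -> frozenset[str]:
        a = self._anc.get(term)
        if a is None:
            from .ontology import ancestors

            a = frozenset(ancestors(self.onto, term))
            self._anc[term] = a
        return a

    def score(self, adr: str, symptom: str) -> float:
        key = (adr, symptom)
        s = self._cache.get(key)
        if s is not None:
            return s
        if adr not in self.wdrug:
            raise KeyError(f"no drug-side weight for term {adr!r}")
        if symptom not in self.wdis:
            raise KeyError(f"no disease-side weight for term {symptom!r}")
        common = self._ancestors(adr) & self._ancestors(symptom)
        mica_ic = max(self.ic[t].ic for t in common)
        s = mica_ic * min(self.wdrug[adr], self.wdis[symptom])
        self._cache[key] = s
        return s

    def matrix(self, adrs: list[str], symptoms: list[str]) -> np.ndarray:
        """Dense score matrix, rows = side effects, columns = symptoms."""
        out = np.empty((len(adrs), len(symptoms)))
        for i, a in enumerate(adrs):
            for j, s in enumerate(symptoms):
                out[i, j] = self.score(a, s)
        return out


def term_pair_score(
    adr: str,
    symptom: str,
    onto: Ontology,
    ic: Mapping[str, TermIC],
    drug_weights: Mapping[str, float],
    disease_weights: Mapping[str, float],
) -> TermPairScore:
    """Score a single side effect / symptom pair (convenience wrapper)."""
    if adr not in drug_weights:
        raise KeyError(f"no drug-side weight for term {adr!r}")
    if symptom not in disease_weights:
        raise KeyError(f"no disease-side weight for term {symptom!r}")
    _, mica_ic = mica(onto, ic, adr, symptom)
    s = mica_ic * min(drug_weights[adr], disease_weights[symptom])
    return TermPairScore(adr=adr, symptom=symptom, s=s)


def best_matches(
    drug_profile: list[str],
    disease_profile: list[str],
    scorer: TermPairScorer,
) -> tuple[np.ndarray, np.ndarray]:
    """Best-scoring partner for every side effect and every symptom.

    Returns (per-side-effect maxima, per-symptom maxima); tie partners are
    irrelevant because only the max score is consumed downstream.
    """
    if not drug_profile or not disease_profile:
        raise ValueError("best_matches requires two nonempty profiles")
    s = scorer.matrix(list(drug_profile), list(disease_profile))
    return s.max(axis=1), s.max(axis=0)


def pair_similarity(
    drug: str,
    disease: str,
    drugs: AnnotationTable,
    diseases: AnnotationTable,
    scorer: TermPairScorer,
) -> ScoredPair:
    """Best-match-average similarity for one drug-disease pair."""
    if drug not in drugs.annot:
        raise KeyError(f"drug {drug!r} has no annotations")
    if disease not in diseases.annot:
        raise KeyError(f"disease {disease!r} has no annotations")
    adrs = sorted(drugs.annot[drug])
    syms = sorted(diseases.annot[disease])
    best_adr, best_sym = best_matches(adrs, syms, scorer)
    sim = (best_adr.sum() + best_sym.sum()) / (len(adrs) + len(syms))
    return ScoredPair(
        drug=drug, disease=disease, similarity=float(sim), n=len(adrs), m=len(syms)
    )


def score_all_pairs(
    drugs: AnnotationTable,
    diseases: AnnotationTable,
    onto: Ontology,
    ic: Mapping[str, TermIC],
) -> pd.DataFrame:
    """Score every drug x disease combination and rank by similarity.

    Returns a DataFrame with columns drug_id, disease_id, similarity, n, m —
    exactly |drugs| x |diseases| rows, sorted by descending similarity with
    (drug_id, disease_id) lexicographic tie-breaking so output is identical
    across runs and input orderings.
    """
    scorer = TermPairScorer(onto, ic, _combined(drugs), _combined(diseases))
    # Precompute the score matrix over the distinct term vocabularies once;
    # per-pair work is then a submatrix max.
    drug_terms = sorted({t for ts in drugs.annot.values() for t in ts})
    dis_terms = sorted({t for ts in diseases.annot.values() for t in ts})
    s_full = scorer.matrix(drug_terms, dis_terms)
    d_idx = {t: i for i, t in enumerate(drug_terms)}
    s_idx = {t: i for i, t in enumerate(dis_terms)}
    drug_rows = {
        d: np.fromiter((d_idx[t] for t in sorted(ts)), dtype=np.intp)
        for d, ts in drugs.annot.items()
    }
    dis_cols = {
        d: np.fromiter((s_idx[t] for t in sorted(ts)), dtype=np.intp)
        for d, ts in diseases.annot.items()
    }
    records = []
    for drug in sorted(drugs.annot):
        rows = drug_rows[drug]
        sub_rows = s_full[rows, :]
        for disease in sorted(diseases.annot):
            cols = dis_cols[disease]
            block = sub_rows[:, cols]
            n, m = block.shape
            sim = (block.max(axis=1).sum() + block.max(axis=0).sum()) / (n + m)
            records.append((drug, disease, float(sim), n, m))
    df = pd.DataFrame(
        records, columns=["drug_id", "disease_id", "similarity", "n", "m"]
    )
    df = df.sort_values(
        ["similarity", "drug_id", "disease_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df


def pair_universe(drugs: AnnotationTable, diseases: AnnotationTable) -> int:
    """Number of drug x disease combinations the all-pairs scoring enumerates.

    Only annotated entities enter the universe (both tables drop entities
    without terms at load time), so this is exactly the row count of
    :func:`score_all_pairs`.
    """
    return drugs.M * diseases.M


def _combined(tab: AnnotationTable) -> dict[str, float]:
    return {t: w.combined for t, w in tab.weights().items()}


def write_scores(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["similarity"] = out["similarity"].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)
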