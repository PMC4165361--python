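"""Lift-curve benchmarking of the similarity ranking against known relations.

Pairs are sorted by decreasing phenotypic similarity. For a rate of positive
prediction r, the top ceil(r * total) pairs are taken as predictions — along
with every pair tied at the cutoff score — and the lift is

    lift(r) = precision(r) / prevalence = (TP / top) / (P / total)

so a random ordering has expected lift 1 at every rate. Lift curves are
computed per clinical relation type (indication, contraindication,
clinical trial, ADR-disease) and, within a relation, per molecular distance
category. The module also selects the network score threshold by Pareto
optimization of distance-{0,1} enrichment and precision over molecularly
covered pairs, compares similarity distributions between relation types with
rank-sum tests, and extracts candidate contraindications (top-ranked
ADR-disease pairs not yet contraindicated).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .molecular import CATEGORIES

__all__ = [
    "RELATIONS",
    "RelationLabels",
    "LiftCurve",
    "ParetoPoint",
    "load_labels",
    "lift_curve",
    "lift_by_relation",
    "lift_by_distance_within_relation",
    "pareto_threshold",
    "compare_relation_scores",
    "adr_fraction_curve",
    "candidate_contraindications",
    "plot_lift_curves",
    "write_lift_curves",
]

log = logging.getLogger(__name__)

RELATIONS = ("indication", "contraindication", "clinical_trial", "adr_disease")

DEFAULT_RATES = (0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0)

#: below this many positives a curve is flagged as statistically fragile
LOW_N = 5


@dataclass(frozen=True)
class RelationLabels:
    relation: str
    pairs: frozenset[tuple[str, str]]


@dataclass
class LiftCurve:
    rates: list[float]
    lifts: list[float]
    positives_total: int
    negatives_total: int
    top_sizes: list[int] = field(default_factory=list)
    true_positives: list[int] = field(default_factory=list)
    low_n: bool = False

    def at(self, rate: float) -> float:
        return self.lifts[self.rates.index(rate)]


@dataclass(frozen=True)
class ParetoPoint:
    threshold: float
    lift01: float
    precision01: float
    recall01: float = 1.0


def load_labels(path: str | Path) -> dict[str, RelationLabels]:
    """Read ``drug_id<TAB>disease_id<TAB>relation`` into per-relation pair sets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"drug_id", "disease_id", "relation"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    out = {}
    for rel, g in df.groupby("relation"):
        pairs = frozenset(zip(g["drug_id"], g["disease_id"]))
        out[str(rel)] = RelationLabels(relation=str(rel), pairs=pairs)
    return out


def _ranked_arrays(
    scored: pd.DataFrame,
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    sims = scored["similarity"].to_numpy()
    if np.any(np.diff(sims) > 1e-12):
        raise ValueError("scored table must be sorted by decreasing similarity")
    pairs = list(zip(scored["drug_id"], scored["disease_id"]))
    return sims, pairs


def _top_size(sims: np.ndarray, rate: float) -> int:
    """Pairs in the top slice at *rate*, extended over ties at the cutoff score."""
    total = len(sims)
    k = max(1, math.ceil(rate * total))
    cutoff = sims[k - 1]
    # include every pair with equal or higher score than the cutoff
    return int(np.searchsorted(-sims, -cutoff, side="right"))


def lift_curve(
    scored: pd.DataFrame,
    positives: Iterable[tuple[str, str]],
    rates: Sequence[float] = DEFAULT_RATES,
) -> LiftCurve:
    """Enrichment of *positives* in the top slice of the ranked list per rate."""
    positives = set(positives)
    if not positives:
        raise ValueError("empty positive set")
    for r in rates:
        if not (0.0 < r <= 1.0):
            raise ValueError(f"rate {r} outside (0, 1]")
    sims, pairs = _ranked_arrays(scored)
    universe = set(pairs)
    stray = positives - universe
    if stray:
        raise ValueError(
            f"{len(stray)} positive pairs are absent from the scored universe, "
            f"e.g. {sorted(stray)[:3]}"
        )
    total = len(pairs)
    p = len(positives)
    is_pos = np.fromiter((pr in positives for pr in pairs), dtype=bool, count=total)
    cum_tp = np.cumsum(is_pos)
    prevalence = p / total
    lifts, tops, tps = [], [], []
    for r in rates:
        top = _top_size(sims, r)
        tp = int(cum_tp[top - 1])
        lifts.append((tp / top) / prevalence)
        tops.append(top)
        tps.append(tp)
    return LiftCurve(
        rates=list(rates),
        lifts=lifts,
        positives_total=p,
        negatives_total=total - p,
        top_sizes=tops,
        true_positives=tps,
        low_n=p < LOW_N,
    )


def lift_by_relation(
    scored: pd.DataFrame,
    labels: Mapping[str, RelationLabels],
    rates: Sequence[float] = DEFAULT_RATES,
) -> dict[str, LiftCurve]:
    """One lift curve per relation plus a pooled ``all`` curve (union of pairs)."""
    universe = set(zip(scored["drug_id"], scored["disease_id"]))
    out: dict[str, LiftCurve] = {}
    pooled: set[tuple[str, str]] = set()
    for rel, lab in labels.items():
        pairs = set(lab.pairs) & universe
        if not pairs:
            log.warning("relation %s has no labeled pairs in the universe; skipped", rel)
            continue
        out[rel] = lift_curve(scored, pairs, rates)
        pooled |= pairs
    if pooled:
        out["all"] = lift_curve(scored, pooled, rates)
    return out


def lift_by_distance_within_relation(
    scored: pd.DataFrame,
    labels: Mapping[str, RelationLabels],
    molecular: pd.DataFrame,
    rates: Sequence[float] = DEFAULT_RATES,
) -> dict[str, dict[str, LiftCurve]]:
    """Within each relation, lift curves of the labeled pairs per distance bin.

    Returns {relation: {category: LiftCurve}}; empty categories are skipped
    and curves with fewer than 5 positives carry ``low_n=True``.
    """
    cat_of = {
        (d, s): c
        for d, s, c in zip(
            molecular["drug_id"], molecular["disease_id"], molecular["category"]
        )
    }
    universe = set(zip(scored["drug_id"], scored["disease_id"]))
    out: dict[str, dict[str, LiftCurve]] = {}
    for rel, lab in labels.items():
        by_cat: dict[str, set] = {c: set() for c in CATEGORIES}
        for pair in lab.pairs:
            if pair in universe and pair in cat_of:
                by_cat[cat_of[pair]].add(pair)
        rel_curves = {}
        for cat in CATEGORIES:
            if not by_cat[cat]:
                continue
            rel_curves[cat] = lift_curve(scored, by_cat[cat], rates)
        if rel_curves:
            out[rel] = rel_curves
    return out


def pareto_threshold(
    scored: pd.DataFrame,
    molecular: pd.DataFrame,
    selector: str = "max_product",
    max_grid: int = 500,
    min_support: int = 10,
) -> tuple[ParetoPoint, list[ParetoPoint]]:
    """Select the network score threshold on the (lift01, precision01) front.

    All quantities are evaluated over the molecularly covered pairs only: at
    each candidate threshold t, ``precision01`` is the fraction of covered
    pairs scoring >= t whose targets and genes lie at PPI distance 0 or 1,
    ``lift01`` is that precision divided by the overall distance-{0,1}
    prevalence, and ``recall01`` is the fraction of all distance-{0,1} pairs
    retained. Candidate thresholds are the distinct observed scores
    (down-sampled to a quantile grid above *max_grid*); thresholds retaining
    fewer than *min_support* distance-{0,1} pairs are excluded so one lucky
    top pair cannot post a precision of 1. Returns the selected
    point and the non-dominated front, ordered by increasing threshold.

    Enrichment over random is precision divided by a constant prevalence, so
    lift01 and precision01 rise and fall together and cannot trade off
    against each other; the genuine tension is between the quality of the
    retained set and how much of the molecular signal it keeps. Dominance is
    therefore assessed on (precision01, recall01); lift01 is reported for
    every point. The ``knee`` selector picks the front point farthest from
    the line joining the front's extremes; ``max_product`` (default)
    maximizes the product of min-max-normalized objectives.
    """
    cat_of = {
        (d, s): c
        for d, s, c in zip(
            molecular["drug_id"], molecular["disease_id"], molecular["category"]
        )
    }
    sub = scored[
        [p in cat_of for p in zip(scored["drug_id"], scored["disease_id"])]
    ]
    if sub.empty:
        raise ValueError("no scored pair has molecular coverage")
    sims = sub["similarity"].to_numpy()
    is01 = np.fromiter(
        (
            cat_of[p] in ("0", "1")
            for p in zip(sub["drug_id"], sub["disease_id"])
        ),
        dtype=bool,
        count=len(sub),
    )
    order = np.argsort(-sims, kind="mergesort")
    sims = sims[order]
    is01 = is01[order]
    total = len(sims)
    p01 = int(is01.sum())
    if p01 == 0:
        raise ValueError("no molecularly covered pair has distance 0 or 1")
    prevalence = p01 / total
    cum_tp = np.cumsum(is01)
    # candidate thresholds: last index of each distinct score (ties included)
    last_of_score = np.nonzero(np.r_[sims[1:] != sims[:-1], True])[0]
    supported = last_of_score[cum_tp[last_of_score] >= min(min_support, p01)]
    if len(supported) >= 2:
        last_of_score = supported
    if len(last_of_score) > max_grid:
        qs = np.linspace(0, len(last_of_score) - 1, max_grid).round().astype(int)
        last_of_score = np.unique(last_of_score[qs])
    points = []
    for idx in last_of_score:
        prec = cum_tp[idx] / (idx + 1)
        points.append(
            ParetoPoint(
                threshold=float(sims[idx]),
                lift01=float(prec / prevalence),
                precision01=float(prec),
                recall01=float(cum_tp[idx] / p01),
            )
        )
    if len({(pt.precision01, pt.recall01) for pt in points}) == 1:
        log.warning("objectives constant across thresholds; returning highest")
        top = max(points, key=lambda pt: pt.threshold)
        return top, [top]
    front = pareto_front(points, objectives=("precision01", "recall01"))
    selected = _select_point(front, selector)
    return selected, front


def pareto_front(
    points: Sequence[ParetoPoint],
    objectives: tuple[str, str] = ("lift01", "precision01"),
) -> list[ParetoPoint]:
    """Non-dominated subset under joint maximization of two objectives.

    A point dominates another when it is >= in both objectives and > in at
    least one. Duplicate-objective points keep the lowest threshold.
    """
    ox, oy = objectives
    front = []
    for pt in points:
        px, py = getattr(pt, ox), getattr(pt, oy)
        dominated = any(
            (getattr(q, ox) >= px and getattr(q, oy) >= py)
            and (getattr(q, ox) > px or getattr(q, oy) > py)
            for q in points
        )
        if not dominated:
            front.append(pt)
    # collapse objective ties onto the most inclusive threshold
    best: dict[tuple[float, float], ParetoPoint] = {}
    for pt in front:
        key = (getattr(pt, ox), getattr(pt, oy))
        if key not in best or pt.threshold < best[key].threshold:
            best[key] = pt
    return sorted(best.values(), key=lambda pt: pt.threshold)


def _select_point(front: list[ParetoPoint], selector: str) -> ParetoPoint:
    if len(front) == 1:
        return front[0]
    xs = np.array([pt.precision01 for pt in front])
    ys = np.array([pt.recall01 for pt in front])

    def norm(v):
        rng = v.max() - v.min()
        return (v - v.min()) / rng if rng > 0 else np.ones_like(v)

    if selector == "max_product":
        score = norm(xs) * norm(ys)
        return front[int(np.argmax(score))]
    if selector == "knee":
        nx_, ny = norm(xs), norm(ys)
        x0, y0, x1, y1 = nx_[0], ny[0], nx_[-1], ny[-1]
        denom = math.hypot(x1 - x0, y1 - y0)
        if denom == 0:
            return front[0]
        d = np.abs((y1 - y0) * nx_ - (x1 - x0) * ny + x1 * y0 - y1 * x0) / denom
        return front[int(np.argmax(d))]
    raise ValueError(f"unknown selector {selector!r}")


def compare_relation_scores(
    scored: pd.DataFrame, labels: Mapping[str, RelationLabels]
) -> pd.DataFrame:
    """Pairwise rank-sum tests between relation similarity distributions.

    Two-sided Wilcoxon rank-sum (Mann-Whitney U) on the similarity values of
    each relation's labeled pairs, exact for group sizes <= 50 and normal
    approximation above, with Benjamini-Hochberg adjustment across all tested
    relation pairs. Direction is the difference of medians (first minus
    second relation).
    """
    sim_of = {
        (d, s): v
        for d, s, v in zip(
            scored["drug_id"], scored["disease_id"], scored["similarity"]
        )
    }
    groups = {}
    for rel, lab in labels.items():
        vals = np.array([sim_of[p] for p in lab.pairs if p in sim_of])
        if len(vals) < 2:
            log.warning("relation %s has <2 scored pairs; skipped", rel)
            continue
        groups[rel] = vals
    rels = sorted(groups)
    if len(rels) < 2:
        raise ValueError("need at least two relations with >=2 scored pairs")
    rows = []
    for i, a in enumerate(rels):
        for b in rels[i + 1:]:
            x, y = groups[a], groups[b]
            method = "exact" if max(len(x), len(y)) <= 50 else "asymptotic"
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            rows.append(
                {
                    "relation_a": a,
                    "relation_b": b,
                    "n_a": len(x),
                    "n_b": len(y),
                    "statistic": float(res.statistic),
                    "p_value": float(res.pvalue),
                    "median_diff": float(np.median(x) - np.median(y)),
                }
            )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def adr_fraction_curve(
    scored: pd.DataFrame,
    labels: Mapping[str, RelationLabels],
    relation: str = "contraindication",
    rates: Sequence[float] = DEFAULT_RATES,
) -> pd.DataFrame:
    """Fraction of a relation's top-ranked pairs that are also ADR-disease pairs.

    The relation's labeled pairs are ranked by similarity; for each rate the
    fraction of the top slice carrying an ADR-disease label is reported.
    """
    if "adr_disease" not in labels:
        raise ValueError("adr_disease labels are required")
    adr = set(labels["adr_disease"].pairs)
    rel_pairs = set(labels[relation].pairs)
    sims, pairs = _ranked_arrays(scored)
    ranked_rel = [(v, p) for v, p in zip(sims, pairs) if p in rel_pairs]
    if not ranked_rel:
        return pd.DataFrame({"rate": list(rates), "fraction": [0.0] * len(rates)})
    rel_sims = np.array([v for v, _ in ranked_rel])
    is_adr = np.array([p in adr for _, p in ranked_rel])
    cum = np.cumsum(is_adr)
    rows = []
    for r in rates:
        top = _top_size(rel_sims, r)
        rows.append({"rate": r, "fraction": float(cum[top - 1] / top)})
    return pd.DataFrame(rows)


def write_lift_curves(curves: Mapping[str, LiftCurve], path: str | Path) -> None:
    """Export a set of named lift curves as a long-format TSV."""
    rows = []
    for name, c in curves.items():
        for r, l, top, tp in zip(c.rates, c.lifts, c.top_sizes, c.true_positives):
            rows.append(
                {
                    "curve": name,
                    "rate": r,
                    "lift": l,
                    "top_size": top,
                    "true_positives": tp,
                    "positives_total": c.positives_total,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def plot_lift_curves(
    curves: Mapping[str, LiftCurve], path: str | Path, title: str = "Lift"
) -> None:
    """Render lift vs rate-of-positive-prediction to SVG (one line per curve)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name in sorted(curves):
        c = curves[name]
        ax.plot(c.rates, c.lifts, marker="o", label=name)
    ax.axhline(1.0, color="black", linestyle="--", linewidth=0.8)
    ax.set_xlabel("rate of positive prediction")
    ax.set_ylabel("lift")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def candidate_contraindications(
    scored: pd.DataFrame,
    labels: Mapping[str, RelationLabels],
    top_fraction: float = 0.02,
) -> tuple[pd.DataFrame, float]:
    """ADR-disease pairs in the top slice not yet labeled as contraindications.

    Returns the candidate table (sorted like the input ranking) and the score
    cutoff that defines the top slice (ties at the cutoff are included).
    """
    if "adr_disease" not in labels:
        raise ValueError("adr_disease labels are required")
    adr = set(labels["adr_disease"].pairs)
    contra = set(labels.get("contraindication", RelationLabels("contraindication", frozenset())).pairs)
    sims, pairs = _ranked_arrays(scored)
    top = _top_size(sims, top_fraction)
    cutoff = float(sims[top - 1])
    rows = [
        {"drug_id": p[0], "disease_id": p[1], "similarity": float(v)}
        for v, p in zip(sims[:top], pairs[:top])
        if p in adr and p not in contra
    ]
    return pd.DataFrame(rows, columns=["drug_id", "disease_id", "similarity"]), cutoff
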