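"""Synthetic worlds for the phenotypic similarity pipeline.

Real MedDRA/UMLS-derived side-effect and symptom annotations are licensed,
so end-to-end behaviour is exercised on generated data that reproduces the
statistical structure the analysis assumes:

* a four-level, multi-parent phenotype DAG (mimicking the SOC > HLGT > HLT >
  PT hierarchy) with one subtree attached only at the root plus a handful of
  bridge edges into other subtrees (mimicking an isolated organ class and
  cross-hierarchy SMQ groupings);
* sparse entity-term annotations over leaf terms with Zipf-distributed term
  popularity (heavy-tailed frequency weights) and a per-entity home subtree
  (correlated co-occurring terms);
* a random PPI graph with drug target and disease gene sets;
* a molecular-phenotypic coupling: diseases close to a drug in the PPI
  network redraw their symptoms from the subtrees housing that drug's side
  effects, with probability decaying over the distance category — this
  plants the signal that molecularly related pairs look phenotypically
  similar, strongest at distance 0;
* clinical relation labels sampled at per-category rates: ADR-disease and
  contraindication labels are concentrated on molecularly close pairs while
  indication and clinical-trial labels are distance-independent.

Identical config and seed give byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .annotations import AnnotationTable
from .molecular import PPINetwork, molecular_links
from .ontology import Ontology

import networkx as nx

__all__ = ["GeneratorConfig", "World", "generate_ontology", "generate_world", "write_world"]

#: probability multiplier for the phenotype coupling per distance category
DEFAULT_COUPLING_DECAY = {"0": 1.0, "1": 0.5, "2": 0.15, "3": 0.05, ">3": 0.0}

#: per-relation, per-distance-category label probabilities
DEFAULT_LABEL_RATES = {
    "indication": {"0": 0.004, "1": 0.004, "2": 0.004, "3": 0.004, ">3": 0.004},
    "clinical_trial": {"0": 0.005, "1": 0.005, "2": 0.005, "3": 0.005, ">3": 0.005},
    "adr_disease": {"0": 0.35, "1": 0.20, "2": 0.02, "3": 0.005, ">3": 0.001},
    "contraindication": {"0": 0.25, "1": 0.12, "2": 0.01, "3": 0.002, ">3": 0.0005},
}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic world; defaults are the standard study conditions."""

    seed: int = 0
    # ontology
    depth: int = 4
    branching: tuple[int, int] = (2, 4)
    multi_parent_prob: float = 0.15
    cross_link_count: int = 5
    # annotations
    n_drugs: int = 200
    n_diseases: int = 300
    annot_size: tuple[int, int] = (4, 12)
    zipf_exponent: float = 1.0
    home_bias: float = 0.6
    # PPI
    ppi_nodes: int = 800
    ppi_edges: int = 1200
    proteins_per_entity: tuple[int, int] = (1, 2)
    # coupling and labels
    coupling_strength: float = 0.8
    mimic_prob: float = 0.6
    coupling_decay: dict = field(default_factory=lambda: dict(DEFAULT_COUPLING_DECAY))
    label_rates: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_LABEL_RATES)))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("branching", "annot_size", "proteins_per_entity"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        lo, hi = self.branching
        if not (1 <= lo <= hi):
            raise ValueError(f"infeasible branching range {self.branching}")
        for p in (self.multi_parent_prob, self.coupling_strength, self.home_bias):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        for count in (self.n_drugs, self.n_diseases, self.ppi_nodes, self.ppi_edges):
            if count <= 0:
                raise ValueError("all counts must be positive")


@dataclass
class World:
    """In-memory synthetic data set; ``write_world`` serializes it to TSVs."""

    config: GeneratorConfig
    ontology: Ontology
    drugs: AnnotationTable
    diseases: AnnotationTable
    ppi: PPINetwork
    targets: dict[str, set[str]]
    genes: dict[str, set[str]]
    labels: dict[str, set[tuple[str, str]]]
    disease_classes: dict[str, set[str]]
    drug_classes: dict[str, set[str]]
    coupled_pairs: set[tuple[str, str]]  # pairs whose coupling event fired
    term_subtree: dict[str, str]  # leaf term -> top-level subtree id


def generate_ontology(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[Ontology, dict[str, str]]:
    """Build the layered multi-parent DAG; returns (ontology, leaf->subtree map).

    Terms are named ``L<level>_<k>``; level-1 terms play the role of organ
    classes (subtrees). The first subtree is kept isolated: its terms never
    gain parents outside it, except for ``cross_link_count`` bridge edges
    added at the end.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    root = "ROOT"
    parent_edges: dict[str, set[str]] = {root: set()}
    levels: list[list[str]] = [[root]]
    subtree: dict[str, str] = {}
    counter = 0
    for lvl in range(1, cfg.depth + 1):
        layer: list[str] = []
        for parent in levels[lvl - 1]:
            k = int(rng.integers(cfg.branching[0], cfg.branching[1] + 1))
            for _ in range(k):
                term = f"L{lvl}_{counter:04d}"
                counter += 1
                parent_edges[term] = {parent}
                subtree[term] = term if lvl == 1 else subtree[parent]
                layer.append(term)
        if not layer:
            raise ValueError(f"infeasible branching: empty level {lvl}")
        levels.append(layer)
    socs = levels[1]
    isolated = socs[0]
    # extra parents within a level boundary, never in or out of the isolated subtree
    for lvl in range(2, cfg.depth + 1):
        for term in levels[lvl]:
            if subtree[term] == isolated:
                continue
            if rng.random() < cfg.multi_parent_prob:
                candidates = [
                    p
                    for p in levels[lvl - 1]
                    if p not in parent_edges[term] and subtree[p] != isolated
                ]
                if candidates:
                    extra = candidates[int(rng.integers(len(candidates)))]
                    parent_edges[term].add(extra)
    # SMQ-like bridges: terms of the isolated subtree gain one outside parent
    if cfg.depth >= 2:
        iso_terms = [
            t for lvl in range(2, cfg.depth + 1) for t in levels[lvl]
            if subtree[t] == isolated
        ]
        rng.shuffle(iso_terms)
        n_bridges = min(cfg.cross_link_count, len(iso_terms))
        for term in iso_terms[:n_bridges]:
            lvl = int(term.split("_")[0][1:])
            candidates = [p for p in levels[lvl - 1] if subtree.get(p, "") != isolated]
            if candidates:
                extra = candidates[int(rng.integers(len(candidates)))]
                parent_edges[term].add(extra)
    onto = Ontology(parent_edges)
    leaf_subtree = {t: subtree[t] for t in onto.leaves()}
    return onto, leaf_subtree


def _draw_profile(
    rng: np.random.Generator,
    size: int,
    leaves: np.ndarray,
    popularity: np.ndarray,
    home_leaves: np.ndarray | None,
    home_bias: float,
) -> set[str]:
    """Sample *size* distinct leaves, biased toward the entity's home subtree."""
    chosen: set[str] = set()
    if home_leaves is not None and len(home_leaves) > 0:
        n_home = int(round(home_bias * size))
        n_home = min(n_home, len(home_leaves))
        if n_home > 0:
            idx = [int(i) for i, t in enumerate(leaves) if t in set(home_leaves)]
            w = popularity[idx] / popularity[idx].sum()
            pick = rng.choice(len(idx), size=n_home, replace=False, p=w)
            chosen.update(leaves[idx[i]] for i in pick)
    remaining = size - len(chosen)
    while remaining > 0:
        w = popularity / popularity.sum()
        pick = rng.choice(len(leaves), size=min(remaining + len(chosen), len(leaves)), replace=False, p=w)
        for i in pick:
            chosen.add(leaves[i])
            if len(chosen) >= size:
                break
        remaining = size - len(chosen)
        if len(chosen) >= len(leaves):
            break
    return chosen


def generate_world(cfg: GeneratorConfig) -> World:
    """Generate ontology, annotations, PPI, coupling, classes and labels."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    onto, leaf_subtree = generate_ontology(cfg, rng)
    leaves = np.array(sorted(onto.leaves()))
    socs = sorted(set(leaf_subtree.values()))
    leaves_by_soc = {
        s: np.array([t for t in leaves if leaf_subtree[t] == s]) for s in socs
    }
    # Zipf-like popularity over a random permutation of the leaves
    ranks = rng.permutation(len(leaves)) + 1
    popularity = 1.0 / ranks.astype(float) ** cfg.zipf_exponent

    drug_ids = [f"DRUG_{i:04d}" for i in range(cfg.n_drugs)]
    disease_ids = [f"DIS_{i:04d}" for i in range(cfg.n_diseases)]

    def draw_entities(ids):
        annot = {}
        homes = {}
        for e in ids:
            home = socs[int(rng.integers(len(socs)))]
            homes[e] = home
            size = int(rng.integers(cfg.annot_size[0], cfg.annot_size[1] + 1))
            annot[e] = _draw_profile(
                rng, size, leaves, popularity, leaves_by_soc[home], cfg.home_bias
            )
        return annot, homes

    drug_annot, _ = draw_entities(drug_ids)
    dis_annot, _ = draw_entities(disease_ids)

    # PPI graph and protein attachments
    g = nx.gnm_random_graph(
        cfg.ppi_nodes, cfg.ppi_edges, seed=int(rng.integers(2**31 - 1))
    )
    g = nx.relabel_nodes(g, {i: f"P{i:05d}" for i in g.nodes})
    ppi = PPINetwork(graph=g)
    proteins = np.array(sorted(ppi.nodes))

    def draw_proteins(ids):
        out = {}
        for e in ids:
            k = int(rng.integers(cfg.proteins_per_entity[0], cfg.proteins_per_entity[1] + 1))
            pick = rng.choice(len(proteins), size=k, replace=False)
            out[e] = {str(proteins[i]) for i in pick}
        return out

    targets = draw_proteins(drug_ids)
    genes = draw_proteins(disease_ids)

    links = molecular_links(ppi, targets, genes)
    cat_of = {
        (d, s): c
        for d, s, c in zip(links["drug_id"], links["disease_id"], links["category"])
    }

    # molecular-phenotypic coupling: redraw symptoms of diseases close to drugs
    coupled_pairs: set[tuple[str, str]] = set()
    coupled_drugs_of: dict[str, list[str]] = {}
    for drug in drug_ids:
        for disease in disease_ids:
            cat = cat_of.get((drug, disease), ">3")
            p = cfg.coupling_strength * cfg.coupling_decay.get(cat, 0.0)
            if p > 0 and rng.random() < p:
                coupled_pairs.add((drug, disease))
                coupled_drugs_of.setdefault(disease, []).append(drug)
    # leaves sharing a parent with a given leaf (same most-specific grouping)
    sibling_leaves: dict[str, list[str]] = {}
    leaf_set = set(str(t) for t in leaves)
    for t in leaf_set:
        sibs = {
            str(c)
            for p in onto.parents(t)
            for c in onto.children(p)
            if c in leaf_set and c != t
        }
        sibling_leaves[t] = sorted(sibs)
    for disease in sorted(coupled_drugs_of):
        anchor = sorted(
            {str(t) for drug in coupled_drugs_of[disease] for t in drug_annot[drug]}
        )
        sibs = sorted(
            {s for t in anchor for s in sibling_leaves[t]} - set(anchor)
        )
        size = len(dis_annot[disease])
        new: set[str] = set()
        anchor_left = list(anchor)
        sibs_left = list(sibs)
        while len(new) < size and (anchor_left or sibs_left):
            take_anchor = anchor_left and (
                not sibs_left or rng.random() < cfg.mimic_prob
            )
            pool = anchor_left if take_anchor else sibs_left
            i = int(rng.integers(len(pool)))
            new.add(pool.pop(i))
        if len(new) < size:  # tiny profiles: pad from the drugs' subtrees
            pad_pool = sorted(
                set().union(
                    *[set(map(str, leaves_by_soc[leaf_subtree[t]])) for t in anchor]
                )
                - new
            )
            k = min(size - len(new), len(pad_pool))
            if k > 0:
                pick = rng.choice(len(pad_pool), size=k, replace=False)
                new.update(pad_pool[i] for i in pick)
        dis_annot[disease] = new

    # clinical labels per relation at distance-dependent rates
    labels: dict[str, set[tuple[str, str]]] = {r: set() for r in cfg.label_rates}
    for drug in drug_ids:
        for disease in disease_ids:
            cat = cat_of.get((drug, disease), ">3")
            for rel, rates in cfg.label_rates.items():
                if rng.random() < rates.get(cat, 0.0):
                    labels[rel].add((drug, disease))

    # classes: dominant subtree of the realized profile
    def dominant_classes(annot, prefix):
        out = {}
        for e, terms in annot.items():
            counts: dict[str, int] = {}
            for t in terms:
                counts[leaf_subtree[t]] = counts.get(leaf_subtree[t], 0) + 1
            top = max(counts.values())
            out[e] = {f"{prefix}_{s}" for s, k in counts.items() if k == top}
        return out

    drug_classes = dominant_classes(drug_annot, "ATC")
    disease_classes = dominant_classes(dis_annot, "MESH")

    return World(
        config=cfg,
        ontology=onto,
        drugs=AnnotationTable("drug", drug_annot),
        diseases=AnnotationTable("disease", dis_annot),
        ppi=ppi,
        targets=targets,
        genes=genes,
        labels=labels,
        disease_classes=disease_classes,
        drug_classes=drug_classes,
        coupled_pairs=coupled_pairs,
        term_subtree=leaf_subtree,
    )


def write_world(world: World, out_dir: str | Path) -> dict[str, Path]:
    """Serialize every component to the TSV dialects the loaders consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = out / "ontology.tsv"
    with open(p, "w", encoding="utf-8") as fh:
        fh.write("child\tparent\n")
        for child in sorted(world.ontology.terms):
            for parent in sorted(world.ontology.parents(child)):
                fh.write(f"{child}\t{parent}\n")
    paths["ontology"] = p

    for name, tab in (("drug_annotations", world.drugs), ("disease_annotations", world.diseases)):
        p = out / f"{name}.tsv"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("entity_id\tterm_id\n")
            for e in sorted(tab.annot):
                for t in sorted(tab.annot[e]):
                    fh.write(f"{e}\t{t}\n")
        paths[name] = p

    p = out / "ppi.tsv"
    with open(p, "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in world.ppi.graph.edges):
            fh.write(f"{a}\t{b}\n")
    paths["ppi"] = p

    for name, mapping in (("drug_targets", world.targets), ("disease_genes", world.genes)):
        p = out / f"{name}.tsv"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("entity_id\tprotein_id\n")
            for e in sorted(mapping):
                for prot in sorted(mapping[e]):
                    fh.write(f"{e}\t{prot}\n")
        paths[name] = p

    p = out / "labels.tsv"
    with open(p, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tdisease_id\trelation\n")
        for rel in sorted(world.labels):
            for d, s in sorted(world.labels[rel]):
                fh.write(f"{d}\t{s}\t{rel}\n")
    paths["labels"] = p

    for name, mapping in (
        ("disease_classes", world.disease_classes),
        ("drug_classes", world.drug_classes),
    ):
        p = out / f"{name}.tsv"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("entity_id\tclass_id\n")
            for e in sorted(mapping):
                for c in sorted(mapping[e]):
                    fh.write(f"{e}\t{c}\n")
        paths[name] = p

    p = out / "config.json"
    with open(p, "w", encoding="utf-8") as fh:
        cfg = asdict(world.config)
        json.dump(cfg, fh, indent=2, sort_keys=True, default=list)
        fh.write("\n")
    paths["config"] = p
    return paths
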