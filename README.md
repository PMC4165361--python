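# phenosim

Phenotypic similarity between drugs and diseases, and what it reveals about
their molecular and clinical relationships.

Drugs perturb human physiology and so do diseases; when a drug's side-effect
profile resembles a disease's symptom profile, the two perturbations often
share machinery. `phenosim` implements an ontology-based pipeline around that
idea, aimed at computational drug-repositioning and pharmacovigilance work:

1. **Score** every drug–disease pair by a weighted best-match semantic
   similarity between side-effect and symptom annotations over a MedDRA-like
   phenotype ontology.
2. **Benchmark** the ranked pair list with lift curves against protein–protein
   interaction (PPI) shortest-path distances between drug targets and disease
   genes, and against clinical relation labels (indication, contraindication,
   clinical trial, ADR–disease).
3. **Analyze** the network of top-scoring pairs: Pareto-selected score
   threshold, greedy multi-level modularity communities, and Fisher-exact
   class enrichments (disease classes, drug classes, class combinations)
   under Benjamini–Hochberg control.
4. **Propose** candidate contraindications: top-ranked pairs where the
   disease is a known adverse reaction of the drug but not yet a listed
   contraindication.

Because real side-effect/symptom corpora derive from licensed vocabularies,
the package ships a first-class synthetic-data generator that reproduces the
statistical structure the analysis assumes (hierarchical multi-parent
ontology, heavy-tailed term usage, molecular–phenotypic coupling, clinical
labels concentrated on molecularly close pairs), so every stage is testable
end to end.

## The similarity measure

Each ontology term gets an information content from its hyponym (descendant)
count — structural rather than corpus-based, so unannotated corners of the
ontology are not penalized:

    IC(t) = 1 − log(hypo(t) + 1) / log(N)

with `N` the total number of terms: leaves score 1, the root 0. A side
effect *a* and a symptom *s* are compared through their most informative
common ancestor (MICA) and damped by per-term frequency and co-occurrence
weights `f·c` (rare, independently occurring terms count more):

    s(a, s) = IC(MICA(a, s)) · min(f_a·c_a, f_s·c_s)

where `f(t) = −ln(n_t / M)` and `c(t)` is the mean of `−ln J(A_t, A_u)` over
co-annotated partner terms (`J` = Jaccard index of entity sets). The
similarity of a drug with `n` side effects and a disease with `m` symptoms is
the best-match average

    similarity = ( Σ_i best_i + Σ_j best_j ) / (n + m),

summing each side effect's best-matching symptom score and vice versa.
Rankings are benchmarked with the lift: at a rate of positive prediction `r`,
`lift(r) = precision(top r) / prevalence`, which is 1 in expectation for a
random ordering.

## Worked example

```python
import phenosim as ps
from phenosim.molecular import molecular_links
from phenosim.benchmark import lift_by_relation, pareto_threshold, candidate_contraindications
from phenosim.network import build_network, detect_communities, community_class_enrichment

world = ps.generate_world(ps.GeneratorConfig(seed=1))
ic = ps.information_content(world.ontology)
scored = ps.score_all_pairs(world.drugs, world.diseases, world.ontology, ic)
links = molecular_links(world.ppi, world.targets, world.genes)
labels = {r: ps.RelationLabels(r, frozenset(p)) for r, p in world.labels.items()}

curves = lift_by_relation(scored, labels, rates=[0.01, 0.1, 1.0])
point, front = pareto_threshold(scored, links)
net = build_network(scored, point.threshold)
part = detect_communities(net, seed=0)
cand, cutoff = candidate_contraindications(scored, labels)
```

With the default study conditions (200 drugs, 300 diseases, coupling 0.8)
this prints:

```
ontology: 135 terms, 89 leaves
scored 60000 drug-disease pairs; top score 6.285
lift[indication] at 1%/10%/100%: 0.41/0.74/1.00
lift[clinical_trial] at 1%/10%/100%: 2.03/1.11/1.00
lift[adr_disease] at 1%/10%/100%: 5.73/2.07/1.00
lift[contraindication] at 1%/10%/100%: 5.33/1.33/1.00
lift[all] at 1%/10%/100%: 2.95/1.27/1.00
Pareto threshold 3.896 (precision01 0.091, recall01 0.127)
network: 858 edges, 153 drugs, 237 diseases, 19 communities (Q = 0.539)
significant (community, disease-class) cells at FDR<=0.01: 3
candidate contraindications in top 2% (score >= 3.789): 17
```

Reading the numbers: ADR–disease and contraindication labels — which the
generator concentrates on pairs whose targets and genes are close in the PPI
network — are strongly enriched at the top of the ranking (lift 5.7 and 5.3
in the top 1%), while indications, planted independently of molecular
distance, sit at or below the random-ordering baseline of 1. Every lift
curve ends at exactly 1.00 at rate 1 by construction. The thresholded
network splits into modularity communities that recover the organ-class
structure of the underlying annotations.

The same steps are available from the shell:

```
phenosim simulate --seed 1 --out world/
phenosim score --ontology world/ontology.tsv \
    --drug-annot world/drug_annotations.tsv \
    --disease-annot world/disease_annotations.tsv --out scores.tsv
phenosim distances --ppi world/ppi.tsv --targets world/drug_targets.tsv \
    --genes world/disease_genes.tsv --out links.tsv
phenosim candidates --scores scores.tsv --labels world/labels.tsv --out cand.tsv
```

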