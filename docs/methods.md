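# Methods

## Model

`phenosim` treats a drug and a disease as two bags of phenotype terms —
side effects and symptoms — drawn from one rooted, possibly multi-parent
ontology, and asks how similar the two perturbation profiles are.

**Term specificity.** Information content is structural:
`IC(t) = 1 − log(hypo(t)+1)/log(N)`, where `hypo(t)` counts the *distinct*
descendants of `t` (set semantics: a multi-parent descendant counts once)
and `N` is the total term count. This puts every leaf at IC 1 and the root
at IC 0 and is invariant to the logarithm base, being a ratio of logs. It
assumes the ontology's shape reflects specificity; it deliberately ignores
annotation frequencies so that sparsely annotated regions are not treated
as uninformative. A single-term ontology has no defined IC (log N = 0) and
is rejected.

**Term weights.** Within each annotation table (drugs with side effects,
diseases with symptoms) a term receives a frequency weight
`f(t) = −ln(n_t/M)` and a co-occurrence weight `c(t)`, the mean of
`−ln J(A_t, A_u)` over partner terms with positive Jaccard overlap of
entity sets. Two choices keep `c` finite and informative: zero-Jaccard
partners are excluded from the average (−ln 0 diverges), and so are self
pairs (they contribute a constant 0 and only shrink the mean). A term
sharing no entity with any partner — maximally non-redundant — falls back
to the maximum observed `c`. Natural logarithms throughout; the weights are
computed once per table and cached.

**Pair similarity.** A side effect and a symptom score
`IC(MICA) · min(f·c, f·c)` — the minimum couples the match to the side
where the phenotype is *less* specific, so a pair scores highly only when
the phenotype is informative for both the drug and the disease. The
drug–disease similarity is the best-match average: each side effect is
matched to its best symptom, each symptom to its best side effect, and the
matched scores are summed and divided by `n + m`. Term-pair scores are
profile-independent and are memoized over the term vocabulary, making the
all-pairs pass a submatrix-maximum per pair. Ranking ties break
lexicographically on (drug id, disease id) so output is platform- and
order-independent.

The `n + m` normalization removes the raw advantage of long profiles but
not all of it: a best match is a maximum over the partner profile, and
maxima over larger samples are stochastically larger. On i.i.d. synthetic
profiles the normalized score still rank-correlates with profile size
(ρ ≈ 0.5 at profile sizes 4–12 over a ~90-leaf vocabulary) — far below the
unnormalized sum (ρ ≈ 0.85), but not zero. Conclusions that hinge on exact
size-independence should be checked against profile-size-matched nulls.

## Molecular distance

Drug targets and disease genes are mapped onto an undirected, unweighted
PPI network; the pair distance is the minimum shortest-path length over all
(target, gene) combinations, computed by one multi-source BFS per drug.
Distances bin into five exhaustive categories 0, 1, 2, 3, ">3"; unreachable
pairs fall into ">3" rather than being dropped, so category totals always
partition the pair universe and lift denominators stay comparable.
Proteins absent from the network are ignored; an entity whose proteins are
all absent has no molecular information and raises an error.

## Lift benchmarking

Pairs are sorted by decreasing similarity. At a rate of positive prediction
`r`, the top `⌈r·total⌉` pairs are predictions, *extended over ties* at the
cutoff score (a threshold on the score, not a count). The lift is
`(TP/top)/(P/total)` — precision over prevalence — which makes the
random-ordering expectation exactly 1 at every rate and forces the curve to
1 at rate 1. Curves with fewer than 5 positives are flagged `low_n`.
Relation-type comparisons use two-sided Wilcoxon rank-sum tests (exact for
group sizes ≤ 50, normal approximation above) with Benjamini–Hochberg
adjustment across the relation pairs, reporting the difference of medians
as direction.

**Threshold selection.** The network score threshold is chosen on the
molecularly covered pairs by Pareto optimization. At each candidate
threshold the implementation reports `precision01` (fraction of retained
covered pairs at distance ≤ 1), `lift01` (that precision over the constant
distance-≤1 prevalence) and `recall01` (fraction of all distance-≤1 pairs
retained). Enrichment-over-random is precision divided by a constant, so
lift and precision rise and fall together and cannot form a trade-off; the
genuine tension is precision versus recall, and dominance is assessed on
(precision01, recall01). Candidate thresholds are the distinct observed
scores (quantile-thinned above 500), excluding thresholds retaining fewer
than 10 distance-≤1 pairs so that a single lucky top pair cannot post a
precision of 1 and distort the min–max normalization. The default selector
maximizes the product of min–max-normalized objectives; a knee selector
(farthest front point from the extreme-to-extreme chord) is available.
Objective ties resolve toward the lowest threshold — the most inclusive
network.

**Candidate contraindications** are the pairs in the top fraction of the
ranking (default 2%, ties included) that carry an ADR–disease label but no
contraindication label; the defining score cutoff is reported alongside.

## Network analysis

Pairs at or above the threshold form a bipartite network (nodes namespaced
`drug:`/`disease:`). Communities come from an in-repo greedy multi-level
modularity optimizer (local moves until no gain, then community
aggregation, repeated): implementing it in-repo keeps the algorithm
deterministic for a fixed seed — node visiting order is a seeded shuffle,
ties break toward the lowest community index — and testable against an
exhaustive maximum-modularity oracle on eight-node graphs; the test suite
also cross-checks modularity against igraph's multilevel implementation.
Modularity uses `Q = Σ_c (e_c/m − (d_c/2m)²)` and the reported value is
always recomputed from the final assignment.

Class enrichment inside communities is a one-sided (greater) Fisher exact
test per (community, class) cell over the classified nodes of one side,
community versus rest of network; BH correction pools all cells of that
side into one family, and families (disease-side, drug-side,
class-combinations) are never mixed. Default FDR cutoffs: 0.01 for
community class enrichment, 0.05 for disease-class × drug-class
combination enrichment, which contrasts network membership with combination
membership over the full scored universe and reports the number and
fraction of network edges covered by significant combinations. A community
holding every classified node has no "rest" and is skipped with a warning;
multi-class entities count once per class.

## Synthetic worlds

The generator emulates the data a real deployment would license, with the
couplings the analysis is meant to detect:

- **Ontology**: four levels below the root (organ class → two intermediate
  groupings → leaf terms), branching 2–4, extra parents within a level with
  probability 0.15. The first top-level subtree is kept isolated (attached
  only at the root) except for 5 bridge edges — mimicking an
  investigations-style branch plus cross-hierarchy query groupings. Bridges
  and extra parents are ordinary parent edges; only reachability matters.
- **Annotations**: 200 drugs and 300 diseases, 4–12 leaf terms each, term
  popularity Zipf(1.0) over a shuffled leaf ranking (heavy-tailed frequency
  weights), 60% of each profile drawn from a per-entity home subtree
  (correlated co-occurrence). Leaf-only annotation mirrors most-specific-term
  coding practice.
- **PPI**: a G(n=800, m=1200) random graph; each entity carries 1–2
  proteins.
- **Coupling** (the planted molecular–phenotypic signal): for a pair at
  distance category d, with probability `0.8 · decay[d]`
  (decay 1.0/0.5/0.15/0.05/0 for 0/1/2/3/">3") the disease's symptoms are
  redrawn to mimic that drug: each symptom is, with probability 0.6, one of
  the drug's own side-effect terms, otherwise a leaf sharing a parent with
  one. Grading the decay over all finite categories (rather than a flat
  boost at distance ≤ 1) is what plants the *monotone* decline of lift
  across distance categories; a disease close to several drugs mimics their
  union.
- **Labels**: sampled per pair at per-category rates. ADR–disease
  (0.35/0.20/0.02/0.005/0.001) and contraindication
  (0.25/0.12/0.01/0.002/0.0005) concentrate their mass on molecularly close
  — hence phenotypically coupled — pairs; indication (0.004 flat) and
  clinical trial (0.005 flat) are distance-independent. This plants the
  contrasts the benchmark stage recovers: high lift and higher score
  distributions for ADR/contraindication labels, a null for indications.
- **Classes**: each entity's classes are the modal top-level subtrees of
  its realized profile (MeSH-like for diseases, ATC/MoA-like for drugs), so
  communities of phenotypically similar entities are class-homogeneous and
  enrichment is recoverable.

Identical config and seed give byte-identical files. What the generator
does *not* emulate: text-mining noise, negation, annotation errors,
realistic PPI topology (scale-free degree structure), or realistic profile
sizes (real drugs carry ~100 side effects). Passing tests therefore show
the pipeline recovers planted structure of this kind, not that the measure
ranks real pharmacopoeias correctly.

## Numerical choices and degenerate inputs

- IC and weights in double precision; exports print 6 decimals.
- MICA ties on IC break by term id; only the IC value is consumed.
- Best-match ties keep the maximum value; partner identity is irrelevant.
- Cycle or multi-root ontologies, empty annotation tables, single-term
  ontologies, empty networks and empty positive sets raise explicit errors;
  empty PPI files and self-loop rows warn.
- Community detection accepts only improving moves (gain > 1e-12), so the
  result never falls below the all-singleton partition's modularity.
- Problem sizes in the test suite (200×300 pair worlds, ≤50-node oracle
  graphs, 100-shuffle calibrations) were chosen so the full suite runs in
  well under a minute on one CPU.

## Known limitations

- Residual profile-size bias of best-match averaging (above).
- The Pareto threshold balances precision against recall of
  molecularly close pairs; it retains only a minority (~10–40% across
  seeds) of the coupled distance-≤1 pairs, because the coupling plants a
  broad similarity range. Use the `knee` selector or a fixed threshold for
  more inclusive networks.
- Lift at very small rates on few positives is noisy; the `low_n` flag
  marks fragile curves but does not suppress them.
- The co-occurrence weight is O(T²) in the term vocabulary; adequate for
  vocabularies up to a few thousand terms.
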