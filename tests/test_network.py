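"""Network construction, community detection, Fisher class enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import phenosim as ps
from phenosim.network import (
    CommunityPartition,
    PhenoNetwork,
    build_network,
    class_combination_enrichment,
    community_class_enrichment,
    detect_communities,
    modularity,
)


def net_from_pairs(pairs, threshold=0.0):
    return PhenoNetwork(
        edges=[(f"drug:{d}", f"disease:{s}", 1.0) for d, s in pairs],
        threshold=threshold,
    )


def all_partitions(items):
    """Every set partition (Bell number growth; fine for <= 8 items)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in all_partitions(rest):
        for i, block in enumerate(partition):
            yield partition[:i] + [block + [first]] + partition[i + 1:]
        yield partition + [[first]]


class TestBuildNetwork:
    @pytest.fixture
    def scored(self):
        return pd.DataFrame(
            {
                "drug_id": [f"d{i}" for i in range(10)],
                "disease_id": [f"x{i}" for i in range(10)],
                "similarity": np.linspace(5.0, 0.5, 10),
            }
        )

    def test_min_threshold_keeps_all(self, scored):
        net = build_network(scored, scored["similarity"].min())
        assert net.n_edges == 10

    def test_above_max_empty_with_warning(self, scored, caplog):
        with caplog.at_level("WARNING"):
            net = build_network(scored, scored["similarity"].max() + 1)
        assert net.n_edges == 0
        assert "empty" in caplog.text

    def test_partial_threshold(self, scored):
        net = build_network(scored, 3.4)
        assert net.n_edges == 4
        assert net.nodes == {f"drug:d{i}" for i in range(4)} | {
            f"disease:x{i}" for i in range(4)
        }


class TestCommunities:
    def test_two_blocks_joined_by_one_edge(self):
        """Two complete bipartite blocks with a single bridge split in two.

        The expected partition is the exhaustive maximum-modularity partition
        over all set partitions of the 8 nodes.
        """
        block1 = [(f"a{i}", f"u{j}") for i in range(2) for j in range(2)]
        block2 = [(f"b{i}", f"v{j}") for i in range(2) for j in range(2)]
        bridge = [("a0", "v0")]
        net = net_from_pairs(block1 + block2 + bridge)
        part = detect_communities(net, seed=0)
        adj = net.adjacency()
        best_q, best_partition = -1.0, None
        for partition in all_partitions(sorted(net.nodes)):
            assignment = {
                n: ci for ci, block in enumerate(partition) for n in block
            }
            q = modularity(adj, assignment)
            if q > best_q + 1e-12:
                best_q, best_partition = q, assignment
        assert part.modularity == pytest.approx(best_q, abs=1e-9)
        # groups match: same partition up to relabeling
        def canon(assignment):
            groups = {}
            for n, c in assignment.items():
                groups.setdefault(c, set()).add(n)
            return frozenset(frozenset(g) for g in groups.values())

        assert canon(part.assignment) == canon(best_partition)
        assert len(canon(part.assignment)) == 2

    def test_single_edge_closed_form(self):
        # one community: Q = 0; two singletons: Q = -1/2 -> merge wins
        net = net_from_pairs([("d", "x")])
        part = detect_communities(net, seed=0)
        assert part.modularity == pytest.approx(0.0)
        assert len(set(part.assignment.values())) == 1

    def test_no_community_spans_components(self):
        pairs = [("d1", "x1"), ("d1", "x2"), ("d2", "x3"), ("d2", "x4")]
        net = net_from_pairs(pairs)
        part = detect_communities(net, seed=0)
        comp1 = {"drug:d1", "disease:x1", "disease:x2"}
        comp2 = {"drug:d2", "disease:x3", "disease:x4"}
        c1 = {part.assignment[n] for n in comp1}
        c2 = {part.assignment[n] for n in comp2}
        assert c1.isdisjoint(c2)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            detect_communities(net_from_pairs([]), seed=0)

    def test_modularity_recomputation_identity(self, default_scored):
        threshold = default_scored["similarity"].quantile(0.99)
        net = build_network(default_scored, threshold)
        part = detect_communities(net, seed=0)
        assert part.modularity == pytest.approx(
            modularity(net.adjacency(), part.assignment), abs=1e-12
        )
        # never below the all-singleton partition
        singletons = {n: i for i, n in enumerate(sorted(net.nodes))}
        assert part.modularity >= modularity(net.adjacency(), singletons)

    def test_deterministic_for_fixed_seed(self, default_scored):
        threshold = default_scored["similarity"].quantile(0.995)
        net = build_network(default_scored, threshold)
        a = detect_communities(net, seed=7)
        b = detect_communities(net, seed=7)
        assert a.assignment == b.assignment

    def test_against_igraph_multilevel(self, default_scored):
        """Independent cross-check: modularity on par with igraph's optimizer."""
        igraph = pytest.importorskip("igraph")
        threshold = default_scored["similarity"].quantile(0.99)
        net = build_network(default_scored, threshold)
        part = detect_communities(net, seed=0)
        nodes = sorted(net.nodes)
        idx = {n: i for i, n in enumerate(nodes)}
        g = igraph.Graph(
            n=len(nodes),
            edges=[(idx[d], idx[s]) for d, s, _ in net.edges],
        )
        ig_part = g.community_multilevel()
        assert part.modularity >= ig_part.modularity - 0.02


class TestCommunityClassEnrichment:
    def planted_network(self, n_comm=4, dis_per_comm=8, drugs_per_comm=3):
        """Dense class-homogeneous blocks, sparsely bridged."""
        pairs = []
        disease_classes = {}
        rng = np.random.default_rng(5)
        for c in range(n_comm):
            drugs = [f"d{c}_{k}" for k in range(drugs_per_comm)]
            diseases = [f"x{c}_{k}" for k in range(dis_per_comm)]
            for s in diseases:
                disease_classes[s] = {f"CLS{c}"}
                for d in drugs:
                    if rng.random() < 0.8:
                        pairs.append((d, s))
            if c:  # one bridge to the previous block
                pairs.append((f"d{c}_0", f"x{c-1}_0"))
        return net_from_pairs(pairs), disease_classes

    def test_planted_classes_recovered(self):
        net, disease_classes = self.planted_network()
        part = detect_communities(net, seed=0)
        out = community_class_enrichment(net, part, disease_classes, "disease")
        sig = out[out["significant"]]
        # every planted class should surface in some community
        assert len(set(sig["class_id"])) >= 0.8 * 4

    def test_uniform_class_not_significant(self):
        net, disease_classes = self.planted_network()
        uniform = {e: {"SAME"} for e in disease_classes}
        part = detect_communities(net, seed=0)
        out = community_class_enrichment(net, part, uniform, "disease")
        assert not out["significant"].any()

    def test_hypergeometric_oracle(self):
        """One-sided Fisher p equals the hypergeometric tail computed directly."""
        # community: 10 diseases, 8 of class X; rest: 100 diseases, 10 of class X
        pairs = [(f"d{i}", f"x{i}") for i in range(110)]
        net = net_from_pairs(pairs)
        assignment = {n: (0 if int(n.split("x")[-1]) < 10 else 1) if n.startswith("disease") else 2 for n in net.nodes}
        part = CommunityPartition(assignment=assignment, modularity=0.0)
        classes = {f"x{i}": ({"X"} if (i < 8 or 10 <= i < 20) else {"Y"}) for i in range(110)}
        out = community_class_enrichment(net, part, classes, "disease", fdr_cutoff=0.01)
        row = out[(out["community"] == 0) & (out["class_id"] == "X")].iloc[0]
        # population 110, 18 of class X, draw 10, observe >= 8
        expected = hypergeom.sf(7, 110, 18, 10)
        assert row["p_value"] == pytest.approx(expected, rel=1e-9)

    def test_single_community_skipped(self, caplog):
        net = net_from_pairs([("d1", "x1"), ("d1", "x2")])
        part = CommunityPartition(
            assignment={n: 0 for n in net.nodes}, modularity=0.0
        )
        classes = {"x1": {"A"}, "x2": {"B"}}
        with caplog.at_level("WARNING"):
            out = community_class_enrichment(net, part, classes, "disease")
        assert out.empty
        assert "no rest" in caplog.text

    def test_invariant_to_community_relabeling(self):
        net, disease_classes = self.planted_network()
        part = detect_communities(net, seed=0)
        shifted = CommunityPartition(
            assignment={n: c + 100 for n, c in part.assignment.items()},
            modularity=part.modularity,
        )
        a = community_class_enrichment(net, part, disease_classes, "disease")
        b = community_class_enrichment(net, shifted, disease_classes, "disease")
        a2 = a.assign(community=a["community"] + 100)
        assert a2.reset_index(drop=True).equals(b.reset_index(drop=True))

    def test_permuted_labels_fdr_control(self):
        """Permuting class labels keeps the significant fraction near zero."""
        net, disease_classes = self.planted_network()
        part = detect_communities(net, seed=0)
        rng = np.random.default_rng(99)
        entities = sorted(disease_classes)
        frac_sig = []
        for _ in range(50):
            perm = rng.permutation(len(entities))
            shuffled = {
                entities[i]: disease_classes[entities[int(j)]]
                for i, j in enumerate(perm)
            }
            out = community_class_enrichment(net, part, shuffled, "disease")
            frac_sig.append(out["significant"].mean() if len(out) else 0.0)
        assert float(np.mean(frac_sig)) <= 0.05


class TestClassCombinationEnrichment:
    def toy_universe(self):
        drugs = [f"d{i}" for i in range(10)]
        diseases = [f"x{j}" for j in range(10)]
        scored = pd.DataFrame(
            [
                (d, x, 1.0)
                for d in drugs
                for x in diseases
            ],
            columns=["drug_id", "disease_id", "similarity"],
        )
        return scored

    def test_hypergeometric_oracle(self):
        scored = self.toy_universe()
        # universe 100 pairs; network = 10 pairs; combination covers 10 pairs
        # overall of which 5 are in the network
        combo_pairs = [(f"d{i}", "x0") for i in range(10)]
        net_pairs = combo_pairs[:5] + [(f"d{i}", "x5") for i in range(5)]
        net = net_from_pairs(net_pairs)
        disease_classes = {"x0": {"C"}}
        drug_classes = {f"d{i}": {"A"} for i in range(10)}
        out, summary = class_combination_enrichment(
            net, scored, disease_classes, drug_classes
        )
        row = out[(out["disease_class"] == "C") & (out["drug_class"] == "A")].iloc[0]
        expected = hypergeom.sf(4, 100, 10, 10)
        assert row["p_value"] == pytest.approx(expected, rel=1e-9)

    def test_network_only_combination_small_p(self):
        scored = self.toy_universe()
        net = net_from_pairs([("d0", "x0"), ("d1", "x0"), ("d2", "x0")])
        out, summary = class_combination_enrichment(
            net,
            scored,
            {"x0": {"C"}},
            {"d0": {"A"}, "d1": {"A"}, "d2": {"A"}},
        )
        assert out.iloc[0]["p_value"] < 0.01
        assert summary["edges_covered"] == 3
        assert summary["fraction_covered"] == pytest.approx(1.0)

    def test_proportional_combination_null(self):
        scored = self.toy_universe()
        # network is an unbiased 10-pair sample w.r.t. the combination
        net = net_from_pairs([(f"d{i}", f"x{i}") for i in range(10)])
        disease_classes = {f"x{j}": {"C"} for j in range(10)}
        drug_classes = {f"d{i}": {"A"} for i in range(10)}
        out, _ = class_combination_enrichment(net, scored, disease_classes, drug_classes)
        assert out.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_default_world_pipeline(self, default_scored, default_world, default_links):
        point, _ = ps.pareto_threshold(default_scored, default_links)
        net = build_network(default_scored, point.threshold)
        out, summary = class_combination_enrichment(
            net,
            default_scored,
            default_world.disease_classes,
            default_world.drug_classes,
        )
        assert summary["n_significant"] >= 1
        assert 0 < summary["fraction_covered"] <= 1
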