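"""Shared fixtures: toy ontologies and a session-scoped synthetic world."""

from __future__ import annotations

import pytest

import phenosim as ps
from phenosim.molecular import molecular_links


@pytest.fixture
def diamond():
    """A <- {B, C} <- D: the minimal multi-parent DAG."""
    return ps.Ontology({"A": set(), "B": {"A"}, "C": {"A"}, "D": {"B", "C"}})


@pytest.fixture
def chain():
    """A <- B <- C."""
    return ps.Ontology({"A": set(), "B": {"A"}, "C": {"B"}})


@pytest.fixture
def two_subtrees():
    """Root with two 2-leaf subtrees; leaves of different subtrees meet at root."""
    return ps.Ontology(
        {
            "R": set(),
            "S1": {"R"},
            "S2": {"R"},
            "L1a": {"S1"},
            "L1b": {"S1"},
            "L2a": {"S2"},
            "L2b": {"S2"},
        }
    )


@pytest.fixture(scope="session")
def default_world():
    """The standard synthetic study conditions (200 drugs, 300 diseases)."""
    return ps.generate_world(ps.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_scored(default_world):
    w = default_world
    ic = ps.information_content(w.ontology)
    return ps.score_all_pairs(w.drugs, w.diseases, w.ontology, ic)


@pytest.fixture(scope="session")
def default_links(default_world):
    w = default_world
    return molecular_links(w.ppi, w.targets, w.genes)


@pytest.fixture(scope="session")
def default_labels(default_world):
    return {
        rel: ps.RelationLabels(rel, frozenset(pairs))
        for rel, pairs in default_world.labels.items()
    }
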