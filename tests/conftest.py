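"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import warnings

import pytest
import rdflib
from rdflib import OWL, RDF

from bpmnkg import (
    encode,
    extract,
    miralax_like_fixture,
    table4_fixture,
)


@pytest.fixture
def table4():
    return table4_fixture()


@pytest.fixture
def miralax():
    return miralax_like_fixture()


@pytest.fixture
def table4_graph(table4):
    nodes, sequences = extract(table4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # the excerpt's dangling link drops
        return encode(nodes, sequences, table4.process_name)


def enumerate_owl(path) -> tuple[int, int]:
    """Brute-force oracle: parse an exported file with a generic RDF parser
    and count named individuals and instance-level triples by enumeration.

    Individuals are subjects with an rdf:type other than owl:Ontology;
    triples are all statements whose subject is such an individual (the
    ontology header is not instance data).
    """
    g = rdflib.Graph()
    fmt = "turtle" if str(path).endswith(".ttl") else "xml"
    g.parse(str(path), format=fmt)
    header = set(g.subjects(RDF.type, OWL.Ontology))
    individuals = {
        s for s, o in g.subject_objects(RDF.type) if s not in header
    }
    triple_count = sum(1 for s, _, _ in g if s in individuals)
    return len(individuals), triple_count


def expected_triple_count(
    n_elements: int, n_labeled_elements: int, n_flows: int, n_xrefs: int = 0
) -> int:
    """Closed-form assertion count for a lenient encode with a named process:
    one type per individual, one label on the process and each labeled
    element, two endpoint refs per flow, one attachment per element and
    flow, plus cross-references."""
    types = 1 + n_elements + n_flows
    labels = 1 + n_labeled_elements
    refs = 2 * n_flows
    attachments = n_elements + n_flows
    return types + labels + refs + attachments + n_xrefs
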