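"""Encoding, identifier minting, serialization, loading and statistics."""

import subprocess
import sys
import warnings

import pytest
import rdflib
from rdflib import RDF, RDFS, URIRef

from bpmnkg import (
    CapacityError,
    EncoderConfig,
    EncodingError,
    FormatError,
    GeneratorConfig,
    InstanceId,
    NodeCollection,
    SequenceCollection,
    UnknownElementError,
    annotate_xref,
    encode,
    export,
    extract,
    generate_process,
    load,
    stats,
)
from bpmnkg.bbo import DEFAULT_NAMESPACE as NS
from bpmnkg.encoder import to_rdflib
from bpmnkg.tabular import NodeRecord, SequenceRecord

from conftest import enumerate_owl, expected_triple_count


def encode_quiet(nodes, sequences, name, config=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return encode(nodes, sequences, name, config)


class TestInstanceId:
    def test_seven_digit_rendering(self):
        iid = InstanceId(NS, 28)
        assert iid.local == "0000028"
        assert iid.rendered == NS + "0000028"

    @pytest.mark.parametrize("serial", [-1, 10_000_000])
    def test_out_of_range_serial_rejected(self, serial):
        with pytest.raises(CapacityError):
            InstanceId(NS, serial)


class TestEncode:
    def test_empty_collections_give_process_only(self):
        graph = encode(NodeCollection(), SequenceCollection(), "Empty Process")
        assert stats(graph).as_dict() == {"instances": 1, "triples": 2}
        assert graph.process.label == "Empty Process"
        assert graph.process.instance_id.local == "0000001"

    def test_worked_example_lenient(self, table4):
        nodes, sequences = extract(table4)
        with pytest.warns(UserWarning, match="AD1_27"):
            graph = encode(nodes, sequences, table4.process_name)
        # 1 Process + 5 elements + 4 retained flows; the AD1_27 link drops
        assert stats(graph).instance_count == 10
        assert len(graph.flows) == 4

    def test_worked_example_strict_raises(self, table4):
        nodes, sequences = extract(table4)
        with pytest.raises(EncodingError, match="AD1_27"):
            encode(nodes, sequences, table4.process_name, EncoderConfig(strict=True))

    def test_minting_order_process_elements_flows(self, table4):
        nodes, sequences = extract(table4)
        graph = encode_quiet(nodes, sequences, table4.process_name)
        assert graph.process.instance_id.serial == 1
        element_serials = [
            graph.elements[eid].instance_id.serial for eid in nodes.ids()
        ]
        assert element_serials == [2, 3, 4, 5, 6]
        assert [f.instance_id.serial for f in graph.flows] == [7, 8, 9, 10]

    def test_task_pair_yields_reified_sequence_flow(self):
        """A Task→Task link is reified: a SequenceFlow individual carries
        source/target refs to the two Task individuals, and everything is
        attached to the Process via has_flowElements."""
        vocab_ns = NS
        nodes = NodeCollection()
        vocab = EncoderConfig().vocabulary
        nodes.add(NodeRecord("A", "Take Dulcolax tablet", vocab.resolve_class("Task")))
        nodes.add(NodeRecord("B", "Hydrate w/clear liquid", vocab.resolve_class("Task")))
        sequences = SequenceCollection([SequenceRecord("A", "B")])
        graph = encode(nodes, sequences, "MiraLAX Process")
        g = to_rdflib(graph)
        flow = graph.flows[0].instance_id
        a, b = graph.elements["A"].instance_id, graph.elements["B"].instance_id
        assert (URIRef(flow.rendered), RDF.type, URIRef(vocab_ns + "SequenceFlow")) in g
        assert (URIRef(flow.rendered), URIRef(vocab_ns + "has_sourceRef"),
                URIRef(a.rendered)) in g
        assert (URIRef(flow.rendered), URIRef(vocab_ns + "has_targetRef"),
                URIRef(b.rendered)) in g
        process = URIRef(graph.process.instance_id.rendered)
        for target in (a, b, flow):
            assert (process, URIRef(vocab_ns + "has_flowElements"),
                    URIRef(target.rendered)) in g

    def test_resource_individual_carries_label(self):
        nodes = NodeCollection()
        vocab = EncoderConfig().vocabulary
        nodes.add(NodeRecord("R", "2× Dulcolax", vocab.resolve_class("Resource")))
        graph = encode(nodes, SequenceCollection(), "p")
        g = to_rdflib(graph)
        iri = URIRef(graph.elements["R"].instance_id.rendered)
        assert (iri, RDF.type, URIRef(NS + "Resource")) in g
        assert (iri, RDFS.label, rdflib.Literal("2× Dulcolax")) in g

    def test_label_language_tag_configurable(self):
        nodes = NodeCollection()
        vocab = EncoderConfig().vocabulary
        nodes.add(NodeRecord("T", "do it", vocab.resolve_class("Task")))
        graph = encode(nodes, SequenceCollection(), "p",
                       EncoderConfig(label_lang="en"))
        g = to_rdflib(graph)
        iri = URIRef(graph.elements["T"].instance_id.rendered)
        assert (iri, RDFS.label, rdflib.Literal("do it", lang="en")) in g


class TestXref:
    def test_xref_adds_one_annotation(self, table4_graph):
        before = stats(table4_graph).triple_count
        annotate_xref(table4_graph, "AD1_24", "rxnorm", "1547091")
        after = stats(table4_graph)
        assert after.triple_count == before + 1
        assert after.instance_count == 10  # annotations mint nothing
        ann = table4_graph.annotations[0]
        assert ann.is_iri and "1547091" in ann.value

    def test_repeated_xref_idempotent(self, table4_graph):
        annotate_xref(table4_graph, "AD1_23", "snomedct", "398941000")
        count = stats(table4_graph).triple_count
        annotate_xref(table4_graph, "AD1_23", "snomedct", "398941000")
        assert stats(table4_graph).triple_count == count

    def test_unknown_element_rejected(self, table4_graph):
        with pytest.raises(UnknownElementError):
            annotate_xref(table4_graph, "AD1_99", "rxnorm", "1")


class TestExportLoad:
    def test_roundtrip_preserves_stats_labels_links(self, miralax, tmp_path):
        nodes, sequences = extract(miralax)
        graph = encode(nodes, sequences, miralax.process_name)
        annotate_xref(graph, "R02", "rxnorm", "854894")
        for fmt, name in (("rdfxml", "g.owl"), ("turtle", "g.ttl")):
            path = tmp_path / name
            export(graph, path, fmt=fmt)
            loaded = load(path)
            assert stats(loaded).as_dict() == stats(graph).as_dict()
            labels = sorted(e.label for e in graph.elements.values())
            assert sorted(e.label for e in loaded.elements.values()) == labels
            links = sorted((f.source_iri, f.target_iri) for f in graph.flows)
            assert sorted((f.source_iri, f.target_iri) for f in loaded.flows) == links

    def test_formats_load_to_identical_triple_sets(self, table4_graph, tmp_path):
        export(table4_graph, tmp_path / "g.owl", fmt="rdfxml")
        export(table4_graph, tmp_path / "g.ttl", fmt="turtle")
        g1, g2 = rdflib.Graph(), rdflib.Graph()
        g1.parse(str(tmp_path / "g.owl"), format="xml")
        g2.parse(str(tmp_path / "g.ttl"), format="turtle")
        assert set(g1) == set(g2)

    def test_export_is_byte_deterministic_across_processes(self, tmp_path):
        """Same table, same config: byte-identical files, even under
        different hash randomization."""
        prog = (
            "import sys, warnings; warnings.simplefilter('ignore');"
            "from bpmnkg import *;"
            "t = miralax_like_fixture(); n, s = extract(t);"
            "g = encode(n, s, t.process_name);"
            "export(g, sys.argv[1], fmt=sys.argv[2])"
        )
        import os

        outputs = []
        for seed, name in (("1", "a"), ("4242", "b")):
            for fmt in ("rdfxml", "turtle"):
                out = tmp_path / f"{name}.{fmt}"
                env = dict(os.environ, PYTHONHASHSEED=seed)
                subprocess.run(
                    [sys.executable, "-c", prog, str(out), fmt],
                    check=True, env=env,
                )
                outputs.append(out)
        assert outputs[0].read_bytes() == outputs[2].read_bytes()
        assert outputs[1].read_bytes() == outputs[3].read_bytes()

    def test_empty_model_is_valid_rdf_with_one_individual(self, tmp_path):
        graph = encode(NodeCollection(), SequenceCollection(), "Empty")
        path = export(graph, tmp_path / "empty.owl")
        assert enumerate_owl(path) == (1, 2)

    def test_load_flags_unknown_class(self, tmp_path):
        path = tmp_path / "foreign.ttl"
        path.write_text(
            "<http://x.org/i1> a <http://x.org/Widget> ;"
            ' <http://www.w3.org/2000/01/rdf-schema#label> "w" .',
            encoding="utf-8",
        )
        graph = load(path)
        assert len(graph.elements) == 1
        assert graph.unknown_class_iris == ["http://x.org/Widget"]

    def test_load_non_rdf_is_format_error(self, tmp_path):
        bad = tmp_path / "bad.owl"
        bad.write_text("this is not an ontology", encoding="utf-8")
        with pytest.raises(FormatError):
            load(bad)


class TestStats:
    @pytest.mark.parametrize("seed", range(12))
    def test_counts_match_brute_force_enumeration(self, seed, tmp_path):
        cfg = GeneratorConfig(
            n_tasks=6 + seed % 5, n_gateways=seed % 2, n_resources=seed % 4,
            n_timers=seed % 3, branch_factor=2, seed=seed,
        )
        table = generate_process(cfg)
        nodes, sequences = extract(table)
        graph = encode(nodes, sequences, table.process_name)
        computed = stats(graph)
        assert computed.instance_count == 1 + len(nodes) + len(sequences)
        labeled = sum(1 for n in nodes if n.action_label)
        assert computed.triple_count == expected_triple_count(
            len(nodes), labeled, len(sequences)
        )
        path = export(graph, tmp_path / f"g{seed}.owl")
        assert enumerate_owl(path) == (computed.instance_count, computed.triple_count)

    def test_stats_roundtrip_through_file(self, table4_graph, tmp_path):
        path = export(table4_graph, tmp_path / "t4.owl")
        assert stats(load(path)).as_dict() == stats(table4_graph).as_dict()
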