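"""Encode BPMN node/sequence collections as an OWL2 ABox knowledge graph.

Every table element becomes a named individual typed to its BBO class and
labeled with its action text; every retained sequence becomes a *reified*
SequenceFlow individual carrying ``has_sourceRef``/``has_targetRef`` links to
the endpoint individuals; one Process individual, labeled with the process
name, is linked to every element and flow individual via
``has_flowElements``.  Individuals are minted under a configurable namespace
with OBO-style zero-padded seven-digit serials, assigned deterministically:
the Process first (serial 1), then elements in table order, then flows in
sequence order.  Identical inputs therefore always produce byte-identical
exports.

Cross-references into external terminologies (SNOMED CT, RxNorm) attach as
IRI-valued annotations on individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape, quoteattr

import rdflib
from rdflib import OWL, RDF, RDFS, Literal, URIRef

from .bbo import (
    DEFAULT_NAMESPACE,
    BboClass,
    Category,
    Vocabulary,
    builtin_vocabulary,
)
from .errors import (
    CapacityError,
    EncodingError,
    FormatError,
    UnknownElementError,
)
from .tabular import NodeCollection, SequenceCollection

MAX_SERIAL = 9_999_999

XREF_IRI_TEMPLATES = {
    "snomedct": "http://snomed.info/id/{code}",
    "rxnorm": "http://purl.bioontology.org/ontology/RXNORM/{code}",
}


@dataclass(frozen=True)
class InstanceId:
    """OBO-style minted identifier: namespace prefix + 7-digit serial.

    Serial 0 is a sentinel for identifiers read from foreign graphs that do
    not follow the seven-digit scheme; the IRI is then kept verbatim in
    ``prefix`` and the validator flags it as malformed.
    """

    prefix: str
    serial: int

    def __post_init__(self) -> None:
        if not 0 <= self.serial <= MAX_SERIAL:
            raise CapacityError(
                f"serial {self.serial} outside the seven-digit range [1, {MAX_SERIAL}]"
            )

    @property
    def local(self) -> str:
        if self.serial == 0:
            return self.prefix.rsplit("#", 1)[-1].rsplit("/", 1)[-1]
        return f"{self.serial:07d}"

    @property
    def rendered(self) -> str:
        return self.prefix if self.serial == 0 else self.prefix + self.local

    def __str__(self) -> str:
        return self.rendered


@dataclass
class ElementIndividual:
    instance_id: InstanceId
    bbo_class: BboClass
    label: str
    attached: bool = True  # linked from the Process via has_flowElements


@dataclass
class FlowIndividual:
    instance_id: InstanceId
    source_iri: str
    target_iri: str
    attached: bool = True


@dataclass(frozen=True)
class Annotation:
    subject_iri: str
    property_iri: str
    value: str
    is_iri: bool


@dataclass
class GraphStats:
    instance_count: int
    triple_count: int

    def as_dict(self) -> dict[str, int]:
        return {"instances": self.instance_count, "triples": self.triple_count}


@dataclass
class EncoderConfig:
    """Knobs for identifier minting and serialization.

    ``base_iri`` is the namespace individuals are minted under (the class
    namespace by default, which is safe because minted local names are purely
    numeric).  ``label_lang`` optionally tags every rdfs:label with a
    language; the default is bare literals.
    """

    base_iri: str = DEFAULT_NAMESPACE
    strict: bool = False
    label_lang: str | None = None
    vocabulary: Vocabulary | None = None
    ontology_iri: str | None = None
    import_tbox: bool = True  # owl:imports the TBox IRI when one was loaded

    def __post_init__(self) -> None:
        if self.vocabulary is None:
            self.vocabulary = builtin_vocabulary()
        if self.ontology_iri is None:
            self.ontology_iri = self.base_iri.rstrip("#/")


@dataclass
class KnowledgeGraph:
    """In-memory OWL2 ABox: one Process, element individuals, reified flows."""

    config: EncoderConfig
    process: ElementIndividual | None = None
    elements: dict[str, ElementIndividual] = field(default_factory=dict)
    flows: list[FlowIndividual] = field(default_factory=list)
    annotations: list[Annotation] = field(default_factory=list)
    unknown_class_iris: list[str] = field(default_factory=list)

    def individuals(self) -> list[ElementIndividual | FlowIndividual]:
        out: list[ElementIndividual | FlowIndividual] = []
        if self.process is not None:
            out.append(self.process)
        out.extend(self.elements.values())
        out.extend(self.flows)
        return out

    def element_iris(self) -> set[str]:
        return {e.instance_id.rendered for e in self.elements.values()}

    def find_element(self, element_id: str) -> ElementIndividual:
        try:
            return self.elements[element_id]
        except KeyError:
            raise UnknownElementError(
                f"element {element_id!r} is not encoded in this graph"
            ) from None


def encode(
    nodes: NodeCollection,
    sequences: SequenceCollection,
    process_name: str,
    config: EncoderConfig | None = None,
) -> KnowledgeGraph:
    """Encode extracted collections as a knowledge graph.

    Serial 1 is the Process individual; elements follow in collection order,
    then one SequenceFlow individual per retained sequence.  A sequence whose
    target has no node record is dropped with a warning in lenient mode and
    raises :class:`EncodingError` under ``config.strict``.
    """
    cfg = config or EncoderConfig()
    graph = KnowledgeGraph(config=cfg)
    vocab = cfg.vocabulary
    assert vocab is not None

    serial = 1

    def mint() -> InstanceId:
        nonlocal serial
        iid = InstanceId(cfg.base_iri, serial)
        serial += 1
        return iid

    process_cls = vocab.resolve_class("Process")
    graph.process = ElementIndividual(mint(), process_cls, process_name)

    for node in nodes:
        graph.elements[node.element_id] = ElementIndividual(
            mint(), node.bbo_class, node.action_label
        )

    for seq in sequences:
        if seq.target_id not in graph.elements:
            if cfg.strict:
                raise EncodingError(
                    f"sequence {seq.source_id} -> {seq.target_id}: "
                    f"target {seq.target_id!r} has no defining row"
                )
            warnings.warn(
                f"dropping sequence {seq.source_id} -> {seq.target_id}: "
                f"target {seq.target_id!r} undefined",
                stacklevel=2,
            )
            continue
        if seq.source_id not in graph.elements:
            # cannot happen for collections built by extract(); guards
            # hand-constructed input
            raise EncodingError(f"sequence source {seq.source_id!r} undefined")
        graph.flows.append(
            FlowIndividual(
                mint(),
                graph.elements[seq.source_id].instance_id.rendered,
                graph.elements[seq.target_id].instance_id.rendered,
            )
        )
    return graph


def annotate_xref(
    graph: KnowledgeGraph,
    element_id: str,
    terminology: str,
    code: str,
) -> KnowledgeGraph:
    """Attach an external-terminology cross-reference to an encoded element.

    ``terminology`` is ``snomedct``, ``rxnorm`` or ``other``; SNOMED CT and
    RxNorm codes expand to their canonical IRIs, anything else is kept as an
    absolute IRI when it looks like one, else as a plain (CURIE) literal.
    Repeated identical calls are no-ops.
    """
    element = graph.find_element(element_id)
    terminology = terminology.lower()
    if terminology in XREF_IRI_TEMPLATES:
        value, is_iri = XREF_IRI_TEMPLATES[terminology].format(code=code), True
    else:
        is_iri = "://" in code
        value = code
    assert graph.config.vocabulary is not None
    annotation = Annotation(
        element.instance_id.rendered,
        graph.config.vocabulary.properties.xref_property,
        value,
        is_iri,
    )
    if annotation not in graph.annotations:
        graph.annotations.append(annotation)
    return graph


# --- serialization ---------------------------------------------------------


def _abox_triples(graph: KnowledgeGraph) -> list[tuple[str, str, str, bool, str | None]]:
    """Deterministic (subject, predicate, object, object_is_iri, lang) list.

    This is the exact assertion set that export writes (minus the ontology
    header) and that :func:`stats` counts.
    """
    cfg = graph.config
    vocab = cfg.vocabulary
    assert vocab is not None
    props = vocab.properties
    flow_cls = vocab.resolve_class("SequenceFlow")
    lang = cfg.label_lang
    triples: list[tuple[str, str, str, bool, str | None]] = []

    def emit_typed_labeled(ind: ElementIndividual) -> None:
        iri = ind.instance_id.rendered
        triples.append((iri, str(RDF.type), ind.bbo_class.iri, True, None))
        if ind.label:
            triples.append((iri, props.label_property, ind.label, False, lang))

    if graph.process is not None:
        emit_typed_labeled(graph.process)
    for element in graph.elements.values():
        emit_typed_labeled(element)
    for flow in graph.flows:
        iri = flow.instance_id.rendered
        triples.append((iri, str(RDF.type), flow_cls.iri, True, None))
        triples.append((iri, props.source_ref, flow.source_iri, True, None))
        triples.append((iri, props.target_ref, flow.target_iri, True, None))
    if graph.process is not None:
        process_iri = graph.process.instance_id.rendered
        for element in graph.elements.values():
            if element.attached:
                triples.append(
                    (process_iri, props.has_flow_elements,
                     element.instance_id.rendered, True, None)
                )
        for flow in graph.flows:
            if flow.attached:
                triples.append(
                    (process_iri, props.has_flow_elements,
                     flow.instance_id.rendered, True, None)
                )
    for ann in graph.annotations:
        triples.append((ann.subject_iri, ann.property_iri, ann.value, ann.is_iri, None))
    return triples


def stats(graph: KnowledgeGraph) -> GraphStats:
    """Instance and ABox-assertion counts.

    ``instance_count`` is the number of named individuals (Process + elements
    + flows); ``triple_count`` the number of asserted instance-level
    statements: one type per individual, one label per labeled individual,
    source/target refs on flows, ``has_flowElements`` attachments, and
    cross-reference annotations.  The ontology header is not counted.
    """
    return GraphStats(
        instance_count=len(graph.individuals()),
        triple_count=len(_abox_triples(graph)),
    )


_PREFIXES = {
    "rdf": str(RDF),
    "rdfs": str(RDFS),
    "owl": str(OWL),
    "oboInOwl": "http://www.geneontology.org/formats/oboInOwl#",
}


def _split_iri(iri: str, namespaces: dict[str, str]) -> tuple[str, str] | None:
    for prefix, ns in namespaces.items():
        if iri.startswith(ns) and iri != ns:
            local = iri[len(ns):]
            if local and all(c.isalnum() or c in "_-." for c in local):
                return prefix, local
    return None


def _serialize_rdfxml(graph: KnowledgeGraph) -> str:
    """Canonical RDF/XML: subjects in minting order, fixed predicate order."""
    cfg = graph.config
    namespaces = dict(_PREFIXES)
    namespaces["bbo"] = cfg.vocabulary.namespace  # type: ignore[union-attr]
    if cfg.base_iri not in namespaces.values():
        namespaces["kg"] = cfg.base_iri

    by_subject: dict[str, list[tuple[str, str, bool, str | None]]] = {}
    order: list[str] = []
    for s, p, o, is_iri, lang in _abox_triples(graph):
        if s not in by_subject:
            by_subject[s] = []
            order.append(s)
        by_subject[s].append((p, o, is_iri, lang))

    lines = ['<?xml version="1.0" encoding="UTF-8"?>']
    ns_attrs = "".join(
        f'\n    xmlns:{prefix}={quoteattr(ns)}' for prefix, ns in sorted(namespaces.items())
    )
    lines.append(f"<rdf:RDF{ns_attrs}>")
    vocab = cfg.vocabulary
    assert vocab is not None
    ontology_about = quoteattr(cfg.ontology_iri or "")
    if cfg.import_tbox and vocab.tbox_iri:
        lines.append(f"  <owl:Ontology rdf:about={ontology_about}>")
        lines.append(f"    <owl:imports rdf:resource={quoteattr(vocab.tbox_iri)}/>")
        lines.append("  </owl:Ontology>")
    else:
        lines.append(f"  <owl:Ontology rdf:about={ontology_about}/>")

    for subject in order:
        lines.append(f"  <rdf:Description rdf:about={quoteattr(subject)}>")
        for p, o, is_iri, lang in by_subject[subject]:
            qname = _split_iri(p, namespaces)
            tag = f"{qname[0]}:{qname[1]}" if qname else None
            if tag is None:
                # predicate outside the bound namespaces: emit with a local
                # xmlns so the document stays well-formed
                cut = max(p.rfind("#"), p.rfind("/")) + 1
                tag, extra = f"x:{p[cut:]}", f' xmlns:x={quoteattr(p[:cut])}'
            else:
                extra = ""
            if is_iri:
                lines.append(f"    <{tag}{extra} rdf:resource={quoteattr(o)}/>")
            else:
                lang_attr = f' xml:lang="{lang}"' if lang else ""
                lines.append(f"    <{tag}{extra}{lang_attr}>{escape(o)}</{tag}>")
        lines.append("  </rdf:Description>")
    lines.append("</rdf:RDF>")
    return "\n".join(lines) + "\n"


def to_rdflib(graph: KnowledgeGraph) -> rdflib.Graph:
    """Materialize the knowledge graph (with ontology header) as rdflib triples."""
    cfg = graph.config
    g = rdflib.Graph()
    vocab = cfg.vocabulary
    assert vocab is not None
    g.bind("bbo", vocab.namespace)
    g.bind("owl", OWL)
    g.bind("oboInOwl", _PREFIXES["oboInOwl"])
    ontology = URIRef(cfg.ontology_iri or cfg.base_iri.rstrip("#/"))
    g.add((ontology, RDF.type, OWL.Ontology))
    if cfg.import_tbox and vocab.tbox_iri:
        g.add((ontology, OWL.imports, URIRef(vocab.tbox_iri)))
    for s, p, o, is_iri, lang in _abox_triples(graph):
        obj = URIRef(o) if is_iri else Literal(o, lang=lang)
        g.add((URIRef(s), URIRef(p), obj))
    return g


def export(graph: KnowledgeGraph, path: str | Path, fmt: str = "rdfxml") -> Path:
    """Write the graph as an OWL2 document; identical graphs yield
    byte-identical files.

    ``fmt`` is ``rdfxml`` (default; canonical writer with subjects in minting
    order) or ``turtle`` (rdflib's sorted serializer).
    """
    path = Path(path)
    fmt = fmt.lower()
    if fmt in ("rdfxml", "xml", "owl", "rdf/xml"):
        payload = _serialize_rdfxml(graph)
    elif fmt in ("turtle", "ttl"):
        payload = to_rdflib(graph).serialize(format="turtle")
    else:
        raise ValueError(f"unknown export format {fmt!r} (expected rdfxml or turtle)")
    path.write_text(payload, encoding="utf-8")
    return path


def _guess_format(path: Path) -> list[str]:
    suffix = path.suffix.lower()
    if suffix in (".ttl", ".n3"):
        return ["turtle", "xml"]
    return ["xml", "turtle"]


def load(path: str | Path, config: EncoderConfig | None = None) -> KnowledgeGraph:
    """Parse an OWL2 file (RDF/XML or Turtle) back into a knowledge graph.

    Individuals typed to classes outside the vocabulary are kept and recorded
    in ``unknown_class_iris``; the validator reports them.  Raises
    :class:`FormatError` when the file parses in no accepted serialization.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cfg = config or EncoderConfig()
    vocab = cfg.vocabulary
    assert vocab is not None
    props = vocab.properties

    g = rdflib.Graph()
    last_error: Exception | None = None
    for fmt in _guess_format(path):
        try:
            g.parse(location=str(path), format=fmt)
            last_error = None
            break
        except Exception as exc:
            last_error = exc
            g = rdflib.Graph()
    if last_error is not None:
        raise FormatError(f"cannot parse {path} as RDF/XML or Turtle: {last_error}")

    graph = KnowledgeGraph(config=cfg)
    label_p = URIRef(props.label_property)
    src_p, tgt_p = URIRef(props.source_ref), URIRef(props.target_ref)
    flowel_p = URIRef(props.has_flow_elements)

    typed: dict[URIRef, URIRef] = {}
    for s, o in sorted(g.subject_objects(RDF.type)):
        if not isinstance(s, URIRef) or not isinstance(o, URIRef):
            continue
        if o in (OWL.Ontology, OWL.Class, RDFS.Class, OWL.ObjectProperty,
                 OWL.DatatypeProperty, OWL.AnnotationProperty, OWL.NamedIndividual):
            continue
        typed.setdefault(s, o)

    attached: set[str] = {str(o) for o in g.objects(None, flowel_p)}

    def first_label(s: URIRef) -> str:
        for o in sorted(g.objects(s, label_p)):
            return str(o)
        return ""

    def make_iid(iri: str) -> InstanceId:
        tail = iri.rsplit("#", 1)[-1].rsplit("/", 1)[-1]
        if tail.isdigit() and len(tail) == 7 and int(tail) >= 1:
            return InstanceId(iri[: -len(tail)], int(tail))
        # foreign identifier scheme: keep the IRI verbatim; the validator
        # flags it as not seven-digit
        return InstanceId(iri, 0)

    known_statement_props = {RDF.type, label_p, src_p, tgt_p, flowel_p}

    for subject in sorted(typed):
        cls_iri = str(typed[subject])
        iri = str(subject)
        try:
            cls = vocab.resolve_class(cls_iri)
        except Exception:
            cls = BboClass(cls_iri.rsplit("#", 1)[-1], cls_iri, Category.UNKNOWN)
            graph.unknown_class_iris.append(cls_iri)
        iid = make_iid(iri)
        if cls.category is Category.PROCESS and graph.process is None:
            graph.process = ElementIndividual(iid, cls, first_label(subject))
        elif cls.category is Category.FLOW_LINK:
            sources = sorted(g.objects(subject, src_p))
            targets = sorted(g.objects(subject, tgt_p))
            if sources and targets:
                graph.flows.append(
                    FlowIndividual(
                        iid, str(sources[0]), str(targets[0]), iri in attached
                    )
                )
            else:  # flow without refs degrades to a plain element
                key = iid.local if iid.local not in graph.elements else iri
                graph.elements[key] = ElementIndividual(
                    iid, cls, first_label(subject), iri in attached
                )
        else:
            key = iid.local if iid.local not in graph.elements else iri
            graph.elements[key] = ElementIndividual(
                iid, cls, first_label(subject), iri in attached
            )

    individual_iris = {ind.instance_id.rendered for ind in graph.individuals()}
    xref_p = URIRef(props.xref_property)
    for s, p, o in sorted(g):
        if str(s) not in individual_iris or p in known_statement_props:
            continue
        if p == xref_p or not str(p).startswith(str(OWL)):
            graph.annotations.append(
                Annotation(str(s), str(p), str(o), isinstance(o, URIRef))
            )
    return graph
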