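"""BBO (BPMN-Based Ontology) vocabulary used to type knowledge-graph individuals.

The engine ships a minimal built-in ABox-facing vocabulary: the BBO core
classes (Process, Task, SequenceFlow, Gateway, StartEvent, EndEvent,
TimerEvent, ConditionalExpression, InputOutputSpecification, Resource) plus
the object/annotation properties the encoder asserts.  A published BBO TBox
can optionally be loaded, in which case its classes extend the built-ins and
the exported graphs can ``owl:imports`` it.

The default namespace is ``http://BPMNbasedOntology#``; both full IRIs and
bare local names (``Task``) resolve to the same class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import rdflib
from rdflib import OWL, RDF, RDFS

from .errors import FormatError, VocabularyError

DEFAULT_NAMESPACE = "http://BPMNbasedOntology#"

#: OBO-in-OWL cross-reference annotation property, the conventional hook for
#: SNOMED CT / RxNorm codes on individuals.
DEFAULT_XREF_IRI = "http://www.geneontology.org/formats/oboInOwl#hasDbXref"

RDFS_LABEL = str(RDFS.label)


class Category(str, Enum):
    PROCESS = "process"
    FLOW_NODE = "flow_node"
    FLOW_LINK = "flow_link"
    RESOURCE = "resource"
    METADATA = "metadata"
    UNKNOWN = "unknown"  # classes seen in loaded graphs but not in the vocabulary


@dataclass(frozen=True)
class BboClass:
    local_name: str
    iri: str
    category: Category

    def __str__(self) -> str:
        return self.iri


@dataclass(frozen=True)
class PropertyVocabulary:
    """IRIs of the properties asserted on encoded individuals."""

    has_flow_elements: str
    source_ref: str
    target_ref: str
    label_property: str = RDFS_LABEL
    xref_property: str = DEFAULT_XREF_IRI


_CORE_CLASSES: tuple[tuple[str, Category], ...] = (
    ("Process", Category.PROCESS),
    ("Task", Category.FLOW_NODE),
    ("SequenceFlow", Category.FLOW_LINK),
    ("Gateway", Category.FLOW_NODE),
    ("StartEvent", Category.FLOW_NODE),
    ("EndEvent", Category.FLOW_NODE),
    ("TimerEvent", Category.FLOW_NODE),
    ("ConditionalExpression", Category.METADATA),
    ("InputOutputSpecification", Category.METADATA),
    ("Resource", Category.RESOURCE),
)


@dataclass
class Vocabulary:
    """Resolvable set of BBO classes plus the encoder's property IRIs."""

    namespace: str = DEFAULT_NAMESPACE
    classes: dict[str, BboClass] = field(default_factory=dict)  # keyed by local name
    properties: PropertyVocabulary | None = None
    tbox_iri: str | None = None  # set when a TBox was loaded; used for owl:imports

    def __post_init__(self) -> None:
        if self.properties is None:
            ns = self.namespace
            self.properties = PropertyVocabulary(
                has_flow_elements=ns + "has_flowElements",
                source_ref=ns + "has_sourceRef",
                target_ref=ns + "has_targetRef",
            )
        self._by_iri = {c.iri: c for c in self.classes.values()}

    def _register(self, cls: BboClass) -> None:
        self.classes[cls.local_name] = cls
        self._by_iri[cls.iri] = cls

    def resolve_class(self, iri_or_name: str) -> BboClass:
        """Resolve a full class IRI or a bare local name to a :class:`BboClass`.

        Matching is exact on the IRI and case-sensitive on the local name;
        anything else raises :class:`VocabularyError`.
        """
        term = iri_or_name.strip()
        if term in self._by_iri:
            return self._by_iri[term]
        if term in self.classes:
            return self.classes[term]
        raise VocabularyError(term)

    def knows_iri(self, iri: str) -> bool:
        return iri in self._by_iri

    def local_names(self) -> list[str]:
        return list(self.classes)

    # classes permitted as flow endpoints (anything concrete except the
    # Process itself and SequenceFlow, which is the reified link)
    def is_flow_endpoint(self, cls: BboClass) -> bool:
        return cls.category in (Category.FLOW_NODE, Category.RESOURCE, Category.METADATA)


def builtin_vocabulary(namespace: str = DEFAULT_NAMESPACE) -> Vocabulary:
    """The ten core BBO classes under ``namespace``, no TBox attached."""
    vocab = Vocabulary(namespace=namespace)
    for name, category in _CORE_CLASSES:
        vocab._register(BboClass(name, namespace + name, category))
    return vocab


def _local_name(iri: str) -> str:
    for sep in ("#", "/"):
        if sep in iri:
            tail = iri.rsplit(sep, 1)[1]
            if tail:
                return tail
    return iri


def load_tbox(path: str | Path | None = None, namespace: str = DEFAULT_NAMESPACE) -> Vocabulary:
    """Return the encoder vocabulary, optionally extended from an OWL TBox file.

    Without a path this is :func:`builtin_vocabulary`.  With a path, every
    ``owl:Class``/``rdfs:Class`` declared in the document is added (built-ins
    are kept so the invariant class list is always resolvable), and the
    ontology IRI is remembered so exports can import it.
    """
    vocab = builtin_vocabulary(namespace)
    if path is None:
        return vocab
    path = Path(path)
    graph = rdflib.Graph()
    try:
        graph.parse(location=str(path))
    except Exception as exc:  # rdflib raises parser-specific exceptions
        raise FormatError(f"cannot parse OWL TBox {path}: {exc}") from exc
    declared = sorted(
        str(s)
        for cls_type in (OWL.Class, RDFS.Class)
        for s in graph.subjects(RDF.type, cls_type)
        if isinstance(s, rdflib.URIRef)
    )
    if not declared:
        raise FormatError(f"{path} parsed as RDF but declares no OWL/RDFS classes")
    for iri in declared:
        if vocab.knows_iri(iri):
            continue
        name = _local_name(iri)
        # a TBox class whose local name collides with a built-in stays
        # addressable by IRI; the built-in keeps the bare-name shortcut
        if name in vocab.classes:
            name = iri
        vocab._register(BboClass(name, iri, _guess_category(name)))
    for s in graph.subjects(RDF.type, OWL.Ontology):
        vocab.tbox_iri = str(s)
        break
    return vocab


def _guess_category(local_name: str) -> Category:
    """Best-effort category for TBox classes outside the core list."""
    lowered = local_name.lower()
    if "process" in lowered:
        return Category.PROCESS
    if "flow" in lowered and "element" not in lowered:
        return Category.FLOW_LINK
    if "resource" in lowered:
        return Category.RESOURCE
    if any(k in lowered for k in ("event", "task", "gateway", "activity")):
        return Category.FLOW_NODE
    return Category.METADATA


def resolve_class(iri_or_name: str, vocabulary: Vocabulary | None = None) -> BboClass:
    """Module-level convenience over :meth:`Vocabulary.resolve_class`."""
    return (vocabulary or builtin_vocabulary()).resolve_class(iri_or_name)
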