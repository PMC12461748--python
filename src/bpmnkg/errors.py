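"""Exception hierarchy for the BPMN knowledge-graph rendering engine."""


class BpmnKgError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(BpmnKgError):
    """A tabular input violates the required ID/ACTION/Type/TARGET layout."""


class VocabularyError(BpmnKgError):
    """A class IRI or local name is not part of the BBO vocabulary in use."""

    def __init__(self, term: str, message: str | None = None):
        self.term = term
        super().__init__(message or f"unknown BBO class term: {term!r}")


class ConflictError(BpmnKgError):
    """The same element identifier appears with contradictory label or class."""


class EncodingError(BpmnKgError):
    """Strict-mode encoding failure, e.g. a sequence targeting an undefined element."""


class CapacityError(BpmnKgError):
    """The seven-digit identifier space is exhausted (serial > 9 999 999)."""


class UnknownElementError(BpmnKgError, LookupError):
    """An element identifier is not present in the knowledge graph."""


class FormatError(BpmnKgError):
    """A file could not be parsed in any accepted RDF/OWL serialization."""


class ReasonerError(BpmnKgError):
    """The external reasoner process failed; diagnostics are attached."""

    def __init__(self, message: str, diagnostics: str = ""):
        self.diagnostics = diagnostics
        super().__init__(message)


class ConfigError(BpmnKgError):
    """An impossible or malformed configuration was supplied."""
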