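"""Well-formedness and consistency checking of encoded knowledge graphs.

Two layers:

* :func:`check_structural` — native rules over the in-memory graph: known
  classes, resolvable flow endpoints, event direction conventions,
  process attachment, reachability from the start event, and seven-digit
  identifier hygiene.  Always available, pure, report-only.
* :func:`check_logical` — delegates consistency/satisfiability to an
  external description-logic reasoner invoked as a subprocess (command
  template with an ``{input}`` placeholder).  Without a configured reasoner
  the logical check degrades to an informational finding.

The package ships :mod:`bpmnkg.dlcheck`, a minimal ABox clash detector
(explicit ``owl:disjointWith`` and ``owl:differentFrom`` violations) that can
serve as the reasoner command when no full DL reasoner is installed:
``python -m bpmnkg.dlcheck {input}``.
"""

from __future__ import annotations

import re
import shlex
import subprocess
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .bbo import Category
from .encoder import EncoderConfig, KnowledgeGraph, load
from .errors import ReasonerError
from .report import Severity, ValidationReport


@dataclass
class StructuralRules:
    """Toggle engine-level conventions that go beyond schema conformance."""

    event_direction: bool = True  # StartEvent no incoming, EndEvent no outgoing
    reachability: bool = True  # flow nodes reachable from a StartEvent


def check_structural(
    graph: KnowledgeGraph, rules: StructuralRules | None = None
) -> ValidationReport:
    """Evaluate structural well-formedness rules; report-only and pure."""
    rules = rules or StructuralRules()
    report = ValidationReport()
    vocab = graph.config.vocabulary
    assert vocab is not None

    element_by_iri = {
        e.instance_id.rendered: e for e in graph.elements.values()
    }
    process_iri = graph.process.instance_id.rendered if graph.process else None

    # R1: every individual typed to a known BBO class
    for element in graph.elements.values():
        if element.bbo_class.category is Category.UNKNOWN or not vocab.knows_iri(
            element.bbo_class.iri
        ):
            report.add(
                Severity.ERROR,
                "unknown-class",
                element.instance_id.local,
                f"typed to {element.bbo_class.iri}, which is outside the vocabulary",
            )

    # R2: flow endpoints exist and are legal (never the Process, never a flow)
    for flow in graph.flows:
        for role, endpoint in (("source", flow.source_iri), ("target", flow.target_iri)):
            if endpoint == process_iri:
                report.add(
                    Severity.ERROR,
                    "flow-endpoint",
                    flow.instance_id.local,
                    f"{role} of the flow is the Process individual",
                )
            elif endpoint not in element_by_iri:
                report.add(
                    Severity.ERROR,
                    "flow-endpoint",
                    flow.instance_id.local,
                    f"{role} {endpoint} is not an element individual in the graph",
                )
            elif not vocab.is_flow_endpoint(element_by_iri[endpoint].bbo_class):
                report.add(
                    Severity.ERROR,
                    "flow-endpoint",
                    flow.instance_id.local,
                    f"{role} {endpoint} is a "
                    f"{element_by_iri[endpoint].bbo_class.local_name}, "
                    "which cannot anchor a sequence flow",
                )

    # R3: event direction conventions
    if rules.event_direction:
        incoming: set[str] = set()
        outgoing: set[str] = set()
        for flow in graph.flows:
            outgoing.add(flow.source_iri)
            incoming.add(flow.target_iri)
        for element in graph.elements.values():
            iri = element.instance_id.rendered
            name = element.bbo_class.local_name
            if name == "StartEvent" and iri in incoming:
                report.add(
                    Severity.ERROR,
                    "event-direction",
                    element.instance_id.local,
                    "StartEvent has an incoming sequence flow",
                )
            if name == "EndEvent" and iri in outgoing:
                report.add(
                    Severity.ERROR,
                    "event-direction",
                    element.instance_id.local,
                    "EndEvent has an outgoing sequence flow",
                )

    # R4: every element/flow individual attached to the Process
    if graph.process is None:
        report.add(
            Severity.WARNING,
            "no-process",
            "-",
            "graph has no Process individual; attachment not checkable",
        )
    else:
        for ind in list(graph.elements.values()) + list(graph.flows):
            if not ind.attached:
                report.add(
                    Severity.ERROR,
                    "unattached",
                    ind.instance_id.local,
                    "individual is not linked from the Process via has_flowElements",
                )

    # R5: flow nodes reachable from some StartEvent (convention; warning).
    # Resource and metadata individuals feed *into* the control flow, so only
    # flow_node-category elements are expected to be reachable.
    if rules.reachability and graph.elements:
        digraph = nx.DiGraph()
        for iri in element_by_iri:
            digraph.add_node(iri)
        for flow in graph.flows:
            if flow.source_iri in element_by_iri and flow.target_iri in element_by_iri:
                digraph.add_edge(flow.source_iri, flow.target_iri)
        starts = [
            e.instance_id.rendered
            for e in graph.elements.values()
            if e.bbo_class.local_name == "StartEvent"
        ]
        if not starts:
            report.add(
                Severity.WARNING,
                "unreachable",
                "-",
                "graph has no StartEvent; reachability not assessable",
            )
        else:
            reachable: set[str] = set(starts)
            for s in starts:
                reachable |= nx.descendants(digraph, s)
            for element in graph.elements.values():
                iri = element.instance_id.rendered
                if (
                    element.bbo_class.category is Category.FLOW_NODE
                    and iri not in reachable
                ):
                    report.add(
                        Severity.WARNING,
                        "unreachable",
                        element.instance_id.local,
                        f"{element.bbo_class.local_name} is not reachable from any "
                        "StartEvent along sequence flows",
                    )

    # R6: identifier hygiene — seven digits, in range, unique
    seen: dict[str, str] = {}
    for ind in graph.individuals():
        iid = ind.instance_id
        if iid.serial == 0 or not re.fullmatch(r"\d{7}", iid.local):
            report.add(
                Severity.ERROR,
                "bad-identifier",
                iid.local,
                f"identifier {iid.rendered} does not use a seven-digit serial",
            )
        if iid.rendered in seen:
            report.add(
                Severity.ERROR,
                "duplicate-identifier",
                iid.local,
                f"identifier {iid.rendered} minted more than once",
            )
        seen[iid.rendered] = iid.local
    return report


_INCONSISTENT = re.compile(r"\binconsistent\b", re.IGNORECASE)
_UNSAT = re.compile(r"\bunsatisfiable\b[:\s]*(\S*)", re.IGNORECASE)


def check_logical(
    graph_path: str | Path,
    reasoner_cmd: str | None = None,
    config: EncoderConfig | None = None,
    rules: StructuralRules | None = None,
    timeout: float = 120.0,
) -> ValidationReport:
    """Run the structural rules plus, when configured, an external reasoner.

    ``reasoner_cmd`` is a shell-style command template whose ``{input}``
    placeholder receives the OWL file path.  The subprocess verdict is parsed
    from standard output: any line mentioning *inconsistent* yields an error
    finding, *unsatisfiable* lines yield one error each, and otherwise the
    graph is reported consistent.  A non-zero exit raises
    :class:`ReasonerError` with the captured diagnostics.
    """
    graph_path = Path(graph_path)
    graph = load(graph_path, config=config)
    report = check_structural(graph, rules=rules)

    if not reasoner_cmd:
        report.add(
            Severity.INFO,
            "logical-skipped",
            str(graph_path.name),
            "logical check skipped: no reasoner configured",
        )
        return report

    argv = [
        arg.replace("{input}", str(graph_path)) for arg in shlex.split(reasoner_cmd)
    ]
    try:
        proc = subprocess.run(
            argv, capture_output=True, text=True, timeout=timeout, check=False
        )
    except (OSError, subprocess.TimeoutExpired) as exc:
        raise ReasonerError(f"reasoner invocation failed: {exc}") from exc
    if proc.returncode != 0:
        raise ReasonerError(
            f"reasoner exited with status {proc.returncode}",
            diagnostics=(proc.stdout + proc.stderr).strip(),
        )

    output = proc.stdout
    unsat = [m.group(1) or "?" for m in _UNSAT.finditer(output)]
    if _INCONSISTENT.search(output):
        report.add(
            Severity.ERROR,
            "logical-inconsistent",
            str(graph_path.name),
            "reasoner reports the ontology inconsistent",
        )
    for cls in unsat:
        report.add(
            Severity.ERROR,
            "logical-unsatisfiable",
            cls,
            f"reasoner reports class {cls} unsatisfiable",
        )
    if not _INCONSISTENT.search(output) and not unsat:
        report.add(
            Severity.INFO,
            "logical-consistent",
            str(graph_path.name),
            "reasoner reports the ontology consistent and all classes satisfiable",
        )
    return report
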