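"""Minimal ABox clash detector, usable as a reasoner command.

This is *not* a description-logic reasoner: it detects only explicitly
asserted clashes in the input document (imports are not resolved):

* an individual typed to two classes declared ``owl:disjointWith``
  (directly, or via ``rdfs:subClassOf`` ancestors);
* an individual typed to ``owl:Nothing``;
* a pair of individuals asserted both ``owl:sameAs`` and
  ``owl:differentFrom``;
* classes declared ``rdfs:subClassOf`` two disjoint classes are reported
  unsatisfiable.

For the instance-level graphs this package produces — plain class
assertions, labels and object links, with no negative axioms — these are
exactly the contradictions that could be stated, so a clean verdict here
mirrors what a full reasoner concludes on them.  Run as::

    python -m bpmnkg.dlcheck graph.owl

Prints ``consistent`` or ``inconsistent: <reason>`` (plus one
``unsatisfiable: <class>`` line per unsatisfiable class) and exits 0; exits
2 on unreadable input.
"""

from __future__ import annotations

import sys
from itertools import combinations
from pathlib import Path

import rdflib
from rdflib import OWL, RDF, RDFS, URIRef


def _parse(path: Path) -> rdflib.Graph:
    g = rdflib.Graph()
    errors = []
    for fmt in ("xml", "turtle"):
        try:
            g.parse(location=str(path), format=fmt)
            return g
        except Exception as exc:
            errors.append(str(exc))
            g = rdflib.Graph()
    raise ValueError("; ".join(errors))


def _ancestors(g: rdflib.Graph, cls: URIRef) -> set[URIRef]:
    out = {cls}
    frontier = [cls]
    while frontier:
        current = frontier.pop()
        for parent in g.objects(current, RDFS.subClassOf):
            if isinstance(parent, URIRef) and parent not in out:
                out.add(parent)
                frontier.append(parent)
    return out


def check_file(path: str | Path) -> tuple[bool, list[str], list[str]]:
    """Return (consistent, reasons, unsatisfiable_class_iris)."""
    g = _parse(Path(path))

    disjoint: set[frozenset[URIRef]] = set()
    for a, b in g.subject_objects(OWL.disjointWith):
        if isinstance(a, URIRef) and isinstance(b, URIRef):
            disjoint.add(frozenset((a, b)))

    reasons: list[str] = []

    typed: dict[URIRef, set[URIRef]] = {}
    for s, o in g.subject_objects(RDF.type):
        if isinstance(s, URIRef) and isinstance(o, URIRef):
            typed.setdefault(s, set()).add(o)

    for individual, classes in sorted(typed.items()):
        if OWL.Nothing in classes:
            reasons.append(f"{individual} is typed to owl:Nothing")
        closure: dict[URIRef, set[URIRef]] = {
            c: _ancestors(g, c) for c in classes if c != OWL.NamedIndividual
        }
        for c1, c2 in combinations(sorted(closure), 2):
            for pair in disjoint:
                a, b = tuple(pair)
                if (a in closure[c1] and b in closure[c2]) or (
                    b in closure[c1] and a in closure[c2]
                ):
                    reasons.append(
                        f"{individual} is typed to disjoint classes {c1} and {c2}"
                    )

    same = {
        frozenset((s, o))
        for s, o in g.subject_objects(OWL.sameAs)
        if isinstance(s, URIRef) and isinstance(o, URIRef)
    }
    different = {
        frozenset((s, o))
        for s, o in g.subject_objects(OWL.differentFrom)
        if isinstance(s, URIRef) and isinstance(o, URIRef)
    }
    for pair in sorted(same & different, key=lambda p: sorted(map(str, p))):
        a, b = sorted(map(str, pair))
        reasons.append(f"{a} and {b} asserted both sameAs and differentFrom")

    unsat: list[str] = []
    classes = {
        s for s in g.subjects(RDF.type, OWL.Class) if isinstance(s, URIRef)
    }
    for cls in sorted(classes):
        anc = _ancestors(g, cls)
        if any(pair <= anc for pair in disjoint) or OWL.Nothing in anc - {cls}:
            unsat.append(str(cls))

    return (not reasons, reasons, unsat)


def main(argv: list[str] | None = None) -> int:
    argv = sys.argv[1:] if argv is None else argv
    if len(argv) != 1:
        print("usage: python -m bpmnkg.dlcheck <owl-file>", file=sys.stderr)
        return 2
    try:
        consistent, reasons, unsat = check_file(argv[0])
    except (OSError, ValueError) as exc:
        print(f"cannot read ontology: {exc}", file=sys.stderr)
        return 2
    if consistent:
        print("consistent")
    else:
        for reason in reasons:
            print(f"inconsistent: {reason}")
    for cls in unsat:
        print(f"unsatisfiable: {cls}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
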