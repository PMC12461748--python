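# bpmnkg

**bpmnkg** renders tabular descriptions of BPMN process models as OWL2
knowledge graphs conforming to the BPMN-Based Ontology (BBO), and validates
the result. It was built for patient-facing clinical process models —
specifically colonoscopy-preparation instructions (laxative intake, diet
restriction, timed steps) modeled from the patient's perspective — but works
for any process expressible in the four-column dialect below.

## Who it is for

Health-informatics and knowledge-engineering teams who author BPMN process
models (e.g. in a diagramming tool), transcribe them into a spreadsheet, and
need a machine-readable, logically checkable knowledge base as the substrate
for downstream ICT tools (reminder systems, dialog agents, decision
support).

## The model

The input is a table `T` of rows `r = {i, x, y, g}`: an element identifier
*i*, a human-readable action label *x*, a BBO class *y* (Task, Gateway,
StartEvent, EndEvent, TimerEvent, Resource, ConditionalExpression, …) and an
optional link target *g*. Extraction splits `T` into a node collection
`Nᶜ` (one node per distinct identifier) and a sequence collection `Sᶜ`
(one directed source→target link per non-empty target).

Encoding maps the collections into an OWL2 ABox `O = {iₙ, lₙ}`:

* each node *n* becomes a named individual typed to its BBO class, labeled
  with `rdfs:label`;
* each sequence *s* is **reified** as a `SequenceFlow` individual with
  `has_sourceRef`/`has_targetRef` links to the endpoint individuals
  (`lₙ = L(r·iₙ, r·iₙ)`);
* one `Process` individual, labeled with the process name, is linked to
  every element and flow individual via `has_flowElements`.

Individuals are minted with OBO-Foundry-style zero-padded seven-digit
serials (`0000028`) in a deterministic order — Process first, elements in
table order, flows in sequence order — so identical inputs yield
byte-identical exports. Individuals can carry SNOMED CT / RxNorm
cross-reference annotations. Validation is two-layered: native structural
rules (known classes, resolvable flow endpoints, event direction,
process attachment, reachability, identifier hygiene) plus an optional
external description-logic reasoner invoked as a subprocess for consistency
and satisfiability.

## Worked example

`demo.csv`, a five-row excerpt of a MiraLAX preparation model:

```csv
ID,ACTION,Type,TARGET
AD1_22,Clock at 8PM,http://BPMNbasedOntology#TimerEvent,AD1_23
AD1_24,2×Dulcolax,http://BPMNbasedOntology#Resource,AD1_23
AD1_25,8oz Clear Liquid,http://BPMNbasedOntology#Resource,AD1_23
AD1_23,Take Dulcolax tablet,http://BPMNbasedOntology#Task,AD1_26
AD1_26,Hydrate w/clear liquid,http://BPMNbasedOntology#Task,AD1_27
```

```sh
$ bpmnkg convert --input demo.csv --name "MiraLAX Process" --out demo.owl
[WARNING] dangling-target: AD1_27: target 'AD1_27' has no defining row
{"instances": 10, "triples": 33}
```

The five rows define five elements; the last row's target (`AD1_27`) has no
defining row in the excerpt, so the linter warns and the lenient encoder
drops that one link. The resulting graph holds 10 individuals — 1 Process +
5 elements + 4 retained SequenceFlows — and 33 ABox triples (types, labels,
endpoint refs, attachments). `demo.owl` is RDF/XML; `--format turtle`
writes Turtle instead, and `--strict` turns the dangling target into a
fatal error.

```sh
$ bpmnkg validate demo.owl --reasoner-cmd "python -m bpmnkg.dlcheck {input}"
[INFO   ] logical-consistent: demo.owl: reasoner reports the ontology consistent and all classes satisfiable
passed (logical+structural)
```

(`bpmnkg.dlcheck` is a minimal bundled ABox clash detector; any reasoner
CLI that prints its verdict can be plugged in via `--reasoner-cmd`.)

Other commands: `bpmnkg stats g.owl` prints `{"instances": N, "triples": M}`
for an existing graph file; `bpmnkg generate --tasks 10 --gateways 2
--resources 5 --seed 42 --out t.csv` writes a random well-formed process
table for testing.

The same pipeline is available as a library:

```python
from bpmnkg import extract, encode, export, stats, table4_fixture

nodes, sequences = extract(table4_fixture())
graph = encode(nodes, sequences, "MiraLAX Process")
stats(graph).as_dict()   # {'instances': 10, 'triples': 33}
export(graph, "demo.owl")
```

## Layout

| Module | Role |
| --- | --- |
| `bpmnkg.tabular` | read/lint the four-column dialect, extract collections |
| `bpmnkg.bbo` | BBO class/property vocabulary, optional TBox loading |
| `bpmnkg.encoder` | ABox encoding, identifier minting, export/load, stats |
| `bpmnkg.validator` | structural rules + external reasoner hook |
| `bpmnkg.dlcheck` | bundled minimal ABox clash detector |
| `bpmnkg.synth` | synthetic process generator and packaged fixtures |
| `bpmnkg.cli` | `bpmnkg convert / validate / stats / generate` |

See `docs/methods.md` for the design notes and known limitations.
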