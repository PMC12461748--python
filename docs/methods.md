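# Methods and design notes

## Problem and scope

The engine converts hand-transcribed BPMN process models — tables in which
each row declares one process element and at most one outgoing link — into
instance-level OWL2 knowledge graphs under the BPMN-Based Ontology (BBO)
schema, then checks the result structurally and, optionally, logically.
It deliberately does **not** parse BPMN 2.0 XML interchange files, author
TBox axioms, or execute process semantics; the unit of work is the tabular
transcription of a reviewed diagram.

## Input dialect

Required header: `ID, ACTION, Type, TARGET` (case-insensitive, any column
order; CSV, TSV or XLSX; UTF-8 throughout — labels such as “2×Dulcolax”
contain non-ASCII characters). Cells are trimmed; empty `TARGET` means "no
outgoing link"; an empty or whitespace-containing `ID` is fatal. A
multi-way fan-out is written either as repeated rows sharing
`ID/ACTION/Type` or as one row with a semicolon-separated `TARGET` list;
the published tables do not reveal which spelling their authors used, so
both normalize to the same internal rows. Duplicate `(ID, TARGET)` pairs
are deduplicated with a warning. `Type` accepts the full class IRI
(`http://BPMNbasedOntology#Task`) or the bare local name (`Task`),
case-sensitively.

## Vocabulary

The built-in vocabulary is the ten instance-facing BBO core classes:
Process, Task, SequenceFlow, Gateway, StartEvent, EndEvent, TimerEvent,
ConditionalExpression, InputOutputSpecification, Resource, under the
configurable default namespace `http://BPMNbasedOntology#`. The linking
properties are `has_flowElements`, `has_sourceRef` and `has_targetRef` in
the same namespace (`has_sourceRef`/`has_targetRef` follow BPMN 2.0
terminology; the published figures show reified flows but not the property
names, so these are engine conventions and overridable). Labels use
`rdfs:label`, bare literals by default (`label_lang` adds a language tag).
Cross-references use `oboInOwl:hasDbXref` with SNOMED CT codes expanded to
`http://snomed.info/id/<code>` and RxNorm codes to the BioPortal RxNorm
namespace. A published BBO TBox can be loaded to extend the class set and
to be `owl:imports`-ed by exports; only the instance-facing vocabulary is
modeled, never the full axiomatization.

## Encoding

Minting order is fixed: the Process individual takes serial 1, element
individuals follow in first-appearance table order, then one SequenceFlow
individual per retained sequence in sequence order. Serials render as
zero-padded seven-digit local names (capacity 9 999 999; exceeding it is an
error). No assignment order is documented for the original graphs, so this
rule was chosen for reproducibility: identical input + config ⇒
byte-identical output, which the tests verify across processes with
different hash randomization.

Sequences whose target identifier has no defining row are dropped with a
warning in lenient mode (the packaged five-row excerpt itself ends in such
a link, so lenient is the default) and are fatal in strict mode.
Resource→Task links are reified exactly like Task→Task links, since
SequenceFlow is defined as the sequential link between Tasks and Resources;
no InputOutputSpecification individuals are auto-created.
ConditionalExpression rows are ordinary typed, labeled individuals — no
expression language is evaluated.

## Serialization

Default export is RDF/XML with an `owl:Ontology` header (plus
`owl:imports` when a TBox is attached); Turtle is offered for diffability.
RDF/XML is written by a small canonical writer (subjects in minting order,
fixed predicate order) because the general-purpose serializer orders
subjects hash-dependently, which would break byte determinism; Turtle goes
through rdflib, whose sorted serializer is already stable. Both formats
parse back (via rdflib) to identical triple sets, and `load()` reconstructs
the in-memory graph from either. Individuals typed to classes outside the
vocabulary are preserved on load and flagged for the validator.

## Statistics

`instance_count` = named individuals = 1 (Process) + elements + retained
flows. `triple_count` = asserted ABox statements: one `rdf:type` per
individual, one `rdfs:label` per labeled individual (empty labels are not
asserted), two endpoint refs per flow, one `has_flowElements` per element
and flow, plus cross-reference annotations. The ontology header is not
instance data and is excluded. The published per-graph statistics do not
state their counting basis (whether the Process individual or the header
is included); this basis is the engine's own, chosen so that
`instances = 1 + |Nᶜ| + |retained Sᶜ|` holds exactly and is verified
against brute-force enumeration of the serialized files.

## Validation

Structural rules (report-only, pure):

* **R1** every element is typed to a vocabulary class;
* **R2** every flow's source and target exist and are flow-node, resource
  or metadata individuals — never the Process, never another flow;
* **R3** no StartEvent has an incoming flow, no EndEvent an outgoing one;
* **R4** every element and flow individual is attached to the Process via
  `has_flowElements`;
* **R5** every flow-node element is reachable from a StartEvent along
  sequence flows (warning only; resources and conditions feed *into* the
  control flow rather than being reached by it, so they are exempt);
* **R6** identifiers are unique seven-digit serials.

R3 and R5 are engine-level conventions — the minimal vocabulary carries no
domain/range axioms that could be violated — and can be switched off.

Logical checking delegates to an external reasoner through a command
template (`reasoner_cmd` with an `{input}` placeholder); the verdict is
parsed from its standard output (*inconsistent*, *unsatisfiable: C*).
Without a configured reasoner the logical check degrades to an
informational "skipped" finding on top of the structural report. The
bundled `bpmnkg.dlcheck` is a minimal ABox clash detector — explicit
disjointness violations, `owl:Nothing` typing, `sameAs`/`differentFrom`
clashes — not a tableau reasoner; for the purely positive ABox graphs this
engine emits, those explicit clashes are the only statable contradictions,
so its clean verdict coincides with a full reasoner's on them, but it must
not be relied on for ontologies with richer TBoxes.

## Synthetic fixtures

The deposited process models live in an external repository; the package
must be testable without downloads, so `bpmnkg.synth` provides:

* `table4_fixture()` — the five-row printed worked excerpt (IDs
  AD1_22–AD1_26), dangling final target included;
* `miralax_like_fixture()` — a complete, hand-written, physician-plausible
  MiraLAX/Gatorade-style preparation process (40 rows: 19 tasks, 9
  resources, 6 timers, a 2-branch split/merge gateway pair with a
  condition, start/end events). It is a *synthetic stand-in*, not a copy
  of any deposited model, so its statistics (79 instances, 275 triples)
  are the engine's own, not comparisons against published counts;
* `generate_process(cfg)` — seeded random models: a Start→tasks→End
  backbone, gateway blocks (split + merge, `branch_factor` single-task
  branches) spliced at random positions, timers interposed before distinct
  random tasks, resources feeding uniformly chosen tasks. One
  `random.Random(seed)` stream; no global randomness. Every emitted table
  is strict-lint-clean by construction and the node count is exactly
  `2 + tasks + 2·gateways + timers + resources`.

What the generator does **not** emulate: free-text noise and typos in
hand-transcribed spreadsheets, cyclic or disconnected diagrams, multi-sheet
workbooks, and clinically meaningful orderings — labels are drawn from a
small preparation-themed bank purely for readability. Passing tests
therefore demonstrate structural correctness of the pipeline, not clinical
validity of any generated instruction sequence.

## Problem sizes and numerical choices

The property sweep uses 100 seeded fixtures of 6–25 elements each — large
enough to hit every element class and gateway/timer interaction, small
enough that the full suite runs in seconds. There are no floating-point
tolerances anywhere: every compared quantity (counts, byte equality, triple
sets) is exact. Tie-breaks are by first occurrence (node order, first
label/type on load) or lexicographic sort (load order, report ordering).
Degenerate inputs: a header-only table encodes to a graph of exactly one
individual (the Process) and two triples; self-loops are linted but
encodable; an element redefined with a conflicting label or class is an
error rather than a silent overwrite.

## Known limitations

* Exit-level agreement with the deposited `*_KG.owl` artifacts (exact
  instance/triple counts of the four published graphs) requires fetching
  them; the engine's counting basis may differ from theirs until calibrated
  against those files.
* `load()` targets the two serializations the engine writes (RDF/XML,
  Turtle); other RDF formats must be converted first.
* The structural reachability rule treats flows as a directed graph and
  does not model gateway semantics (exclusive vs. parallel), which BPMN
  distinguishes but the four-column dialect does not record.
* `dlcheck` detects only explicitly asserted clashes (see above).
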