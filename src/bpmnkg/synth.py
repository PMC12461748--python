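"""Synthetic process tables and packaged worked examples.

Real colonoscopy-preparation models are hand-authored and deposited
externally; everything here is generated or reconstructed so the engine is
fully testable offline.  :func:`generate_process` emits random but
structurally well-formed tables (single StartEvent, acyclic flow, every node
connected); :func:`table4_fixture` is the five-row printed worked example;
:func:`miralax_like_fixture` is a complete synthetic preparation process in
the same dialect — a plausible reconstruction, not a copy of any deposited
model.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .bbo import DEFAULT_NAMESPACE
from .errors import ConfigError
from .tabular import ProcessTable, RawRow

_NS = DEFAULT_NAMESPACE

_TASK_LABELS = (
    "Drink 8oz of prep solution",
    "Take laxative dose",
    "Hydrate with clear liquid",
    "Check preparation instructions",
    "Record bowel movement",
    "Rest near a bathroom",
    "Mix laxative powder",
    "Stop solid food intake",
    "Continue clear liquid diet",
    "Confirm appointment time",
)

_RESOURCE_LABELS = (
    "Laxative sachet",
    "Sports drink bottle",
    "Clear broth",
    "Instruction pamphlet",
    "Glass of water",
)

_TIMER_LABELS = (
    "Clock at 6AM",
    "Clock at noon",
    "Clock at 4PM",
    "Clock at 8PM",
    "Two hours before procedure",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Size and randomness knobs for synthetic process models.

    A generated model always has exactly one StartEvent and one EndEvent,
    an acyclic flow connected from the start, ``n_tasks`` tasks,
    ``n_gateways`` split/merge gateway pairs each fanning out to
    ``branch_factor`` single-task branches, ``n_timers`` timer events
    interposed before distinct tasks, and ``n_resources`` resources each
    feeding a uniformly chosen task.
    """

    n_tasks: int
    n_gateways: int = 0
    n_resources: int = 0
    branch_factor: int = 2
    n_timers: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_tasks < 1:
            raise ConfigError("n_tasks must be >= 1")
        if min(self.n_gateways, self.n_resources, self.n_timers) < 0:
            raise ConfigError("counts must be non-negative")
        if self.branch_factor < 2:
            raise ConfigError("branch_factor must be >= 2")
        if self.n_gateways and self.n_gateways * self.branch_factor > self.n_tasks:
            raise ConfigError(
                f"{self.n_gateways} gateway(s) with branch_factor "
                f"{self.branch_factor} need at least "
                f"{self.n_gateways * self.branch_factor} tasks, "
                f"got {self.n_tasks}"
            )
        if self.n_timers > self.n_tasks:
            raise ConfigError("at most one timer per task")

    @property
    def expected_node_count(self) -> int:
        """Start + End + tasks + 2 per gateway (split+merge) + timers + resources."""
        return 2 + self.n_tasks + 2 * self.n_gateways + self.n_timers + self.n_resources


def generate_process(config: GeneratorConfig) -> ProcessTable:
    """Emit a random well-formed process table, deterministic in ``seed``."""
    config.validate()
    rng = random.Random(config.seed)

    counter = 0
    nodes: list[tuple[str, str, str]] = []  # (id, label, class local name)

    def add_node(label: str, cls: str) -> str:
        nonlocal counter
        counter += 1
        eid = f"SY_{counter:04d}"
        nodes.append((eid, label, cls))
        return eid

    def task_label(i: int) -> str:
        base = _TASK_LABELS[i % len(_TASK_LABELS)]
        return base if i < len(_TASK_LABELS) else f"{base} (step {i + 1})"

    start = add_node("Begin preparation", "StartEvent")

    task_ids = [add_node(task_label(i), "Task") for i in range(config.n_tasks)]
    pool = list(task_ids)
    gateway_branches: list[list[str]] = []
    for _ in range(config.n_gateways):
        branches = [pool.pop() for _ in range(config.branch_factor)]
        gateway_branches.append(branches)

    # segments: plain tasks plus gateway blocks spliced in at random positions
    segments: list[tuple[str, object]] = [("task", tid) for tid in pool]
    for branches in gateway_branches:
        split = add_node("Choose next step", "Gateway")
        merge = add_node("Paths rejoin", "Gateway")
        position = rng.randint(0, len(segments))
        segments.insert(position, ("gateway", (split, merge, branches)))

    edges: list[tuple[str, str]] = []
    cursor = start
    for kind, payload in segments:
        if kind == "task":
            edges.append((cursor, payload))  # type: ignore[arg-type]
            cursor = payload  # type: ignore[assignment]
        else:
            split, merge, branches = payload  # type: ignore[misc]
            edges.append((cursor, split))
            for branch in branches:
                edges.append((split, branch))
                edges.append((branch, merge))
            cursor = merge
    end = add_node("Preparation complete", "EndEvent")
    edges.append((cursor, end))

    # interpose timers before distinct tasks: predecessors now point at the
    # timer, the timer points at the task
    for i, task in enumerate(sorted(rng.sample(task_ids, config.n_timers))):
        timer = add_node(_TIMER_LABELS[i % len(_TIMER_LABELS)], "TimerEvent")
        edges = [
            (src, timer) if dst == task else (src, dst) for src, dst in edges
        ]
        edges.append((timer, task))

    for i in range(config.n_resources):
        resource = add_node(
            _RESOURCE_LABELS[i % len(_RESOURCE_LABELS)]
            + ("" if i < len(_RESOURCE_LABELS) else f" #{i + 1}"),
            "Resource",
        )
        edges.append((resource, rng.choice(task_ids)))

    outgoing: dict[str, list[str]] = {eid: [] for eid, _, _ in nodes}
    for src, dst in edges:
        outgoing[src].append(dst)

    rows = [
        RawRow(eid, label, _NS + cls, target)
        for eid, label, cls in nodes
        for target in (outgoing[eid] or [""])
    ]
    return ProcessTable(
        process_name=f"Synthetic preparation process (seed {config.seed})",
        rows=rows,
        source_path="inline",
    )


def table4_fixture() -> ProcessTable:
    """The five-row printed worked example (an excerpt of a larger model).

    Note the last row's target (AD1_27) has no defining row in the excerpt:
    the linter reports it dangling and the lenient encoder drops that link.
    """
    rows = [
        RawRow("AD1_22", "Clock at 8PM", _NS + "TimerEvent", "AD1_23"),
        RawRow("AD1_24", "2×Dulcolax", _NS + "Resource", "AD1_23"),
        RawRow("AD1_25", "8oz Clear Liquid", _NS + "Resource", "AD1_23"),
        RawRow("AD1_23", "Take Dulcolax tablet", _NS + "Task", "AD1_26"),
        RawRow("AD1_26", "Hydrate w/clear liquid", _NS + "Task", "AD1_27"),
    ]
    return ProcessTable("MiraLAX Process", rows, "inline")


def miralax_like_fixture() -> ProcessTable:
    """A complete synthetic MiraLAX/Gatorade-style preparation process.

    Hand-written, physician-plausible and structurally clean (strict lint
    passes); it is a synthetic stand-in for the deposited models, not a copy
    of any of them.  Covers diet-restriction and laxative-intake tasks,
    timers, a split-dose gateway with a condition, and consumable resources.
    """
    t = _NS + "Task"
    r = _NS + "Resource"
    tm = _NS + "TimerEvent"
    g = _NS + "Gateway"
    rows = [
        RawRow("P_START", "Begin preparation", _NS + "StartEvent", "T01"),
        RawRow("T01", "Confirm colonoscopy appointment", t, "T15"),
        RawRow("R01", "Appointment instructions", r, "T01"),
        RawRow("T15", "Review medications with clinic", t, "T02"),
        RawRow("R07", "Medication list", r, "T15"),
        RawRow("T02", "Purchase preparation supplies", t, "T16"),
        RawRow("R02", "238g MiraLAX bottle", r, "T02"),
        RawRow("R03", "64oz Gatorade", r, "T02"),
        RawRow("R04", "2× Dulcolax tablets", r, "T02"),
        RawRow("T16", "Arrange transportation home", t, "TM0"),
        RawRow("TM0", "Two days before procedure", tm, "T17"),
        RawRow("T17", "Eat light low-fiber meals", t, "T03"),
        RawRow("T03", "Stop eating solid food", t, "TM1"),
        RawRow("TM1", "Morning before procedure", tm, "T04"),
        RawRow("T04", "Begin clear liquid diet", t, "T05"),
        RawRow("R05", "Clear liquids", r, "T04"),
        RawRow("T05", "Mix MiraLAX with 64oz Gatorade", t, "T06"),
        RawRow("T06", "Chill laxative mixture", t, "TM2"),
        RawRow("TM2", "Clock at 4PM", tm, "T07"),
        RawRow("T07", "Take Dulcolax tablets", t, "T08"),
        RawRow("T08", "Hydrate w/clear liquid", t, "TM3"),
        RawRow("TM3", "Clock at 6PM", tm, "G01"),
        RawRow("C01", "Procedure scheduled before noon", _NS + "ConditionalExpression", "G01"),
        RawRow("G01", "Split-dose regimen?", g, "T09"),
        RawRow("G01", "Split-dose regimen?", g, "T11"),
        RawRow("T09", "Drink 8oz mixture every 15 min", t, "T10"),
        RawRow("T10", "Finish remaining mixture tonight", t, "T18"),
        RawRow("T18", "Remain near a bathroom", t, "G02"),
        RawRow("R09", "Soothing wipes", r, "T18"),
        RawRow("T11", "Drink half mixture this evening", t, "TM4"),
        RawRow("TM4", "Five hours before procedure", tm, "T12"),
        RawRow("T12", "Drink remaining mixture", t, "G02"),
        RawRow("R08", "8oz clear liquid", r, "T12"),
        RawRow("G02", "Doses complete", g, "T13"),
        RawRow("T13", "Continue clear liquids until cutoff", t, "TM5"),
        RawRow("R06", "Water or sports drink", r, "T13"),
        RawRow("TM5", "Two hours before procedure", tm, "T14"),
        RawRow("T14", "Stop all food and drink", t, "T19"),
        RawRow("T19", "Pack for the appointment", t, "P_END"),
        RawRow("P_END", "Preparation complete", _NS + "EndEvent", ""),
    ]
    return ProcessTable("MiraLAX Gatorade Preparation (synthetic)", rows, "inline")
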