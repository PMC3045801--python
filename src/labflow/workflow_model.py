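"""In-memory model of a laboratory workflow definition and its static validation.

A workflow definition describes one laboratory's process: the *activities*
(bench steps such as "RNA Extraction"), the *transitions* that order them,
the typed, constrained *attributes* each activity records, and the declared
input/output *artifact* classes (with cardinalities) through which results of
one activity become inputs of later ones.

The model is deliberately declarative: nothing here executes.  Runtime state
(projects, experiments, per-sample traces) lives in :mod:`labflow.engine`;
reading and writing the XPDL file format lives in :mod:`labflow.xpdl_io`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "Datatype",
    "Direction",
    "AttributeSpec",
    "IOSpec",
    "ActivitySpec",
    "TransitionSpec",
    "WorkflowDefinition",
    "Issue",
    "DefinitionError",
    "validate_definition",
    "start_activities",
    "successors",
    "topological_order",
    "terminal_activities",
]


class Datatype(str, Enum):
    """Value types an activity attribute may take."""

    STRING = "string"
    INTEGER = "integer"
    REAL = "real"
    DATE = "date"
    FILE = "file"


NUMERIC_TYPES = frozenset({Datatype.INTEGER, Datatype.REAL})


class Direction(str, Enum):
    INPUT = "input"
    OUTPUT = "output"


# Activity / transition / workflow identifiers follow the XML NCName shape;
# display names and attribute names are unrestricted non-empty strings.
NCNAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.\-]*$")


class DefinitionError(ValueError):
    """A workflow definition violates a structural rule that blocks use."""


@dataclass(frozen=True)
class AttributeSpec:
    """One typed, constrained data field of an activity or artifact.

    Parameters
    ----------
    name:
        Field label shown on the entry form (spaces allowed, e.g.
        ``"RNA total concentration"``).
    datatype:
        One of ``string``, ``integer``, ``real``, ``date``, ``file``.
    required:
        "Not null": the value must always be filled at execution time.
    format:
        Optional pattern — a regular expression for strings, a
        ``strftime``/``strptime`` pattern for dates (default ISO-8601,
        ``%Y-%m-%d``).
    allowed_values:
        Optional ordered list of literals (rendered as a dropdown in a GUI);
        any entered value must equal one of them after parsing.
    numeric_range:
        Optional ``(min, max)`` bounds for integer/real values; either end
        may be ``None`` (open).
    derivation:
        Optional arithmetic expression over *sibling* attribute names; the
        value is auto-calculated, never typed by the operator.
    documentation:
        Free-text help for the operator.
    """

    name: str
    datatype: Datatype
    required: bool = False
    format: str | None = None
    allowed_values: tuple[str, ...] | None = None
    numeric_range: tuple[float | None, float | None] | None = None
    derivation: str | None = None
    documentation: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "datatype", Datatype(self.datatype))
        if self.allowed_values is not None:
            object.__setattr__(
                self, "allowed_values", tuple(str(v) for v in self.allowed_values)
            )
        if self.numeric_range is not None:
            lo, hi = self.numeric_range
            object.__setattr__(
                self,
                "numeric_range",
                (
                    None if lo is None else float(lo),
                    None if hi is None else float(hi),
                ),
            )


@dataclass(frozen=True)
class IOSpec:
    """A declared input or output artifact class of an activity.

    ``min_count``/``max_count`` bound how many artifact instances of
    ``artifact_type`` one execution consumes (inputs) or produces (outputs);
    ``max_count=None`` means unbounded.  ``attributes`` is the schema of the
    data carried by each artifact instance.
    """

    artifact_type: str
    direction: Direction
    attributes: tuple[AttributeSpec, ...] = ()
    min_count: int = 1
    max_count: int | None = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction(self.direction))
        object.__setattr__(self, "attributes", tuple(self.attributes))


@dataclass(frozen=True)
class ActivitySpec:
    """One step of the workflow with its form fields and artifact contracts."""

    id: str
    name: str = ""
    attributes: tuple[AttributeSpec, ...] = ()
    inputs: tuple[IOSpec, ...] = ()
    outputs: tuple[IOSpec, ...] = ()
    repeatable: bool = True
    documentation: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", tuple(self.attributes))
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(self, "outputs", tuple(self.outputs))
        doc = self.documentation
        if isinstance(doc, str):
            doc = (doc,)
        object.__setattr__(self, "documentation", tuple(doc))

    def attribute(self, name: str) -> AttributeSpec:
        for spec in self.attributes:
            if spec.name == name:
                return spec
        raise KeyError(name)


@dataclass(frozen=True)
class TransitionSpec:
    """A directed, unconditional edge between two activities."""

    id: str
    from_activity: str
    to_activity: str


@dataclass
class WorkflowDefinition:
    """A complete laboratory process: activities plus their ordering."""

    id: str
    name: str = ""
    version: str = "1.0"
    activities: dict[str, ActivitySpec] = field(default_factory=dict)
    transitions: tuple[TransitionSpec, ...] = ()

    def __post_init__(self) -> None:
        if not isinstance(self.activities, Mapping):
            self.activities = {a.id: a for a in self.activities}
        self.transitions = tuple(self.transitions)

    def activity(self, activity_id: str) -> ActivitySpec:
        try:
            return self.activities[activity_id]
        except KeyError:
            raise LookupError(f"unknown activity id: {activity_id!r}") from None


@dataclass(frozen=True)
class Issue:
    """One static-validation finding; ``severity`` is ``error`` or ``warning``."""

    severity: str
    code: str
    location: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.code} at {self.location}: {self.message}"


def _resolved_graph(w: WorkflowDefinition) -> nx.DiGraph:
    """Transition graph restricted to edges whose endpoints exist."""
    g = nx.DiGraph()
    g.add_nodes_from(w.activities)
    for t in w.transitions:
        if t.from_activity in w.activities and t.to_activity in w.activities:
            g.add_edge(t.from_activity, t.to_activity)
    return g


def _probe_date_format(fmt: str) -> bool:
    import datetime as _dt

    try:
        rendered = _dt.date(2004, 12, 31).strftime(fmt)
        _dt.datetime.strptime(rendered, fmt)
    except (ValueError, TypeError):
        return False
    # A pattern without any directive (e.g. "abc") renders but carries no
    # calendar information; reject it.
    return "%" in fmt and rendered != fmt


def validate_definition(w: WorkflowDefinition) -> list[Issue]:
    """Check every structural invariant of a workflow definition.

    Returns all violations at once (issues are data, not exceptions); the
    definition is executable iff no returned issue has severity ``error``.
    Unreachable activities are errors; outputs that no downstream activity
    ever consumes are warnings.
    """
    from .value_validation import parse_raw  # local import: avoids a cycle
    from .value_validation import expression_names

    issues: list[Issue] = []

    def err(code: str, loc: str, msg: str) -> None:
        issues.append(Issue("error", code, loc, msg))

    def warn(code: str, loc: str, msg: str) -> None:
        issues.append(Issue("warning", code, loc, msg))

    if not NCNAME_RE.match(w.id or ""):
        err("INVALID_IDENTIFIER", "workflow", f"workflow id {w.id!r} is not a valid identifier")

    def check_attributes(specs: tuple[AttributeSpec, ...], loc_prefix: str) -> None:
        seen: set[str] = set()
        names = {s.name for s in specs}
        numeric_names = {s.name for s in specs if s.datatype in NUMERIC_TYPES}
        for s in specs:
            loc = f"{loc_prefix}, attribute {s.name!r}"
            if not s.name:
                err("EMPTY_NAME", loc_prefix, "attribute with empty name")
                continue
            if s.name in seen:
                err("DUPLICATE_ATTRIBUTE", loc, "attribute name declared twice")
            seen.add(s.name)
            if s.allowed_values is not None:
                if len(s.allowed_values) == 0:
                    err("EMPTY_ALLOWED", loc, "allowed_values present but empty")
                elif s.datatype is Datatype.FILE:
                    err("ALLOWED_ON_FILE", loc, "allowed_values not supported on file attributes")
                else:
                    for lit in s.allowed_values:
                        _, code = parse_raw(s.datatype, lit, s.format)
                        if code is not None:
                            err(
                                "BAD_ALLOWED_LITERAL",
                                loc,
                                f"allowed value {lit!r} does not parse as {s.datatype.value}",
                            )
            if s.format is not None:
                if s.datatype is Datatype.STRING:
                    try:
                        re.compile(s.format)
                    except re.error as exc:
                        err("BAD_FORMAT", loc, f"invalid regular expression: {exc}")
                elif s.datatype is Datatype.DATE:
                    if not _probe_date_format(s.format):
                        err("BAD_FORMAT", loc, f"invalid date pattern {s.format!r}")
                else:
                    err(
                        "FORMAT_UNSUPPORTED",
                        loc,
                        f"format not supported on {s.datatype.value} attributes",
                    )
            if s.numeric_range is not None:
                if s.datatype not in NUMERIC_TYPES:
                    err(
                        "RANGE_UNSUPPORTED",
                        loc,
                        f"numeric_range not supported on {s.datatype.value} attributes",
                    )
                else:
                    lo, hi = s.numeric_range
                    if lo is not None and hi is not None and lo > hi:
                        err("BAD_RANGE", loc, f"range minimum {lo} exceeds maximum {hi}")
            if s.derivation is not None:
                if s.required:
                    err(
                        "DERIVED_REQUIRED",
                        loc,
                        "auto-calculated attribute cannot be marked required for entry",
                    )
                if s.datatype not in NUMERIC_TYPES:
                    err("DERIVED_NON_NUMERIC", loc, "auto-calculated attribute must be numeric")
                try:
                    refs = expression_names(s.derivation)
                except ValueError as exc:
                    err("DERIVATION_SYNTAX", loc, f"cannot parse derivation: {exc}")
                else:
                    for ref in sorted(refs):
                        if ref == s.name or ref not in names:
                            err(
                                "DERIVATION_UNKNOWN_NAME",
                                loc,
                                f"derivation references unknown sibling {ref!r}",
                            )
                        elif ref not in numeric_names:
                            err(
                                "DERIVATION_NON_NUMERIC",
                                loc,
                                f"derivation references non-numeric sibling {ref!r}",
                            )

    for aid, act in w.activities.items():
        loc = f"activity {aid}"
        if aid != act.id:
            err("MISMATCHED_ID", loc, f"map key {aid!r} differs from activity id {act.id!r}")
        if not NCNAME_RE.match(act.id or ""):
            err("INVALID_IDENTIFIER", loc, f"activity id {act.id!r} is not a valid identifier")
        check_attributes(act.attributes, loc)
        for io in act.inputs + act.outputs:
            io_loc = f"{loc}, {io.direction.value} {io.artifact_type!r}"
            expected = Direction.INPUT if io in act.inputs else Direction.OUTPUT
            if io.direction is not expected:
                err("BAD_DIRECTION", io_loc, f"declared under {expected.value}s")
            if io.min_count < 0 or (io.max_count is not None and io.max_count < 1):
                err("BAD_CARDINALITY", io_loc, "counts must satisfy min >= 0 and max >= 1")
            elif io.max_count is not None and io.min_count > io.max_count:
                err(
                    "BAD_CARDINALITY",
                    io_loc,
                    f"min_count {io.min_count} exceeds max_count {io.max_count}",
                )
            check_attributes(io.attributes, io_loc)

    for t in w.transitions:
        loc = f"transition {t.id}"
        if t.from_activity not in w.activities or t.to_activity not in w.activities:
            err(
                "DANGLING_TRANSITION",
                loc,
                f"references undeclared activity "
                f"({t.from_activity!r} -> {t.to_activity!r})",
            )
        elif t.from_activity == t.to_activity:
            err(
                "SELF_LOOP",
                loc,
                "self-transition not allowed; re-runs are engine-level repetition",
            )

    g = _resolved_graph(w)
    acyclic = nx.is_directed_acyclic_graph(g)
    if not acyclic:
        cycle = nx.find_cycle(g)
        err(
            "CYCLE",
            "workflow",
            "transition graph contains a cycle: "
            + " -> ".join(edge[0] for edge in cycle)
            + f" -> {cycle[0][0]}",
        )

    starts = {a for a in g.nodes if g.in_degree(a) == 0}
    if w.activities and not starts:
        err("NO_START", "workflow", "no activity without incoming transitions")
    reachable: set[str] = set()
    for s in starts:
        reachable |= {s} | nx.descendants(g, s)
    for aid in w.activities:
        if aid not in reachable and starts:
            err("UNREACHABLE_ACTIVITY", f"activity {aid}", "not reachable from any start activity")

    # Artifact plumbing: every declared input must be producible upstream,
    # and outputs nobody can ever consume are suspicious but not fatal.
    for aid, act in w.activities.items():
        ancestors = nx.ancestors(g, aid) if aid in g else set()
        for io in act.inputs:
            produced = any(
                out.artifact_type == io.artifact_type
                for anc in ancestors
                for out in w.activities[anc].outputs
            )
            if not produced:
                err(
                    "UNSATISFIABLE_INPUT",
                    f"activity {aid}",
                    f"input artifact type {io.artifact_type!r} is not produced by any "
                    "activity that can precede it",
                )
        descendants = nx.descendants(g, aid) if aid in g else set()
        for io in act.outputs:
            consumed = any(
                inp.artifact_type == io.artifact_type
                for desc in descendants
                for inp in w.activities[desc].inputs
            )
            if not consumed:
                warn(
                    "UNCONSUMED_OUTPUT",
                    f"activity {aid}",
                    f"output artifact type {io.artifact_type!r} is never consumed downstream",
                )

    return issues


def has_errors(issues: Iterable[Issue]) -> bool:
    return any(i.severity == "error" for i in issues)


def _require_valid(w: WorkflowDefinition) -> None:
    issues = validate_definition(w)
    if has_errors(issues):
        detail = "; ".join(str(i) for i in issues if i.severity == "error")
        raise DefinitionError(f"workflow {w.id!r} is not executable: {detail}")


def start_activities(w: WorkflowDefinition, *, validated: bool = False) -> set[str]:
    """Activities with no incoming transition (where every sample trace begins)."""
    if not validated:
        _require_valid(w)
    targets = {t.to_activity for t in w.transitions}
    return {aid for aid in w.activities if aid not in targets}


def successors(w: WorkflowDefinition, activity_id: str) -> set[str]:
    """All activities directly reachable from ``activity_id``."""
    if activity_id not in w.activities:
        raise LookupError(f"unknown activity id: {activity_id!r}")
    return {t.to_activity for t in w.transitions if t.from_activity == activity_id}


def terminal_activities(w: WorkflowDefinition) -> set[str]:
    """Activities with no outgoing transition (workflow end points)."""
    sources = {t.from_activity for t in w.transitions}
    return {aid for aid in w.activities if aid not in sources}


def topological_order(w: WorkflowDefinition) -> list[str]:
    """Activities in execution order, stable w.r.t. declaration order."""
    g = _resolved_graph(w)
    order_index = {aid: i for i, aid in enumerate(w.activities)}
    return list(nx.lexicographical_topological_sort(g, key=lambda a: order_index[a]))


# ---------------------------------------------------------------------------
# Plain-dict (de)serialisation, shared by the snapshot store and the XPDL
# extension payloads.
# ---------------------------------------------------------------------------

def attribute_to_dict(s: AttributeSpec) -> dict:
    return {
        "name": s.name,
        "datatype": s.datatype.value,
        "required": s.required,
        "format": s.format,
        "allowed": None if s.allowed_values is None else list(s.allowed_values),
        "range": None if s.numeric_range is None else list(s.numeric_range),
        "derivation": s.derivation,
        "doc": s.documentation,
    }


def attribute_from_dict(d: Mapping) -> AttributeSpec:
    rng = d.get("range")
    return AttributeSpec(
        name=d["name"],
        datatype=Datatype(d["datatype"]),
        required=bool(d.get("required", False)),
        format=d.get("format"),
        allowed_values=None if d.get("allowed") is None else tuple(d["allowed"]),
        numeric_range=None if rng is None else (rng[0], rng[1]),
        derivation=d.get("derivation"),
        documentation=d.get("doc"),
    )


def iospec_to_dict(io: IOSpec) -> dict:
    return {
        "artifact_type": io.artifact_type,
        "min": io.min_count,
        "max": io.max_count,
        "attributes": [attribute_to_dict(a) for a in io.attributes],
    }


def iospec_from_dict(d: Mapping, direction: Direction) -> IOSpec:
    return IOSpec(
        artifact_type=d["artifact_type"],
        direction=direction,
        attributes=tuple(attribute_from_dict(a) for a in d.get("attributes", ())),
        min_count=int(d.get("min", 1)),
        max_count=None if d.get("max") is None else int(d["max"]),
    )


def activity_to_dict(a: ActivitySpec) -> dict:
    return {
        "id": a.id,
        "name": a.name,
        "attributes": [attribute_to_dict(s) for s in a.attributes],
        "inputs": [iospec_to_dict(io) for io in a.inputs],
        "outputs": [iospec_to_dict(io) for io in a.outputs],
        "repeatable": a.repeatable,
        "documentation": list(a.documentation),
    }


def activity_from_dict(d: Mapping) -> ActivitySpec:
    return ActivitySpec(
        id=d["id"],
        name=d.get("name", ""),
        attributes=tuple(attribute_from_dict(s) for s in d.get("attributes", ())),
        inputs=tuple(iospec_from_dict(io, Direction.INPUT) for io in d.get("inputs", ())),
        outputs=tuple(iospec_from_dict(io, Direction.OUTPUT) for io in d.get("outputs", ())),
        repeatable=bool(d.get("repeatable", True)),
        documentation=tuple(d.get("documentation", ())),
    )


def workflow_to_dict(w: WorkflowDefinition) -> dict:
    return {
        "id": w.id,
        "name": w.name,
        "version": w.version,
        "activities": [activity_to_dict(a) for a in w.activities.values()],
        "transitions": [
            {"id": t.id, "from": t.from_activity, "to": t.to_activity} for t in w.transitions
        ],
    }


def workflow_from_dict(d: Mapping) -> WorkflowDefinition:
    return WorkflowDefinition(
        id=d["id"],
        name=d.get("name", ""),
        version=d.get("version", "1.0"),
        activities={a["id"]: activity_from_dict(a) for a in d.get("activities", ())},
        transitions=tuple(
            TransitionSpec(t["id"], t["from"], t["to"]) for t in d.get("transitions", ())
        ),
    )
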