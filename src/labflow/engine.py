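"""Runtime engine: projects, experiments, per-sample traces, execution,
repetition and artifact provenance.

The organising hierarchy mirrors laboratory practice: a *project* holds
*experiments*; within an experiment every registered biological sample is an
independent *trace* through the workflow.  Executing an activity on a trace
appends an immutable :class:`ActivityExecution` record (who, when, validated
values), consumes previously produced :class:`Artifact` instances under the
activity's input cardinality rules, and produces new artifacts consumable
downstream.  Repeating an already-executed activity (the everyday "the gel
was unclear, run it again") appends a new record with an incremented
repetition index — history is append-only, and earlier downstream results are
never invalidated.

Determinism is injectable: a :class:`FixedClock` and a seeded id generator
make a replayed run byte-identical, which is what the audit log format is
built around (one JSON record per execution, canonical key order).
"""

from __future__ import annotations

import copy
import datetime as dt
import json
import random
import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from . import workflow_model as wm
from .value_validation import (
    FileRef,
    FormResult,
    TypedValue,
    ValidationError,
    validate_attributes,
)

__all__ = [
    "Project",
    "Experiment",
    "SampleTrace",
    "ActivityExecution",
    "Artifact",
    "EngineError",
    "EngineIssue",
    "ExecutionRefused",
    "SystemClock",
    "FixedClock",
    "Lims",
    "compute_available",
]


# ---------------------------------------------------------------------------
# Runtime records
# ---------------------------------------------------------------------------


@dataclass
class Project:
    id: str
    name: str
    created_at: dt.datetime
    created_by: str
    experiment_ids: list[str] = field(default_factory=list)


@dataclass
class Experiment:
    """A run of one workflow; the definition is frozen at creation time, so
    later edits to the loaded workflow never alter a running experiment."""

    id: str
    project_id: str
    workflow: wm.WorkflowDefinition
    created_at: dt.datetime
    created_by: str
    trace_ids: list[str] = field(default_factory=list)

    @property
    def workflow_id(self) -> str:
        return self.workflow.id

    @property
    def workflow_version(self) -> str:
        return self.workflow.version


@dataclass
class SampleTrace:
    """The independent execution history of one sample (one grid row)."""

    id: str
    experiment_id: str
    sample_label: str
    execution_ids: list[str] = field(default_factory=list)


@dataclass
class ActivityExecution:
    id: str
    trace_id: str
    activity_id: str
    repetition_index: int
    executed_at: dt.datetime
    executed_by: str
    values: dict[str, TypedValue]
    consumed_artifacts: list[str]
    produced_artifacts: list[str]
    status: str = "completed"


@dataclass
class Artifact:
    """A produced data object (extracted RNA, a labeled sample, a slide, …)."""

    id: str
    experiment_id: str
    artifact_type: str
    values: dict[str, TypedValue]
    produced_by: str
    consumed_by: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EngineIssue:
    """A structured refusal reason from input selection or availability."""

    code: str
    message: str
    attribute: str | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.code}: {self.message}"


class EngineError(RuntimeError):
    def __init__(self, code: str, message: str):
        super().__init__(f"{code}: {message}")
        self.code = code


class ExecutionRefused(EngineError):
    """An execute call failed validation; nothing was persisted."""

    def __init__(self, issues: Sequence[Union[EngineIssue, ValidationError]]):
        self.issues = list(issues)
        detail = "; ".join(str(i) for i in self.issues)
        super().__init__("EXECUTION_REFUSED", detail or "refused")


# ---------------------------------------------------------------------------
# Injected clock and id generation
# ---------------------------------------------------------------------------


class SystemClock:
    """Wall-clock UTC timestamps."""

    kind = "system"

    def now(self) -> dt.datetime:
        return dt.datetime.now(dt.timezone.utc).replace(microsecond=0)

    def state(self) -> dict:
        return {"kind": self.kind}


class FixedClock:
    """Deterministic clock: starts at ``start`` and advances ``step`` seconds
    per reading.  Guarantees strictly increasing timestamps."""

    kind = "fixed"

    def __init__(self, start: dt.datetime | None = None, step: float = 60.0, ticks: int = 0):
        self.start = start or dt.datetime(2026, 1, 5, 9, 0, 0, tzinfo=dt.timezone.utc)
        self.step = step
        self.ticks = ticks

    def now(self) -> dt.datetime:
        t = self.start + dt.timedelta(seconds=self.step * self.ticks)
        self.ticks += 1
        return t

    def state(self) -> dict:
        return {
            "kind": self.kind,
            "start": self.start.isoformat(),
            "step": self.step,
            "ticks": self.ticks,
        }


def _clock_from_state(state: Mapping) -> Union[SystemClock, FixedClock]:
    if state.get("kind") == "fixed":
        return FixedClock(
            start=dt.datetime.fromisoformat(state["start"]),
            step=float(state["step"]),
            ticks=int(state["ticks"]),
        )
    return SystemClock()


_ID_NAMESPACE = uuid.UUID("6ba7b810-9dad-11d1-80b4-00c04fd430c8")  # uuid NAMESPACE_DNS


class DeterministicIds:
    """UUID-format ids derived from a seed and a running counter (uuid5)."""

    kind = "deterministic"

    def __init__(self, seed: int, counter: int = 0):
        self.seed = int(seed)
        self.counter = int(counter)

    def new(self) -> str:
        self.counter += 1
        return str(uuid.uuid5(_ID_NAMESPACE, f"labflow:{self.seed}:{self.counter}"))

    def state(self) -> dict:
        return {"kind": self.kind, "seed": self.seed, "counter": self.counter}


class RandomIds:
    kind = "random"

    def new(self) -> str:
        return str(uuid.uuid4())

    def state(self) -> dict:
        return {"kind": self.kind}


def _ids_from_state(state: Mapping) -> Union[DeterministicIds, RandomIds]:
    if state.get("kind") == "deterministic":
        return DeterministicIds(state["seed"], state.get("counter", 0))
    return RandomIds()


# ---------------------------------------------------------------------------
# Availability (pure function, shared with tests/oracles)
# ---------------------------------------------------------------------------


def compute_available(w: wm.WorkflowDefinition, executed: Iterable[str]) -> frozenset[str]:
    """Activities a trace may execute next, given the set already executed.

    A not-yet-executed activity is available if it is a start activity or at
    least one predecessor has executed (OR-join: availability is gated by
    input cardinality at execution time, not by join logic).  Forks are
    OR-splits: every successor becomes available, any subset may run.
    Re-execution of repeatable activities is reported separately.
    """
    executed = set(executed)
    targets = {t.to_activity for t in w.transitions}
    preds: dict[str, set[str]] = {}
    for t in w.transitions:
        preds.setdefault(t.to_activity, set()).add(t.from_activity)
    return frozenset(
        aid
        for aid in w.activities
        if aid not in executed
        and (aid not in targets or (preds.get(aid, set()) & executed))
    )


# ---------------------------------------------------------------------------
# Value (de)serialisation for the event log / snapshot
# ---------------------------------------------------------------------------


def value_to_json(v: TypedValue) -> object:
    if isinstance(v, bool):  # bools are not attribute values; guard anyway
        raise TypeError("boolean attribute values are not supported")
    if isinstance(v, int):
        return {"t": "integer", "v": v}
    if isinstance(v, float):
        return {"t": "real", "v": v}
    if isinstance(v, str):
        return {"t": "string", "v": v}
    if isinstance(v, dt.date):
        return {"t": "date", "v": v.isoformat()}
    if isinstance(v, FileRef):
        return {
            "t": "file",
            "path": v.path,
            "size": v.size,
            "sha256": v.sha256,
            "content_hashed": v.content_hashed,
        }
    raise TypeError(f"unsupported value type {type(v).__name__}")


def value_from_json(d: Mapping) -> TypedValue:
    t = d["t"]
    if t == "integer":
        return int(d["v"])
    if t == "real":
        return float(d["v"])
    if t == "string":
        return str(d["v"])
    if t == "date":
        return dt.date.fromisoformat(d["v"])
    if t == "file":
        return FileRef(d["path"], d["size"], d["sha256"], d["content_hashed"])
    raise ValueError(f"unknown value tag {t!r}")


def _values_to_json(values: Mapping[str, TypedValue]) -> dict:
    return {k: value_to_json(v) for k, v in values.items()}


def _values_from_json(d: Mapping) -> dict[str, TypedValue]:
    return {k: value_from_json(v) for k, v in d.items()}


def canonical_json(obj: object) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), ensure_ascii=False)


def _iso(t: dt.datetime) -> str:
    return t.astimezone(dt.timezone.utc).isoformat().replace("+00:00", "Z")


# ---------------------------------------------------------------------------
# The store
# ---------------------------------------------------------------------------

TraceRef = Union[str, SampleTrace]
ExperimentRef = Union[str, Experiment]
ProjectRef = Union[str, Project]

#: output entries: artifact_type -> list of raw-entry maps, one per instance
OutputEntries = Mapping[str, Sequence[Mapping[str, str]]]


class Lims:
    """An in-memory laboratory store with optional directory persistence.

    All mutating operations are atomic: every validation runs before any
    state changes, so a refused call leaves the store byte-identical to its
    pre-call snapshot.
    """

    SNAPSHOT_VERSION = 1

    def __init__(self, clock=None, id_seed: int | None = None, ids=None):
        self.clock = clock or SystemClock()
        if ids is not None:
            self.ids = ids
        elif id_seed is not None:
            self.ids = DeterministicIds(id_seed)
        else:
            self.ids = RandomIds()
        self.workflows: dict[str, wm.WorkflowDefinition] = {}
        self.projects: dict[str, Project] = {}
        self.experiments: dict[str, Experiment] = {}
        self.traces: dict[str, SampleTrace] = {}
        self.executions: dict[str, ActivityExecution] = {}
        self.artifacts: dict[str, Artifact] = {}
        self.event_records: list[dict] = []

    # -- lookups ------------------------------------------------------------

    def _trace(self, ref: TraceRef) -> SampleTrace:
        tid = ref.id if isinstance(ref, SampleTrace) else ref
        try:
            return self.traces[tid]
        except KeyError:
            raise EngineError("UNKNOWN_TRACE", f"no trace {tid!r}") from None

    def _experiment(self, ref: ExperimentRef) -> Experiment:
        eid = ref.id if isinstance(ref, Experiment) else ref
        try:
            return self.experiments[eid]
        except KeyError:
            raise EngineError("UNKNOWN_EXPERIMENT", f"no experiment {eid!r}") from None

    def _project(self, ref: ProjectRef) -> Project:
        pid = ref.id if isinstance(ref, Project) else ref
        try:
            return self.projects[pid]
        except KeyError:
            raise EngineError("UNKNOWN_PROJECT", f"no project {pid!r}") from None

    def find_trace(self, experiment: ExperimentRef, sample_label: str) -> SampleTrace:
        exp = self._experiment(experiment)
        for tid in exp.trace_ids:
            if self.traces[tid].sample_label == sample_label:
                return self.traces[tid]
        raise EngineError("UNKNOWN_SAMPLE", f"no sample {sample_label!r} in experiment {exp.id}")

    # -- workflow library ---------------------------------------------------

    def add_workflow(self, w: wm.WorkflowDefinition) -> None:
        issues = wm.validate_definition(w)
        if wm.has_errors(issues):
            detail = "; ".join(str(i) for i in issues if i.severity == "error")
            raise EngineError("INVALID_WORKFLOW", detail)
        self.workflows[w.id] = copy.deepcopy(w)

    # -- lifecycle ----------------------------------------------------------

    def create_project(self, name: str, actor: str) -> Project:
        if not name:
            raise EngineError("INVALID_NAME", "project name must be non-empty")
        p = Project(id=self.ids.new(), name=name, created_at=self.clock.now(), created_by=actor)
        self.projects[p.id] = p
        return p

    def create_experiment(
        self, project: ProjectRef, workflow: Union[str, wm.WorkflowDefinition], actor: str
    ) -> Experiment:
        proj = self._project(project)
        if isinstance(workflow, str):
            if workflow not in self.workflows:
                raise EngineError("UNKNOWN_WORKFLOW", f"no loaded workflow {workflow!r}")
            workflow = self.workflows[workflow]
        issues = wm.validate_definition(workflow)
        if wm.has_errors(issues):
            detail = "; ".join(str(i) for i in issues if i.severity == "error")
            raise EngineError("INVALID_WORKFLOW", detail)
        exp = Experiment(
            id=self.ids.new(),
            project_id=proj.id,
            workflow=copy.deepcopy(workflow),
            created_at=self.clock.now(),
            created_by=actor,
        )
        self.experiments[exp.id] = exp
        proj.experiment_ids.append(exp.id)
        return exp

    def register_sample(self, experiment: ExperimentRef, label: str) -> SampleTrace:
        exp = self._experiment(experiment)
        if not label:
            raise EngineError("INVALID_NAME", "sample label must be non-empty")
        for tid in exp.trace_ids:
            if self.traces[tid].sample_label == label:
                raise EngineError(
                    "DUPLICATE_SAMPLE", f"sample {label!r} already registered in experiment {exp.id}"
                )
        trace = SampleTrace(id=self.ids.new(), experiment_id=exp.id, sample_label=label)
        self.traces[trace.id] = trace
        exp.trace_ids.append(trace.id)
        return trace

    # -- availability -------------------------------------------------------

    def executed_activities(self, trace: TraceRef) -> set[str]:
        t = self._trace(trace)
        return {self.executions[eid].activity_id for eid in t.execution_ids}

    def available_activities(self, trace: TraceRef) -> frozenset[str]:
        """Activities newly available on this trace (never yet executed)."""
        t = self._trace(trace)
        w = self.experiments[t.experiment_id].workflow
        return compute_available(w, self.executed_activities(t))

    def repeatable_activities(self, trace: TraceRef) -> frozenset[str]:
        """Already-executed activities that may be run again on this trace."""
        t = self._trace(trace)
        w = self.experiments[t.experiment_id].workflow
        return frozenset(
            aid for aid in self.executed_activities(t) if w.activities[aid].repeatable
        )

    # -- input selection ----------------------------------------------------

    def select_inputs(
        self, trace: TraceRef, activity_id: str, chosen: Sequence[str]
    ) -> list[EngineIssue]:
        """Check a proposed set of input artifacts against the activity's
        input cardinality and type contracts; returns all problems (empty
        list means the selection is acceptable)."""
        t = self._trace(trace)
        exp = self.experiments[t.experiment_id]
        act = exp.workflow.activity(activity_id)
        issues: list[EngineIssue] = []

        by_type: dict[str, list[Artifact]] = {}
        declared_types = {io.artifact_type for io in act.inputs}
        for aid in chosen:
            art = self.artifacts.get(aid)
            if art is None or art.experiment_id != exp.id:
                issues.append(
                    EngineIssue(
                        "FOREIGN_ARTIFACT",
                        f"artifact {aid!r} does not exist in this experiment",
                    )
                )
                continue
            if art.artifact_type not in declared_types:
                issues.append(
                    EngineIssue(
                        "TYPE_INCOMPATIBLE",
                        f"artifact {aid!r} has type {art.artifact_type!r}, not an input of "
                        f"{activity_id!r}",
                    )
                )
                continue
            by_type.setdefault(art.artifact_type, []).append(art)

        for io in act.inputs:
            n = len(by_type.get(io.artifact_type, []))
            if n < io.min_count:
                issues.append(
                    EngineIssue(
                        "INPUT_COUNT_LOW",
                        f"{activity_id!r} requires at least {io.min_count} "
                        f"{io.artifact_type!r} input(s), got {n}",
                    )
                )
            elif io.max_count is not None and n > io.max_count:
                issues.append(
                    EngineIssue(
                        "INPUT_COUNT_HIGH",
                        f"{activity_id!r} accepts at most {io.max_count} "
                        f"{io.artifact_type!r} input(s), got {n}",
                    )
                )
        return issues

    # -- execution ----------------------------------------------------------

    def execute_activity(
        self,
        trace: TraceRef,
        activity_id: str,
        entries: Mapping[str, str] | None = None,
        chosen_inputs: Sequence[str] = (),
        output_entries: OutputEntries | None = None,
        actor: str = "anonymous",
    ) -> ActivityExecution:
        """Execute one activity on one trace, atomically.

        ``entries`` are the raw form values for the activity's own
        attributes; ``chosen_inputs`` are ids of artifacts to consume;
        ``output_entries`` maps each declared output artifact type to a list
        of raw-entry maps, one per produced instance (default: one instance
        per declared output).  Any validation failure raises
        :class:`ExecutionRefused` and persists nothing.
        """
        t = self._trace(trace)
        exp = self.experiments[t.experiment_id]
        w = exp.workflow
        if activity_id not in w.activities:
            raise EngineError("UNKNOWN_ACTIVITY", f"no activity {activity_id!r} in workflow {w.id}")
        act = w.activities[activity_id]

        executed = self.executed_activities(t)
        available = compute_available(w, executed)
        if activity_id not in available:
            if activity_id in executed and act.repeatable:
                pass  # repetition of an already-executed activity
            else:
                raise ExecutionRefused(
                    [
                        EngineIssue(
                            "NOT_AVAILABLE",
                            f"activity {activity_id!r} is not available on sample "
                            f"{t.sample_label!r}",
                        )
                    ]
                )

        issues: list[Union[EngineIssue, ValidationError]] = []
        issues.extend(self.select_inputs(t, activity_id, chosen_inputs))

        form = validate_attributes(act.attributes, entries or {})
        issues.extend(form.errors)

        # Validate declared outputs before touching any state.
        output_entries = dict(output_entries or {})
        declared = {io.artifact_type: io for io in act.outputs}
        for artifact_type in output_entries:
            if artifact_type not in declared:
                issues.append(
                    EngineIssue(
                        "UNDECLARED_OUTPUT",
                        f"{activity_id!r} does not declare output type {artifact_type!r}",
                    )
                )
        validated_outputs: list[tuple[wm.IOSpec, FormResult]] = []
        for io in act.outputs:
            instances = list(output_entries.get(io.artifact_type, [{}]))
            if len(instances) < io.min_count:
                issues.append(
                    EngineIssue(
                        "OUTPUT_COUNT_LOW",
                        f"{activity_id!r} must produce at least {io.min_count} "
                        f"{io.artifact_type!r} artifact(s), got {len(instances)}",
                    )
                )
            elif io.max_count is not None and len(instances) > io.max_count:
                issues.append(
                    EngineIssue(
                        "OUTPUT_COUNT_HIGH",
                        f"{activity_id!r} may produce at most {io.max_count} "
                        f"{io.artifact_type!r} artifact(s), got {len(instances)}",
                    )
                )
            for inst in instances:
                result = validate_attributes(io.attributes, inst)
                issues.extend(result.errors)
                validated_outputs.append((io, result))

        if issues:
            raise ExecutionRefused(issues)

        # ---- commit point: everything below is guaranteed to succeed ----
        repetition_index = 1 + sum(
            1 for eid in t.execution_ids if self.executions[eid].activity_id == activity_id
        )
        execution = ActivityExecution(
            id=self.ids.new(),
            trace_id=t.id,
            activity_id=activity_id,
            repetition_index=repetition_index,
            executed_at=self.clock.now(),
            executed_by=actor,
            values=form.values,
            consumed_artifacts=list(chosen_inputs),
            produced_artifacts=[],
        )
        produced: list[Artifact] = []
        for io, result in validated_outputs:
            art = Artifact(
                id=self.ids.new(),
                experiment_id=exp.id,
                artifact_type=io.artifact_type,
                values=result.values,
                produced_by=execution.id,
            )
            produced.append(art)
            execution.produced_artifacts.append(art.id)

        self.executions[execution.id] = execution
        for art in produced:
            self.artifacts[art.id] = art
        for aid in chosen_inputs:
            self.artifacts[aid].consumed_by.append(execution.id)
        t.execution_ids.append(execution.id)
        self.event_records.append(self._event(exp, t, execution, produced))
        return execution

    def _event(
        self,
        exp: Experiment,
        trace: SampleTrace,
        execution: ActivityExecution,
        produced: list[Artifact],
    ) -> dict:
        return {
            "event": "execution",
            "execution_id": execution.id,
            "experiment_id": exp.id,
            "trace_id": trace.id,
            "sample_label": trace.sample_label,
            "activity_id": execution.activity_id,
            "activity_name": exp.workflow.activities[execution.activity_id].name,
            "repetition_index": execution.repetition_index,
            "executed_at": _iso(execution.executed_at),
            "executed_by": execution.executed_by,
            "values": _values_to_json(execution.values),
            "consumed_artifacts": list(execution.consumed_artifacts),
            "produced_artifacts": [
                {
                    "id": a.id,
                    "artifact_type": a.artifact_type,
                    "values": _values_to_json(a.values),
                }
                for a in produced
            ],
        }

    # -- derived views ------------------------------------------------------

    def experiment_executions(self, experiment: ExperimentRef) -> list[ActivityExecution]:
        exp = self._experiment(experiment)
        execs = [
            self.executions[eid]
            for tid in exp.trace_ids
            for eid in self.traces[tid].execution_ids
        ]
        return sorted(execs, key=lambda e: (e.executed_at, e.id))

    def lineage_traces(self, execution_id: str) -> set[str]:
        """Traces whose sample lineage feeds (transitively) into an execution."""
        seen_exec: set[str] = set()
        traces: set[str] = set()
        stack = [execution_id]
        while stack:
            eid = stack.pop()
            if eid in seen_exec:
                continue
            seen_exec.add(eid)
            ex = self.executions[eid]
            traces.add(ex.trace_id)
            for aid in ex.consumed_artifacts:
                stack.append(self.artifacts[aid].produced_by)
        return traces

    def completed_traces(self, experiment: ExperimentRef) -> set[str]:
        """Traces counted complete: some execution whose lineage includes the
        trace reached a terminal activity.

        A cross-sample step (a two-dye slide hybridization) is recorded on
        one designated trace but completes every sample whose artifacts it
        consumed, which is how a per-sample row view reconciles with
        slide-level steps.
        """
        exp = self._experiment(experiment)
        terminals = wm.terminal_activities(exp.workflow)
        done: set[str] = set()
        for ex in self.experiment_executions(exp):
            if ex.activity_id in terminals:
                done |= self.lineage_traces(ex.id)
        return done

    # -- persistence --------------------------------------------------------

    def snapshot(self) -> dict:
        return {
            "version": self.SNAPSHOT_VERSION,
            "clock": self.clock.state(),
            "ids": self.ids.state(),
            "workflows": {wid: wm.workflow_to_dict(w) for wid, w in self.workflows.items()},
            "projects": [
                {
                    "id": p.id,
                    "name": p.name,
                    "created_at": _iso(p.created_at),
                    "created_by": p.created_by,
                    "experiment_ids": list(p.experiment_ids),
                }
                for p in self.projects.values()
            ],
            "experiments": [
                {
                    "id": e.id,
                    "project_id": e.project_id,
                    "workflow": wm.workflow_to_dict(e.workflow),
                    "created_at": _iso(e.created_at),
                    "created_by": e.created_by,
                    "trace_ids": list(e.trace_ids),
                }
                for e in self.experiments.values()
            ],
            "traces": [
                {
                    "id": t.id,
                    "experiment_id": t.experiment_id,
                    "sample_label": t.sample_label,
                    "execution_ids": list(t.execution_ids),
                }
                for t in self.traces.values()
            ],
            "executions": [
                {
                    "id": e.id,
                    "trace_id": e.trace_id,
                    "activity_id": e.activity_id,
                    "repetition_index": e.repetition_index,
                    "executed_at": _iso(e.executed_at),
                    "executed_by": e.executed_by,
                    "values": _values_to_json(e.values),
                    "consumed_artifacts": list(e.consumed_artifacts),
                    "produced_artifacts": list(e.produced_artifacts),
                    "status": e.status,
                }
                for e in self.executions.values()
            ],
            "artifacts": [
                {
                    "id": a.id,
                    "experiment_id": a.experiment_id,
                    "artifact_type": a.artifact_type,
                    "values": _values_to_json(a.values),
                    "produced_by": a.produced_by,
                    "consumed_by": list(a.consumed_by),
                }
                for a in self.artifacts.values()
            ],
            "events": self.event_records,
        }

    def snapshot_bytes(self) -> bytes:
        return (canonical_json(self.snapshot()) + "\n").encode("utf-8")

    def event_log_bytes(self) -> bytes:
        return "".join(canonical_json(rec) + "\n" for rec in self.event_records).encode("utf-8")

    def save(self, directory: str | Path) -> None:
        """Write the single-directory store: ``snapshot.json`` (full state)
        plus ``events.jsonl`` (one JSON record per execution)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "snapshot.json").write_bytes(self.snapshot_bytes())
        (directory / "events.jsonl").write_bytes(self.event_log_bytes())

    @classmethod
    def load(cls, directory: str | Path) -> "Lims":
        directory = Path(directory)
        data = json.loads((directory / "snapshot.json").read_text("utf-8"))
        if data.get("version") != cls.SNAPSHOT_VERSION:
            raise EngineError("STORE_CORRUPT", f"unsupported snapshot version {data.get('version')!r}")
        lims = cls(clock=_clock_from_state(data["clock"]), ids=_ids_from_state(data["ids"]))
        lims.workflows = {
            wid: wm.workflow_from_dict(d) for wid, d in data.get("workflows", {}).items()
        }
        for p in data["projects"]:
            lims.projects[p["id"]] = Project(
                id=p["id"],
                name=p["name"],
                created_at=dt.datetime.fromisoformat(p["created_at"].replace("Z", "+00:00")),
                created_by=p["created_by"],
                experiment_ids=list(p["experiment_ids"]),
            )
        for e in data["experiments"]:
            lims.experiments[e["id"]] = Experiment(
                id=e["id"],
                project_id=e["project_id"],
                workflow=wm.workflow_from_dict(e["workflow"]),
                created_at=dt.datetime.fromisoformat(e["created_at"].replace("Z", "+00:00")),
                created_by=e["created_by"],
                trace_ids=list(e["trace_ids"]),
            )
        for t in data["traces"]:
            lims.traces[t["id"]] = SampleTrace(
                id=t["id"],
                experiment_id=t["experiment_id"],
                sample_label=t["sample_label"],
                execution_ids=list(t["execution_ids"]),
            )
        for e in data["executions"]:
            lims.executions[e["id"]] = ActivityExecution(
                id=e["id"],
                trace_id=e["trace_id"],
                activity_id=e["activity_id"],
                repetition_index=e["repetition_index"],
                executed_at=dt.datetime.fromisoformat(e["executed_at"].replace("Z", "+00:00")),
                executed_by=e["executed_by"],
                values=_values_from_json(e["values"]),
                consumed_artifacts=list(e["consumed_artifacts"]),
                produced_artifacts=list(e["produced_artifacts"]),
                status=e["status"],
            )
        for a in data["artifacts"]:
            lims.artifacts[a["id"]] = Artifact(
                id=a["id"],
                experiment_id=a["experiment_id"],
                artifact_type=a["artifact_type"],
                values=_values_from_json(a["values"]),
                produced_by=a["produced_by"],
                consumed_by=list(a["consumed_by"]),
            )
        lims.event_records = list(data.get("events", []))
        return lims
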