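"""Programmatic workflow builders and a deterministic run driver.

Two laboratory processes are built here in code so the whole engine is
exercisable with no external files:

* a **two-color microarray** workflow — sample registration, RNA extraction
  (recording total concentration, final volume, gel image and dosage method
  on the extracted-RNA artifact), optional cleaning and amplification,
  Cy3/Cy5 labeling, two-sample-per-slide hybridization, scanning and data
  analysis;
* a small **proteomics** workflow (sample preparation, separation, mass
  spectrometry, protein identification) demonstrating that a second
  laboratory loads onto the same engine with zero code changes.

:func:`simulate_run` drives every registered sample through a workflow end
to end, generating attribute values that satisfy every constraint and
submitting them through the ordinary validation path (no back door).  For
the microarray workflow it labels samples alternately Cy3/Cy5 and
hybridizes differently-dyed pairs onto one slide, reproducing the
12-samples-on-6-slides validation design.

:func:`random_workflow` generates arbitrary valid workflow definitions for
property-based testing of the validator, the XPDL round trip and the
availability rules.
"""

from __future__ import annotations

import datetime as dt
import random
import re
from dataclasses import dataclass

from . import workflow_model as wm
from .engine import Experiment, FixedClock, Lims, Project
from .workflow_model import (
    ActivitySpec,
    AttributeSpec,
    Datatype,
    Direction,
    IOSpec,
    TransitionSpec,
    WorkflowDefinition,
)

__all__ = [
    "build_microarray_workflow",
    "build_proteomics_workflow",
    "FIXTURE_BUILDERS",
    "SimulationError",
    "SimulationResult",
    "simulate_run",
    "random_workflow",
]


def _attr(name, datatype, **kw) -> AttributeSpec:
    return AttributeSpec(name=name, datatype=datatype, **kw)


def _io(direction, artifact_type, attributes=(), min_count=1, max_count=1) -> IOSpec:
    return IOSpec(
        artifact_type=artifact_type,
        direction=direction,
        attributes=tuple(attributes),
        min_count=min_count,
        max_count=max_count,
    )


def _extracted_rna_attrs() -> tuple[AttributeSpec, ...]:
    return (
        _attr("RNA total concentration", Datatype.REAL, required=True, numeric_range=(0, None),
              documentation="ng/ul"),
        _attr("RNA final volume", Datatype.REAL, required=True, numeric_range=(0, None),
              documentation="ul"),
        _attr("Gel image", Datatype.FILE, required=True),
        _attr("Dosage method", Datatype.STRING, required=True,
              allowed_values=("Spectrophotometer", "Fluorometer")),
    )


def build_microarray_workflow() -> WorkflowDefinition:
    """Two-color (Cy3/Cy5) spotted-array workflow.

    After RNA extraction the process forks: cleaning, amplification or
    labeling may each follow (any subset, in that partial order).
    Hybridization consumes exactly two labeled samples — one per dye — and
    produces one slide, so per-sample traces merge at the slide level.
    """
    extracted = _extracted_rna_attrs()
    activities = [
        ActivitySpec(
            id="SampleRegistration",
            name="Sample Registration",
            attributes=(
                _attr("Sample name", Datatype.STRING, required=True),
                _attr("Organism", Datatype.STRING),
                _attr("Collection date", Datatype.DATE, required=True),
            ),
            outputs=(_io(Direction.OUTPUT, "TissueSample",
                         (_attr("Tissue", Datatype.STRING),)),),
            documentation=("doc://protocols/sample-reception",),
        ),
        ActivitySpec(
            id="RNAExtraction",
            name="RNA Extraction",
            attributes=(
                _attr("Extraction protocol", Datatype.STRING, required=True,
                      allowed_values=("TRIzol", "Column kit")),
                _attr("Extraction date", Datatype.DATE),
            ),
            inputs=(_io(Direction.INPUT, "TissueSample"),),
            outputs=(_io(Direction.OUTPUT, "ExtractedRNA", extracted),),
            documentation=("doc://protocols/rna-extraction",),
        ),
        ActivitySpec(
            id="Cleaning",
            name="Cleaning",
            attributes=(_attr("Cleaning kit", Datatype.STRING),),
            inputs=(_io(Direction.INPUT, "ExtractedRNA"),),
            outputs=(_io(Direction.OUTPUT, "ExtractedRNA", extracted),),
        ),
        ActivitySpec(
            id="Amplification",
            name="Amplification",
            attributes=(
                _attr("Amplification method", Datatype.STRING,
                      allowed_values=("T7 IVT", "PCR")),
                _attr("Cycles", Datatype.INTEGER, numeric_range=(1, 50)),
            ),
            inputs=(_io(Direction.INPUT, "ExtractedRNA"),),
            outputs=(_io(Direction.OUTPUT, "ExtractedRNA", extracted),),
        ),
        ActivitySpec(
            id="Labeling",
            name="Labeling",
            attributes=(_attr("Labeling kit", Datatype.STRING),),
            inputs=(_io(Direction.INPUT, "ExtractedRNA"),),
            outputs=(
                _io(
                    Direction.OUTPUT,
                    "LabeledSample",
                    (
                        _attr("Dye", Datatype.STRING, required=True,
                              allowed_values=("Cy3", "Cy5")),
                        _attr("Labeled yield", Datatype.REAL, numeric_range=(0, None)),
                    ),
                ),
            ),
        ),
        ActivitySpec(
            id="Hybridization",
            name="Hybridization",
            attributes=(
                _attr("hyb_hours", Datatype.REAL, required=True, numeric_range=(1, 72),
                      documentation="hybridization time, hours"),
                _attr("wash_hours", Datatype.REAL, required=True, numeric_range=(0, 24),
                      documentation="post-hybridization wash time, hours"),
                _attr("total_hours", Datatype.REAL, derivation="hyb_hours + wash_hours",
                      documentation="auto-calculated total bench time"),
            ),
            inputs=(_io(Direction.INPUT, "LabeledSample", min_count=2, max_count=2),),
            outputs=(
                _io(
                    Direction.OUTPUT,
                    "Slide",
                    (
                        _attr("Slide barcode", Datatype.STRING, required=True),
                        _attr("Hybridization temperature", Datatype.REAL, required=True,
                              numeric_range=(20, 70), documentation="degrees C"),
                    ),
                ),
            ),
            documentation=("doc://protocols/two-color-hybridization",),
        ),
        ActivitySpec(
            id="Scanning",
            name="Scanning",
            attributes=(
                _attr("Scanner", Datatype.STRING,
                      allowed_values=("GenePix 4000B", "Agilent G2565")),
            ),
            inputs=(_io(Direction.INPUT, "Slide"),),
            outputs=(
                _io(
                    Direction.OUTPUT,
                    "ScanImage",
                    (
                        _attr("Image file", Datatype.FILE, required=True),
                        _attr("Resolution", Datatype.REAL, numeric_range=(1, 50),
                              documentation="micrometres per pixel"),
                    ),
                ),
            ),
        ),
        ActivitySpec(
            id="DataAnalysis",
            name="Data Analysis",
            attributes=(
                _attr("Annotation file", Datatype.FILE,
                      documentation="gene sequence annotation consumed by external analysis"),
                _attr("Normalization", Datatype.STRING,
                      allowed_values=("lowess", "quantile")),
                _attr("Software", Datatype.STRING),
            ),
            inputs=(_io(Direction.INPUT, "ScanImage"),),
        ),
    ]
    transitions = [
        ("SampleRegistration", "RNAExtraction"),
        ("RNAExtraction", "Cleaning"),
        ("RNAExtraction", "Amplification"),
        ("RNAExtraction", "Labeling"),
        ("Cleaning", "Amplification"),
        ("Cleaning", "Labeling"),
        ("Amplification", "Labeling"),
        ("Labeling", "Hybridization"),
        ("Hybridization", "Scanning"),
        ("Scanning", "DataAnalysis"),
    ]
    return WorkflowDefinition(
        id="microarray",
        name="Two-color microarray workflow",
        version="1.0",
        activities={a.id: a for a in activities},
        transitions=tuple(
            TransitionSpec(f"t{i}", src, dst) for i, (src, dst) in enumerate(transitions)
        ),
    )


def build_proteomics_workflow() -> WorkflowDefinition:
    """Minimal proteomics process: a second laboratory on the same engine."""
    activities = [
        ActivitySpec(
            id="SamplePrep",
            name="Sample Preparation",
            attributes=(
                _attr("Protein concentration", Datatype.REAL, required=True,
                      numeric_range=(0, None), documentation="ug/ul"),
                _attr("Buffer", Datatype.STRING),
            ),
            outputs=(_io(Direction.OUTPUT, "PreparedSample"),),
        ),
        ActivitySpec(
            id="Separation",
            name="Separation",
            attributes=(
                _attr("Method", Datatype.STRING, required=True,
                      allowed_values=("2D gel", "LC")),
            ),
            inputs=(_io(Direction.INPUT, "PreparedSample"),),
            outputs=(
                _io(Direction.OUTPUT, "Fraction",
                    (_attr("Gel image", Datatype.FILE),)),
            ),
        ),
        ActivitySpec(
            id="MassSpectrometry",
            name="Mass Spectrometry",
            attributes=(
                _attr("Instrument", Datatype.STRING),
                _attr("Acquisition date", Datatype.DATE),
            ),
            inputs=(_io(Direction.INPUT, "Fraction"),),
            outputs=(
                _io(Direction.OUTPUT, "SpectraFile",
                    (_attr("Raw file", Datatype.FILE, required=True),)),
            ),
        ),
        ActivitySpec(
            id="ProteinIdentification",
            name="Protein Identification",
            attributes=(
                _attr("Search engine", Datatype.STRING,
                      allowed_values=("Mascot", "SEQUEST")),
                _attr("Proteins identified", Datatype.INTEGER, numeric_range=(0, None)),
            ),
            inputs=(_io(Direction.INPUT, "SpectraFile"),),
        ),
    ]
    transitions = [
        ("SamplePrep", "Separation"),
        ("Separation", "MassSpectrometry"),
        ("MassSpectrometry", "ProteinIdentification"),
    ]
    return WorkflowDefinition(
        id="proteomics",
        name="Proteomics workflow",
        version="1.0",
        activities={a.id: a for a in activities},
        transitions=tuple(
            TransitionSpec(f"t{i}", src, dst) for i, (src, dst) in enumerate(transitions)
        ),
    )


FIXTURE_BUILDERS = {
    "microarray": build_microarray_workflow,
    "proteomics": build_proteomics_workflow,
}


# ---------------------------------------------------------------------------
# Deterministic run driver
# ---------------------------------------------------------------------------


class SimulationError(RuntimeError):
    """The workflow cannot be driven to completion under its own constraints."""


@dataclass
class SimulationResult:
    lims: Lims
    project: Project
    experiment: Experiment


def _slug(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "_", text).strip("_").lower()


def _generate_value(spec: AttributeSpec, rng: random.Random, trace_index: int, label: str,
                    activity_id: str) -> str:
    """A raw string satisfying one attribute spec, drawn deterministically.

    Attributes with an allowed-values list cycle through the list by sample
    index, which is what alternates dyes Cy3/Cy5 across consecutive samples.
    """
    if spec.allowed_values:
        return spec.allowed_values[trace_index % len(spec.allowed_values)]
    if spec.datatype is Datatype.INTEGER:
        lo, hi = spec.numeric_range or (None, None)
        lo = 1 if lo is None else int(lo)
        hi = lo + 99 if hi is None else int(hi)
        return str(rng.randint(lo, hi))
    if spec.datatype is Datatype.REAL:
        lo, hi = spec.numeric_range or (None, None)
        lo = 0.5 if lo is None else float(lo)
        hi = lo + 500.0 if hi is None else float(hi)
        return f"{rng.uniform(lo, hi):.3f}"
    if spec.datatype is Datatype.DATE:
        day = dt.date(2026, 1, 5) + dt.timedelta(days=rng.randint(0, 120))
        from .value_validation import DEFAULT_DATE_FORMAT

        return day.strftime(spec.format or DEFAULT_DATE_FORMAT)
    if spec.datatype is Datatype.FILE:
        return f"files/{label}_{activity_id}_{_slug(spec.name)}.dat"
    # string
    if spec.format is not None:
        raise SimulationError(
            f"cannot synthesize a value for string attribute {spec.name!r} "
            f"with pattern {spec.format!r}"
        )
    return f"{_slug(spec.name)}-{rng.randint(100, 999)}"


def _entries_for(specs, rng, trace_index, label, activity_id) -> dict[str, str]:
    return {
        spec.name: _generate_value(spec, rng, trace_index, label, activity_id)
        for spec in specs
        if spec.derivation is None
    }


def simulate_run(
    workflow: WorkflowDefinition,
    n_samples: int,
    seed: int = 0,
    lims: Lims | None = None,
    actor: str = "simulator",
    project_name: str = "Simulated project",
) -> SimulationResult:
    """Register ``n_samples`` traces and drive each to a terminal activity.

    Every activity of the workflow is executed in topological order.  Steps
    whose input cardinality exceeds what one sample's lineage provides merge
    consecutive sample groups (two-dye hybridization pairs consecutive,
    hence differently-dyed, samples); if merging every remaining group still
    cannot satisfy an input, an already-executed producer is repeated.  All
    values pass through ordinary form validation.  With the same seed and a
    fixed clock two runs produce byte-identical event logs.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    issues = wm.validate_definition(workflow)
    if wm.has_errors(issues):
        raise SimulationError(
            "workflow is not executable: "
            + "; ".join(str(i) for i in issues if i.severity == "error")
        )
    if lims is None:
        lims = Lims(clock=FixedClock(), id_seed=seed % (2**31))
    rng = random.Random(seed)
    project = lims.create_project(project_name, actor)
    experiment = lims.create_experiment(project, workflow, actor)
    traces = [lims.register_sample(experiment, f"S{i + 1:02d}") for i in range(n_samples)]
    trace_index = {t.id: i for i, t in enumerate(traces)}
    labels = {t.id: t.sample_label for t in traces}

    # Each group is an ordered list of trace ids that have merged; activities
    # execute once per group, recorded on the designated (first) trace.
    groups: list[list[str]] = [[t.id] for t in traces]
    w = experiment.workflow

    def artifacts_of(group: list[str], artifact_type: str) -> list[str]:
        """Artifact ids of a type in the group's lineage: the most recent one
        of each member trace first (in member order), then older ones."""
        member_set = set(group)
        per_trace: dict[str, list[str]] = {tid: [] for tid in group}
        for art in lims.artifacts.values():  # insertion order == production order
            if art.experiment_id != experiment.id or art.artifact_type != artifact_type:
                continue
            producer_trace = lims.executions[art.produced_by].trace_id
            if producer_trace in member_set:
                per_trace[producer_trace].append(art.id)
        newest = [ids[-1] for tid in group if (ids := per_trace[tid])]
        older = [
            aid
            for tid in group
            for aid in reversed(per_trace[tid][:-1])
        ]
        return newest + older

    def run_activity(aid: str, group: list[str], depth: int = 0) -> None:
        if depth > 50:
            raise SimulationError(f"cannot satisfy inputs of activity {aid!r}")
        act = w.activities[aid]
        designated = group[0]
        idx = trace_index[designated]
        label = labels[designated]
        chosen: list[str] = []
        for io in act.inputs:
            need = io.min_count if io.min_count >= 1 else (1 if io.max_count != 0 else 0)
            avail = artifacts_of(group, io.artifact_type)
            while len(avail) < need:
                producer = _latest_producer(group, io.artifact_type)
                if producer is None:
                    raise SimulationError(
                        f"activity {aid!r} needs {need} {io.artifact_type!r} input(s) "
                        f"but none can be produced for sample {label!r}"
                    )
                run_activity(producer, group, depth + 1)
                avail = artifacts_of(group, io.artifact_type)
            chosen.extend(avail[:need])
        entries = _entries_for(act.attributes, rng, idx, label, aid)
        output_entries = {
            io.artifact_type: [
                _entries_for(io.attributes, rng, idx, label, aid)
                for _ in range(max(io.min_count, 1))
            ]
            for io in act.outputs
        }
        lims.execute_activity(
            designated, aid, entries, chosen, output_entries, actor=actor
        )

    def _latest_producer(group: list[str], artifact_type: str) -> str | None:
        member_set = set(group)
        for tid in group:
            for eid in reversed(lims.traces[tid].execution_ids):
                ex = lims.executions[eid]
                if ex.trace_id in member_set and any(
                    io.artifact_type == artifact_type
                    for io in w.activities[ex.activity_id].outputs
                ):
                    return ex.activity_id
        return None

    def group_satisfies(group: list[str], act: ActivitySpec) -> bool:
        return all(
            len(artifacts_of(group, io.artifact_type)) >= io.min_count for io in act.inputs
        )

    for aid in wm.topological_order(w):
        act = w.activities[aid]
        next_groups: list[list[str]] = []
        pending: list[str] = []
        for group in groups:
            pending = pending + group
            if group_satisfies(pending, act):
                next_groups.append(pending)
                pending = []
        if pending:
            # Leftover samples that could not pair up stay their own group;
            # the shortfall is covered by repeating the producing activity
            # (e.g. labeling the leftover sample twice for its own slide).
            next_groups.append(pending)
        groups = next_groups
        for group in groups:
            run_activity(aid, group)

    return SimulationResult(lims=lims, project=project, experiment=experiment)


# ---------------------------------------------------------------------------
# Random valid workflows for property-based testing
# ---------------------------------------------------------------------------


def random_workflow(
    rng: random.Random,
    max_activities: int = 30,
    io_probability: float = 0.6,
) -> WorkflowDefinition:
    """A random workflow definition guaranteed to pass static validation
    with zero errors (unconsumed-output warnings may remain).

    The transition graph is acyclic by construction (edges only point from
    lower to higher activity index); declared inputs are drawn from artifact
    types some ancestor produces, so every input is satisfiable.
    """
    n = rng.randint(1, max_activities)
    ids = [f"A{i}" for i in range(n)]
    transitions: list[TransitionSpec] = []
    ancestors: list[set[int]] = [set() for _ in range(n)]
    for j in range(1, n):
        for p in sorted(rng.sample(range(j), rng.randint(0, min(j, 2)))):
            transitions.append(TransitionSpec(f"t{len(transitions)}", ids[p], ids[j]))
            ancestors[j] |= {p} | ancestors[p]

    produced_types: list[set[str]] = [set() for _ in range(n)]
    activities: dict[str, ActivitySpec] = {}
    for i in range(n):
        attributes: list[AttributeSpec] = []
        numeric_names: list[str] = []
        for k in range(rng.randint(0, 3)):
            name = f"f{k}_{i}"
            choice = rng.random()
            if choice < 0.3:
                lo = rng.randint(0, 10)
                spec = AttributeSpec(
                    name, Datatype.INTEGER, required=rng.random() < 0.5,
                    numeric_range=(lo, lo + rng.randint(1, 100)),
                )
                numeric_names.append(name)
            elif choice < 0.55:
                spec = AttributeSpec(
                    name, Datatype.REAL, required=rng.random() < 0.5,
                    numeric_range=(0, 1000) if rng.random() < 0.5 else None,
                )
                numeric_names.append(name)
            elif choice < 0.75:
                spec = AttributeSpec(
                    name, Datatype.STRING, required=rng.random() < 0.5,
                    allowed_values=tuple(f"opt{v}" for v in range(rng.randint(1, 4)))
                    if rng.random() < 0.4
                    else None,
                )
            elif choice < 0.9:
                spec = AttributeSpec(
                    name, Datatype.DATE, required=rng.random() < 0.5,
                    format="%d/%m/%Y" if rng.random() < 0.3 else None,
                )
            else:
                spec = AttributeSpec(name, Datatype.FILE, required=rng.random() < 0.5)
            attributes.append(spec)
        if len(numeric_names) >= 2 and rng.random() < 0.5:
            a, b = rng.sample(numeric_names, 2)
            op = rng.choice(["+", "-", "*"])
            attributes.append(
                AttributeSpec(f"calc_{i}", Datatype.REAL, derivation=f"{a} {op} {b}")
            )

        outputs: list[IOSpec] = []
        if rng.random() < io_probability:
            t = f"T{i}"
            outputs.append(
                IOSpec(
                    artifact_type=t,
                    direction=Direction.OUTPUT,
                    attributes=(AttributeSpec(f"out_{i}", Datatype.REAL, required=True),),
                    min_count=1,
                    max_count=rng.choice([1, 1, 2]),
                )
            )
            produced_types[i].add(t)

        inputs: list[IOSpec] = []
        upstream = sorted({t for a in ancestors[i] for t in produced_types[a]})
        if upstream and rng.random() < io_probability:
            t = rng.choice(upstream)
            min_c = 2 if rng.random() < 0.1 else 1
            inputs.append(
                IOSpec(
                    artifact_type=t,
                    direction=Direction.INPUT,
                    min_count=min_c,
                    max_count=max(min_c, rng.choice([1, 2])),
                )
            )

        activities[ids[i]] = ActivitySpec(
            id=ids[i],
            name=f"Activity {i} – étape",  # exercises unicode round-tripping
            attributes=tuple(attributes),
            inputs=tuple(inputs),
            outputs=tuple(outputs),
            repeatable=True if outputs else rng.random() < 0.9,
            documentation=(f"doc://step/{i}",) if rng.random() < 0.3 else (),
        )

    return WorkflowDefinition(
        id=f"random{rng.randint(0, 10**6)}",
        name="Randomly generated workflow",
        version="1.0",
        activities=activities,
        transitions=tuple(transitions),
    )
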