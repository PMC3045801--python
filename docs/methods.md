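# Methods

## The model

A laboratory process is a **workflow definition**: a set of activities, a
directed acyclic transition graph over them, and per-activity data
contracts. Three layers are deliberately separated:

1. **Definition** (`labflow.workflow_model`) — pure data plus a static
   validator. Nothing here executes.
2. **File format** (`labflow.xpdl_io`) — XPDL 1.0 reading/writing with a
   documented extension encoding.
3. **Runtime** (`labflow.engine`) — projects, experiments, per-sample
   traces, execution, provenance, persistence.

### Attributes

Each activity (and each artifact class) carries an ordered list of attribute
specifications: name, datatype (`string`, `integer`, `real`, `date`,
`file`), a *required* ("not null") flag, an optional format (regular
expression for strings, `strptime` pattern for dates; default ISO-8601
`%Y-%m-%d`), an optional ordered list of allowed values (a dropdown), an
optional numeric range for integers/reals, and an optional **derivation**:
an arithmetic expression over sibling attribute names whose value is
auto-calculated, never typed by the operator.

The derivation language is deliberately minimal: `+ - * /`, parentheses,
numeric literals and sibling names, with standard precedence. No functions,
no cross-activity references, no strings. Derived attributes must be numeric
and may not be marked required-for-entry; chains (a derived attribute
referencing another derived sibling) are evaluated in dependency order and a
cycle is reported as `DERIVATION_FAILED`. Division by zero and missing
referenced values are errors-as-data, never exceptions.

### Value validation semantics

Raw values arrive as strings. The per-value check order is fixed and
documented: **type → format → allowed values → numeric range**; the first
failure is reported for a single value. Whole-form validation collects
*every* error in one pass (so an operator fixes the form once), evaluates
derivations only after all plain fields pass, and on any error returns no
values at all — partial forms are never persisted.

Decimal reals use `.` only; locale handling is a presentation concern.
Dates are stored as calendar dates, not strings; a date failing its
explicit pattern is a `FORMAT_MISMATCH`, one failing the ISO default a
`TYPE_MISMATCH`. Allowed-values lists are rejected on `file` attributes
(there is no meaningful literal equality for files).

File-typed values store identity, not bytes: path, size and SHA-256 of the
content when the path exists at attachment time; otherwise the reference is
identified by the SHA-256 of the path text itself and flagged
`content_hashed=false`. Provenance needs identity — microarray images are
far too large to copy into an audit store.

### Static workflow validation

`validate_definition` returns *all* violations as data (severity `error` or
`warning`): malformed attribute constraints, duplicate attribute names,
dangling or self-loop transitions, cycles, missing start activities,
unreachable activities, bad I/O cardinalities, and **input satisfiability**
(every declared input artifact type must be produced by some activity that
can precede the consumer). An output no downstream activity ever consumes is
a warning, not an error. A definition is executable iff it has zero errors;
this soundness is fuzz-tested by generating random valid workflows and
driving them to completion.

Transitions are unconditional in this version: the examples that motivate
the design need only forks and joins, and no guard-condition syntax is
specified anywhere authoritative, so guards are deferred rather than
guessed. Fork semantics are OR-split (all successors become available, any
subset may run) and join semantics OR-join (one executed predecessor
suffices); correctness of merging paths is gated by input cardinality, not
join logic. Cycles are rejected at validation; re-work is modeled by
engine-level repetition instead.

## XPDL encoding

Documents use the XPDL 1.0 element subset `Package / WorkflowProcesses /
WorkflowProcess / Activities / Activity / Transitions / Transition` with
`ExtendedAttributes` — the standard XPDL escape hatch — carrying everything
XPDL itself cannot express. Extension names use the `labflow.` prefix and
JSON payloads (see the `labflow.xpdl_io` module docstring for the exact
grammar): `labflow.attribute`, `labflow.input`, `labflow.output`,
`labflow.repeatable`, `labflow.doc`. JSON was chosen over a
delimiter-separated payload because attribute names are free text (spaces,
unicode, delimiters) and must round-trip exactly.

Parsing enforces only syntactic/typing rules; graph-level rules stay in
`validate_definition` so a linter can report every problem at once. Unknown
elements and foreign extended attributes are skipped with a logged warning,
never an error. Serialization refuses structurally unwritable definitions
(empty identifiers/names). The round-trip contract —
`parse(serialize(w)) == w`, attribute order preserved — is property-tested
over randomly generated definitions. This encoding is a self-consistent
dialect, not a claim of byte compatibility with any other tool's files.

## Engine semantics

* **Hierarchy** — project → experiments → sample traces. The workflow is
  deep-copied into the experiment at creation: later edits to the loaded
  definition never alter a running experiment.
* **Availability** — per trace, an unexecuted activity is available if it is
  a start activity or any predecessor has executed; already-executed
  repeatable activities are reported separately as re-executable. Every
  activity defaults to repeatable.
* **Execution** — one call validates input selection (cardinality, type,
  same-experiment scope), the activity form, and every output instance's
  form, *then* commits: an immutable execution record (actor, timestamp,
  validated values), one artifact per declared output instance, and
  provenance links in both directions. Validation failures raise with the
  complete issue list and persist nothing — the store is byte-identical to
  its pre-call snapshot (ids and clock are only consumed after validation).
* **Repetition** — re-running an activity appends a record with an
  incremented repetition index. History is append-only: downstream
  executions recorded earlier are never invalidated; re-running downstream
  steps is the operator's choice, as laboratory quality assurance requires
  an immutable trail.
* **Cross-sample steps** — artifacts are selectable across traces within one
  experiment (a slide consumes two samples' labeled RNA) but never across
  experiments. A multi-sample execution is recorded on one designated trace;
  a trace counts *complete* when some execution whose consumed-artifact
  lineage includes that trace reaches a terminal activity.
* **Determinism** — clock and id generation are injected. `FixedClock`
  advances 60 s per reading from 2026-01-05T09:00Z; deterministic ids are
  UUIDv5 values derived from a seed and a counter. Under a fixed clock and
  seeded ids, a replayed call sequence reproduces a byte-identical store.
* **Persistence** — a single directory holding `snapshot.json` (full state,
  canonical JSON: sorted keys, compact separators) and `events.jsonl` (one
  canonical-JSON record per execution: who/when/values/consumed/produced).
  The reports are derived views over the same records.

Dye-balance and other experimental-design policies are deliberately *not*
engine rules: the engine enforces cardinality and type, and two same-dye
labeled samples are accepted on one slide. Design policy belongs to the
workflow author and the operator.

## The simulator

`simulate_run` registers `n` samples and drives each through **every**
activity of the workflow in topological order, generating attribute values
deterministically from a seed and submitting them through ordinary form
validation — there is no back door past the validator. Generation rules:
allowed-values attributes cycle through the list by sample index (which is
exactly what alternates Cy3/Cy5 across consecutive samples); numerics draw
uniformly inside their declared range (defaults 1–100 for integers, 0.5–500
for reals); dates fall in early 2026 and render under the spec's pattern;
file attributes get deterministic per-sample paths (detached references). A
string attribute constrained by an arbitrary regular expression cannot be
synthesized and is reported as unsatisfiable rather than skipped.

When an activity's input cardinality exceeds what one sample's lineage
provides (hybridization needs two labeled samples), consecutive sample
groups merge and the step executes once per merged group on its designated
(first) trace — pairing samples (1,2), (3,4), … so each slide receives one
Cy3 and one Cy5 sample. A leftover sample that cannot pair satisfies the
shortfall by repetition (it is labeled twice and hybridized on its own
slide). If neither merging nor repetition can satisfy an input, the run
fails loudly.

The simulator emulates the *bookkeeping* of a laboratory run — paths,
cardinalities, pairing, constraint-satisfying values — not the biology:
values are uniform draws with no correlation structure, no failure/repeat
dynamics beyond the structural ones above, and no dye-swap replicate
designs. Passing tests therefore demonstrate engine correctness (state
machine, validation, provenance, determinism), not anything about real
measurement distributions.

### Problem sizes

The shipped scenario is 12 samples on 6 slides (78 executions, < 1 s).
Property suites use: 500 random workflows (≤ 30 activities) for the XPDL
round trip; 1,000 random (DAG, executed-set) instances — executed sets drawn
as random playouts, i.e. valid histories — for the availability oracle;
10,000 random (spec, raw value) pairs for validation safety; 100 simulated
runs with a corrupted duplicate of every execution call injected for
atomicity/provenance; and two full 12-sample replays for byte-level
determinism. The whole suite runs in a few seconds on one CPU.

## Known limitations

* No transition guard conditions, AND-join synchronization, sub-workflows,
  timers, or cyclic graphs (see rationale above).
* Single-writer store; no concurrency control, roles or authentication.
* Derivations are intra-activity and numeric only.
* Report layouts are information-equivalent audit listings, not a
  reproduction of any particular GUI or PDF layout.
* The proteomics fixture is an illustrative stand-in process demonstrating
  engine reuse, not a transcription of any specific laboratory's protocol.
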