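# labflow

A workflow-driven laboratory information management engine.

Research, testing and service laboratories generate large volumes of
heterogeneous data — per-sample measurements, instrument files, gel and slide
images — and the procedures that produce them differ between laboratories,
even between laboratories of the same kind. Most LIMS are therefore built
for one laboratory and adapting them means changing code. `labflow` takes
the workflow-as-configuration approach instead: the laboratory's process is
written **once, as data**, in an XPDL (XML Process Definition Language,
WfMC) file — and the engine manages everything else. Adapting the system to
a new laboratory means writing a new workflow definition, not new software.

A workflow definition declares:

* **activities** — the bench steps (e.g. *RNA Extraction*), each with typed
  attributes (`string`, `integer`, `real`, `date`, `file`) that may be
  *not-null*, pattern-constrained, range-bounded, restricted to a dropdown
  list of allowed values, or *auto-calculated* from sibling attributes;
* **transitions** — the partial order of the steps (forks offer alternative
  next steps);
* **input/output artifact classes** — the data objects each activity
  consumes and produces (extracted RNA, labeled samples, slides, …), with
  minimum/maximum cardinalities.

At run time a *project* holds *experiments*; each registered sample is an
independent *trace* through the workflow. The engine tracks which activities
are available versus executed per sample, validates every entered value
before anything is persisted (all errors reported in one pass), enforces
input/output cardinalities, supports repetition ("the gel was unclear — run
it again") with an append-only history, records full artifact provenance,
and renders short/long audit reports (text, RFC-4180 CSV, Markdown).

Two laboratory processes ship as programmatic fixtures and as XPDL files
under `fixtures/`: a **two-color (Cy3/Cy5) microarray** workflow and a small
**proteomics** workflow demonstrating that a second laboratory runs on the
same engine unchanged.

## Worked example

The microarray validation scenario — 12 RNA samples, labeled alternately
Cy3/Cy5 and hybridized in differently-dyed pairs onto 6 slides — driven from
the shell:

```console
$ labflow --store store --actor specialist --clock-mode fixed \
      simulate --workflow microarray --samples 12 --seed 0
a1eea400-f72f-51c4-96d2-8ce81beb476a
samples complete: 12/12
```

Every one of the 12 sample traces reached the terminal *Data Analysis*
activity (via its slide's lineage); 78 activity executions were recorded in
all (12 samples × 5 per-sample steps + 6 slides × 3 slide-level steps). The
first line is the new experiment's id; any unambiguous prefix works below.

```console
$ labflow --store store report short --experiment a1eea400 | head -4
sample  activity             repetition  executed_at           executed_by
------  -------------------  ----------  --------------------  -----------
S01     Sample Registration  1           2026-01-05T09:02:00Z  specialist
S02     Sample Registration  1           2026-01-05T09:03:00Z  specialist

$ labflow --store store status --experiment a1eea400 | head -3
S01 [complete]
  executed:  SampleRegistration, RNAExtraction, Cleaning, Amplification, Labeling, Hybridization, Scanning, DataAnalysis
  available: -
```

The same lifecycle is available step by step (`workflow load`,
`project create`, `experiment create`, `sample add`, `exec`, `report`), and
as a library:

```python
from labflow import Lims, FixedClock, build_microarray_workflow

lims = Lims(clock=FixedClock(), id_seed=0)
project = lims.create_project("Expression atlas", actor="alice")
experiment = lims.create_experiment(project, build_microarray_workflow(), actor="alice")
trace = lims.register_sample(experiment, "S01")
lims.available_activities(trace)        # frozenset({'SampleRegistration'})
lims.execute_activity(
    trace, "SampleRegistration",
    {"Sample name": "liver-1", "Collection date": "2026-01-10"},
    actor="alice",
)
```

Invalid entries are refused atomically — a rejected execution leaves the
store byte-identical — with every problem reported at once:

```console
$ labflow --store store exec SampleRegistration --experiment a1eea400 \
      --sample S13 --set "Sample name="
UNKNOWN_SAMPLE: no sample 'S13' in experiment ...
```

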