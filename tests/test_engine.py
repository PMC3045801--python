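"""Runtime engine: lifecycle, availability, execution, repetition,
atomicity, provenance, determinism."""

import random

import pytest

from labflow.engine import (
    EngineError,
    ExecutionRefused,
    FixedClock,
    Lims,
    compute_available,
)
from labflow.fixtures import build_microarray_workflow, random_workflow, simulate_run
from labflow.workflow_model import TransitionSpec

REGISTRATION = {"Sample name": "liver-1", "Collection date": "2026-01-10"}
RNA_OUTPUT = {
    "RNA total concentration": "250.5",
    "RNA final volume": "30",
    "Gel image": "files/gel.png",
    "Dosage method": "Fluorometer",
}


def register_and_extract(lims, experiment, label):
    trace = lims.register_sample(experiment, label)
    reg = lims.execute_activity(
        trace, "SampleRegistration", REGISTRATION, actor="alice"
    )
    extraction = lims.execute_activity(
        trace,
        "RNAExtraction",
        {"Extraction protocol": "TRIzol"},
        chosen_inputs=reg.produced_artifacts,
        output_entries={"ExtractedRNA": [RNA_OUTPUT]},
        actor="alice",
    )
    return trace, extraction


class TestLifecycle:
    def test_fresh_trace_offers_start_activities(self, lims, experiment):
        trace = lims.register_sample(experiment, "S01")
        assert lims.available_activities(trace) == {"SampleRegistration"}

    def test_duplicate_sample_label_refused(self, lims, experiment):
        lims.register_sample(experiment, "S01")
        with pytest.raises(EngineError, match="DUPLICATE_SAMPLE"):
            lims.register_sample(experiment, "S01")

    def test_invalid_workflow_refused_at_experiment_creation(self, lims, microarray):
        microarray.transitions += (TransitionSpec("bad", "Scanning", "Ghost"),)
        project = lims.create_project("P", "alice")
        with pytest.raises(EngineError, match="DANGLING_TRANSITION"):
            lims.create_experiment(project, microarray, "alice")

    def test_workflow_frozen_at_experiment_creation(self, lims, microarray):
        project = lims.create_project("P", "alice")
        experiment = lims.create_experiment(project, microarray, "alice")
        del microarray.activities["DataAnalysis"]  # later edit to the source
        assert "DataAnalysis" in experiment.workflow.activities


class TestAvailabilityAndExecution:
    def test_fork_opens_after_extraction(self, lims, experiment):
        trace, _ = register_and_extract(lims, experiment, "S01")
        assert {"Cleaning", "Amplification", "Labeling"} <= lims.available_activities(trace)

    def test_execution_records_artifacts_and_values(self, lims, experiment):
        trace, extraction = register_and_extract(lims, experiment, "S01")
        assert extraction.repetition_index == 1
        (rna_id,) = extraction.produced_artifacts
        rna = lims.artifacts[rna_id]
        assert rna.artifact_type == "ExtractedRNA"
        assert rna.values["RNA total concentration"] == 250.5
        assert rna.produced_by == extraction.id

    def test_not_available_refused(self, lims, experiment):
        trace = lims.register_sample(experiment, "S01")
        with pytest.raises(ExecutionRefused) as exc_info:
            lims.execute_activity(trace, "Labeling", actor="alice")
        assert exc_info.value.issues[0].code == "NOT_AVAILABLE"

    def test_repetition_appends_new_record(self, lims, experiment):
        trace, first = register_and_extract(lims, experiment, "S01")
        tissue = first.consumed_artifacts
        second = lims.execute_activity(
            trace,
            "RNAExtraction",
            {"Extraction protocol": "Column kit"},
            chosen_inputs=tissue,
            output_entries={"ExtractedRNA": [RNA_OUTPUT]},
            actor="alice",
        )
        assert second.repetition_index == 2
        rnas = [a for a in lims.artifacts.values() if a.artifact_type == "ExtractedRNA"]
        assert len(rnas) == 2
        # both extractions remain selectable downstream
        assert lims.select_inputs(trace, "Cleaning", [rnas[0].id]) == []
        assert lims.select_inputs(trace, "Cleaning", [rnas[1].id]) == []

    def test_repetition_does_not_remove_downstream_history(self, lims, experiment):
        trace, extraction = register_and_extract(lims, experiment, "S01")
        lims.execute_activity(
            trace,
            "Labeling",
            chosen_inputs=extraction.produced_artifacts,
            output_entries={"LabeledSample": [{"Dye": "Cy3"}]},
            actor="alice",
        )
        executions_before = set(lims.executions)
        lims.execute_activity(
            trace,
            "RNAExtraction",
            {"Extraction protocol": "TRIzol"},
            chosen_inputs=extraction.consumed_artifacts,
            output_entries={"ExtractedRNA": [RNA_OUTPUT]},
            actor="alice",
        )
        assert executions_before <= set(lims.executions)


class TestSelectInputs:
    def test_cardinality_and_type_errors(self, lims, experiment):
        trace, extraction = register_and_extract(lims, experiment, "S01")
        (rna,) = extraction.produced_artifacts
        tissue = extraction.consumed_artifacts[0]

        assert lims.select_inputs(trace, "Cleaning", [rna]) == []
        assert [i.code for i in lims.select_inputs(trace, "Cleaning", [])] == [
            "INPUT_COUNT_LOW"
        ]
        assert [i.code for i in lims.select_inputs(trace, "Cleaning", [rna, tissue])] == [
            "TYPE_INCOMPATIBLE"
        ]

    def test_too_many_inputs(self, lims, experiment):
        trace, first = register_and_extract(lims, experiment, "S01")
        second = lims.execute_activity(
            trace,
            "RNAExtraction",
            {"Extraction protocol": "TRIzol"},
            chosen_inputs=first.consumed_artifacts,
            output_entries={"ExtractedRNA": [RNA_OUTPUT]},
            actor="alice",
        )
        chosen = first.produced_artifacts + second.produced_artifacts
        assert [i.code for i in lims.select_inputs(trace, "Cleaning", chosen)] == [
            "INPUT_COUNT_HIGH"
        ]

    def test_foreign_artifact_rejected(self, lims, microarray):
        project = lims.create_project("P", "alice")
        exp_a = lims.create_experiment(project, microarray, "alice")
        exp_b = lims.create_experiment(project, microarray, "alice")
        trace_a, extraction = register_and_extract(lims, exp_a, "S01")
        trace_b, _ = register_and_extract(lims, exp_b, "S01")
        (rna_a,) = extraction.produced_artifacts
        issues = lims.select_inputs(trace_b, "Cleaning", [rna_a])
        assert [i.code for i in issues] == ["FOREIGN_ARTIFACT", "INPUT_COUNT_LOW"]

    def test_same_dye_pair_is_engine_ok(self, lims, experiment):
        """Dye pairing is experimental-design policy, not an engine rule:
        two Cy3-labeled samples still satisfy cardinality and type."""
        labeled = []
        for label in ("S01", "S02"):
            trace, extraction = register_and_extract(lims, experiment, label)
            ex = lims.execute_activity(
                trace,
                "Labeling",
                chosen_inputs=extraction.produced_artifacts,
                output_entries={"LabeledSample": [{"Dye": "Cy3"}]},
                actor="alice",
            )
            labeled.extend(ex.produced_artifacts)
        trace = lims.find_trace(experiment, "S01")
        assert lims.select_inputs(trace, "Hybridization", labeled) == []


class TestAtomicity:
    def test_failed_calls_leave_store_bit_identical(self, lims, experiment):
        trace, extraction = register_and_extract(lims, experiment, "S01")
        before = lims.snapshot_bytes()
        attempts = [
            # invalid attribute value
            dict(entries={"Cleaning kit": ""}, chosen_inputs=extraction.produced_artifacts,
                 output_entries={"ExtractedRNA": [{**RNA_OUTPUT, "RNA final volume": "abc"}]}),
            # input cardinality violation
            dict(entries={}, chosen_inputs=[], output_entries={"ExtractedRNA": [RNA_OUTPUT]}),
            # undeclared output type
            dict(entries={}, chosen_inputs=extraction.produced_artifacts,
                 output_entries={"Slide": [{}], "ExtractedRNA": [RNA_OUTPUT]}),
        ]
        for kw in attempts:
            with pytest.raises(ExecutionRefused):
                lims.execute_activity(trace, "Cleaning", actor="alice", **kw)
            assert lims.snapshot_bytes() == before

    def test_refusal_reports_all_problems_together(self, lims, experiment):
        trace, _ = register_and_extract(lims, experiment, "S01")
        with pytest.raises(ExecutionRefused) as exc_info:
            lims.execute_activity(
                trace,
                "Cleaning",
                chosen_inputs=[],
                output_entries={"ExtractedRNA": [{**RNA_OUTPUT, "Dosage method": "Cy4"}]},
                actor="alice",
            )
        codes = {i.code for i in exc_info.value.issues}  # str-valued enums compare equal
        assert {"INPUT_COUNT_LOW", "NOT_IN_ALLOWED"} <= codes
        assert any(getattr(i, "attribute", None) == "Dosage method" for i in exc_info.value.issues)


class TestProvenanceAndDeterminism:
    def test_provenance_conservation_over_simulated_runs(self):
        for seed in range(5):
            result = simulate_run(build_microarray_workflow(), 4, seed=seed)
            lims = result.lims
            order = {e.id: (e.executed_at, e.id) for e in lims.executions.values()}
            for ex in lims.executions.values():
                for aid in ex.consumed_artifacts:
                    art = lims.artifacts[aid]
                    assert aid in lims.executions[art.produced_by].produced_artifacts
                    assert order[art.produced_by] < order[ex.id]
                    assert ex.id in art.consumed_by

    def test_timestamps_nondecreasing_per_trace(self):
        result = simulate_run(build_microarray_workflow(), 4, seed=1)
        lims = result.lims
        for trace in lims.traces.values():
            times = [lims.executions[eid].executed_at for eid in trace.execution_ids]
            assert times == sorted(times)

    def test_execution_never_removes_availability(self, lims, experiment):
        trace, extraction = register_and_extract(lims, experiment, "S01")
        before = lims.available_activities(trace) | lims.repeatable_activities(trace)
        lims.execute_activity(
            trace,
            "Cleaning",
            chosen_inputs=extraction.produced_artifacts,
            output_entries={"ExtractedRNA": [RNA_OUTPUT]},
            actor="alice",
        )
        after = lims.available_activities(trace) | lims.repeatable_activities(trace)
        assert before <= after

    def test_replay_produces_identical_store(self, microarray):
        def run():
            lims = Lims(clock=FixedClock(), id_seed=42)
            project = lims.create_project("P", "alice")
            experiment = lims.create_experiment(project, microarray, "alice")
            register_and_extract(lims, experiment, "S01")
            return lims

        assert run().snapshot_bytes() == run().snapshot_bytes()
        assert run().event_log_bytes() == run().event_log_bytes()

    def test_save_load_round_trip(self, tmp_path, lims, experiment):
        register_and_extract(lims, experiment, "S01")
        lims.save(tmp_path / "store")
        reloaded = Lims.load(tmp_path / "store")
        assert reloaded.snapshot_bytes() == lims.snapshot_bytes()
        assert reloaded.event_log_bytes() == lims.event_log_bytes()


class TestAvailabilityOracle:
    @staticmethod
    def brute_force(w, executed):
        available = set()
        for aid in w.activities:
            if aid in executed:
                continue
            incoming = [t.from_activity for t in w.transitions if t.to_activity == aid]
            if not incoming or any(p in executed for p in incoming):
                available.add(aid)
        return available

    def test_matches_brute_force_on_random_playouts(self):
        rng = random.Random(321)
        for _ in range(100):
            w = random_workflow(rng, max_activities=30)
            executed = set()
            assert compute_available(w, executed) == self.brute_force(w, executed)
            for _ in range(rng.randint(0, len(w.activities))):
                frontier = compute_available(w, executed)
                if not frontier:
                    break
                executed.add(rng.choice(sorted(frontier)))
                assert compute_available(w, executed) == self.brute_force(w, executed)

    def test_engine_view_matches_brute_force_during_live_run(self, lims, experiment):
        trace, extraction = register_and_extract(lims, experiment, "S01")
        w = experiment.workflow
        executed = lims.executed_activities(trace)
        assert lims.available_activities(trace) == self.brute_force(w, executed)
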