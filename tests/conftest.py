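from pathlib import Path

import pytest

from labflow.engine import FixedClock, Lims
from labflow.fixtures import build_microarray_workflow, build_proteomics_workflow

FIXTURE_DIR = Path(__file__).resolve().parent.parent / "fixtures"


@pytest.fixture
def microarray():
    return build_microarray_workflow()


@pytest.fixture
def proteomics():
    return build_proteomics_workflow()


@pytest.fixture
def lims():
    """A deterministic store: fixed clock, seeded UUID generation."""
    return Lims(clock=FixedClock(), id_seed=123)


@pytest.fixture
def experiment(lims, microarray):
    project = lims.create_project("Expression atlas", actor="alice")
    return lims.create_experiment(project, microarray, actor="alice")
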