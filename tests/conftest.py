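from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

DATA_DIR = Path(__file__).parent / "data"
FIXTURE_CHART = DATA_DIR / "fixture_cohort.csv"
FIXTURE_SEED = 7
FIXTURE_N = 10


@pytest.fixture
def fixture_chart_path() -> Path:
    return FIXTURE_CHART


@pytest.fixture
def fixture_spec():
    from natribalance import CohortSpec

    return CohortSpec(n_patients=FIXTURE_N, seed=FIXTURE_SEED)


@pytest.fixture
def simple_epoch():
    """70 kg patient at 140 mmol/L with one liter of isotonic saline infused."""
    from natribalance import FluidFlux, PatientEpoch

    return PatientEpoch(
        patient_id="P1",
        epoch_label="epoch1",
        weight=70.0,
        na_initial=140.0,
        fluxes=(FluidFlux(kind="infused", volume=1.0, na_conc=154.0),),
    )
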