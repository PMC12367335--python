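import numpy as np
import pytest

from wtlstm.data import CohortTable, StayRecord
from wtlstm.simulate import preset, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> CohortTable:
    """120 fully-observed signal-rich synthetic stays (shared, read-only)."""
    return simulate_cohort(preset("signal-rich", n_stays=120, seed=42, missing_rate=0.0))


@pytest.fixture(scope="session")
def medium_cohort() -> CohortTable:
    """400 fully-observed signal-rich synthetic stays (shared, read-only)."""
    return simulate_cohort(preset("signal-rich", n_stays=400, seed=7, missing_rate=0.0))


@pytest.fixture
def long_stay() -> StayRecord:
    """One fully-observed 48 h stay on the 5-minute grid."""
    n = 48 * 12
    rng = np.random.default_rng(0)
    return StayRecord(
        stay_id="stay-1",
        diagnosis="HF",
        los=3.5,
        heartrate=85 + rng.normal(0, 5, n),
        respiration=18 + rng.normal(0, 2, n),
        sao2=np.clip(96 + rng.normal(0, 1, n), 0, 100),
    )
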