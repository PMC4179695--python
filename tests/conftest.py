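import numpy as np
import pytest

from dacircuit import (
    ModelParameters,
    TimingConfig,
    TrialType,
    build_schedule,
    run_session,
)
from dacircuit.analysis import FiringTrace, SessionResult


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def timing():
    return TimingConfig()


@pytest.fixture(scope="session")
def baseline_session(params, timing):
    """One full default 488-trial session of the baseline individual."""
    return run_session(params, build_schedule(seed=1), timing)


@pytest.fixture(scope="session")
def mini_session(params, timing):
    """A short 28-trial session preserving the 80/20 contingency structure."""
    schedule = build_schedule({"PR": 10, "PNR": 10, "UR": 4, "UNR": 4}, seed=2)
    return run_session(params, schedule, timing)


def synthetic_session(rate_rows, timing, trial_types=None):
    """Build a SessionResult from raw per-trial bin-rate arrays (spikes/bin)."""
    trial_types = trial_types or list(TrialType)
    n_bins = rate_rows[0].shape[0]
    traces = [
        FiringTrace(
            trial_type=tt,
            bin_start=np.arange(n_bins) * timing.bin_width,
            rates=np.asarray(row, dtype=float),
            bin_width=timing.bin_width,
        )
        for tt, row in zip(trial_types, rate_rows)
    ]
    counts = {tt.value: sum(1 for t in traces if t.trial_type is tt)
              for tt in TrialType}
    schedule = build_schedule(counts, seed=0, shuffle=False)
    return SessionResult(traces=traces, schedule=schedule, timing=timing)
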