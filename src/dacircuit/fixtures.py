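"""Deterministic miniature fixtures for tests and quick demonstrations.

Everything here is synthetic and generated at call time: a shortened trial
schedule, toy binned traces with known window statistics, and toy cohorts
with planted parameter-output relationships (an exact line with known r and a
step function with a known breakpoint).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .task import TrialSchedule, build_schedule

__all__ = ["MINI_COUNTS", "make_fixtures", "linear_cohort", "step_cohort"]

MINI_COUNTS = {"PR": 10, "PNR": 10, "UR": 4, "UNR": 4}


def linear_cohort(n: int = 20, slope: float = 2.0, intercept: float = 1.0,
                  seed: int = 0) -> pd.DataFrame:
    """Cohort whose output is an exact linear function of the parameter.

    Pearson r is exactly 1 (for positive slope) and the output SD is
    ``slope`` times the parameter SD.
    """
    rng = np.random.default_rng(seed)
    values = rng.normal(1.0, 0.3, size=n)
    out = slope * values + intercept
    return pd.DataFrame(
        {
            "individual_id": np.arange(n),
            "parameter_value": values,
            "s2_output": out,
            "s1_output": 3.0 * out,
        }
    )


def step_cohort(n: int = 20, breakpoint: float = 0.8, low: float = 0.1,
                high: float = 0.22) -> pd.DataFrame:
    """Cohort whose output steps from ``low`` to ``high`` at ``breakpoint``."""
    values = np.linspace(0.1, 2.0, n)
    out = np.where(values < breakpoint, low, high)
    return pd.DataFrame(
        {
            "individual_id": np.arange(n),
            "parameter_value": values,
            "s2_output": out,
            "s1_output": out,
        }
    )


def ramp_trace_frame(n_bins: int = 25, bin_width: float = 0.020
                     ) -> pd.DataFrame:
    """A toy linearly ramping binned trace with hand-computable window means."""
    starts = np.arange(n_bins) * bin_width
    return pd.DataFrame({"bin_start_s": starts,
                         "rate_spikes_per_bin": 0.01 * np.arange(n_bins)})


def make_fixtures(seed: int = 0) -> dict[str, object]:
    """Build the full fixture set used by the test-suite and CLI demos."""
    schedule: TrialSchedule = build_schedule(MINI_COUNTS, seed=seed)
    return {
        "mini_schedule": schedule,
        "linear_cohort": linear_cohort(seed=seed),
        "step_cohort": step_cohort(),
        "ramp_trace": ramp_trace_frame(),
    }
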