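"""Binned firing traces and endophenotype outputs.

The simulated endophenotype is a pair of baseline-referenced DA firing
statistics measured on 20 ms-binned condition-average traces:

* the S2 output -- mean firing over the first 300 ms after S2 onset minus the
  mean over the 100 ms before S2, for UR trials minus UNR trials;
* the S1 output -- the same windows mirrored onto S1 onset, for the mean of
  the PR and UNR conditions minus the mean of the UR and PNR conditions
  (the conditions whose S1 stimulus is reward-predictive minus those whose
  S1 stimulus is not).

All binned values are expressed as spikes per 20 ms bin (mean rate within the
bin times the bin width).  Both outputs are linear in the traces, so
normalising per trial then averaging and averaging then normalising coincide;
the implementation averages first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import TimingConfig, TrialSchedule, TrialType

__all__ = [
    "FiringTrace",
    "SessionResult",
    "ConditionAverages",
    "EndophenotypeOutput",
    "bin_rates",
    "normalized_window_mean",
    "condition_average",
    "s2_output",
    "s1_output",
    "endophenotype_output",
]


def bin_rates(rates: np.ndarray, dt: float, bin_width: float) -> np.ndarray:
    """Collapse an instantaneous rate trace (spikes/s) into spikes-per-bin.

    Each bin value is the mean rate within the bin multiplied by the bin
    width, i.e. the expected spike count of the bin.  Trailing samples that do
    not fill a complete bin are dropped.
    """
    per_bin = int(round(bin_width / dt))
    if not np.isclose(per_bin * dt, bin_width, rtol=1e-9, atol=1e-12):
        raise ValueError("bin_width must be an integer multiple of dt")
    n_bins = rates.shape[0] // per_bin
    trimmed = rates[: n_bins * per_bin].reshape(n_bins, per_bin)
    return trimmed.mean(axis=1) * bin_width


@dataclass(frozen=True)
class FiringTrace:
    """DA firing of one trial in 20 ms bins (spikes per bin)."""

    trial_type: TrialType
    bin_start: np.ndarray        # seconds from trial start
    rates: np.ndarray            # expected spikes per bin, >= 0
    bin_width: float = 0.020
    events: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_start.shape != self.rates.shape:
            raise ValueError("bin_start and rates must align")

    def window_mean(self, window: tuple[float, float]) -> float:
        """Mean spikes-per-bin over bins whose start lies in [lo, hi)."""
        lo, hi = window
        mask = (self.bin_start >= lo - 1e-9) & (self.bin_start < hi - 1e-9)
        expected = int(round((hi - lo) / self.bin_width))
        if int(mask.sum()) != expected:
            raise ValueError(
                f"window [{lo}, {hi}) s is not fully covered by this trace "
                f"(bins span [{self.bin_start[0]}, "
                f"{self.bin_start[-1] + self.bin_width}) s)"
            )
        return float(self.rates[mask].mean())


def normalized_window_mean(
    trace: FiringTrace,
    window: tuple[float, float],
    baseline_window: tuple[float, float],
) -> float:
    """Window mean minus baseline-window mean, both in spikes per bin.

    Windows are absolute trial times; callers shift event-relative windows by
    the relevant onset before calling.
    """
    return trace.window_mean(window) - trace.window_mean(baseline_window)


@dataclass
class SessionResult:
    """All per-trial firing traces of one simulated individual's session."""

    traces: list[FiringTrace]
    schedule: TrialSchedule
    timing: TimingConfig
    final_state: object | None = None  # learned CircuitState after the run

    def by_type(self, trial_type: TrialType) -> list[FiringTrace]:
        return [tr for tr in self.traces if tr.trial_type is trial_type]


@dataclass(frozen=True)
class ConditionAverages:
    """Per-trial-type arithmetic mean of the binned traces."""

    traces: dict[TrialType, FiringTrace]
    counts: dict[TrialType, int]
    missing: tuple[TrialType, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for trial_type, trace in self.traces.items():
            rows.append(
                pd.DataFrame(
                    {
                        "trial_type": trial_type.value,
                        "bin_start_s": trace.bin_start,
                        "mean_rate": trace.rates,
                        "n_trials": self.counts[trial_type],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def condition_average(
    session: SessionResult,
    types: tuple[TrialType, ...] = tuple(TrialType),
) -> ConditionAverages:
    """Average the session's traces within each requested trial type.

    Types with no trials in the session are reported in ``missing`` and
    excluded from the averages.
    """
    averages: dict[TrialType, FiringTrace] = {}
    counts: dict[TrialType, int] = {}
    missing: list[TrialType] = []
    for trial_type in types:
        group = session.by_type(trial_type)
        if not group:
            missing.append(trial_type)
            continue
        stack = np.stack([tr.rates for tr in group])
        averages[trial_type] = FiringTrace(
            trial_type=trial_type,
            bin_start=group[0].bin_start,
            rates=stack.mean(axis=0),
            bin_width=group[0].bin_width,
            events=dict(group[0].events),
        )
        counts[trial_type] = len(group)
    return ConditionAverages(traces=averages, counts=counts,
                             missing=tuple(missing))


def _event_windows(
    timing: TimingConfig, onset: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    lo, hi = timing.analysis_window
    blo, bhi = timing.baseline_window
    return (onset + lo, onset + hi), (onset + blo, onset + bhi)


def _normalized_by_type(
    session: SessionResult, onset: float
) -> dict[TrialType, float]:
    averages = condition_average(session)
    window, baseline = _event_windows(session.timing, onset)
    return {
        trial_type: normalized_window_mean(trace, window, baseline)
        for trial_type, trace in averages.traces.items()
    }


def s2_by_type(session: SessionResult) -> dict[TrialType, float]:
    """Baseline-referenced S2-window firing per condition (spikes/bin)."""
    return _normalized_by_type(session, session.timing.s2_onset)


def s2_output(session: SessionResult) -> float:
    """The key endophenotype output: S2 firing for UR minus UNR trials."""
    values = s2_by_type(session)
    return values[TrialType.UR] - values[TrialType.UNR]


def s1_output(session: SessionResult) -> float:
    """S1 difference wave: mean(PR, UNR) minus mean(UR, PNR) at S1.

    Unweighted condition-level means are used on both sides despite the
    unequal trial counts, mirroring how a condition-level ERP difference wave
    is formed.
    """
    values = _normalized_by_type(session, session.timing.s1_onset)
    return 0.5 * (values[TrialType.PR] + values[TrialType.UNR]) - 0.5 * (
        values[TrialType.UR] + values[TrialType.PNR]
    )


@dataclass(frozen=True)
class EndophenotypeOutput:
    """The scalar outputs extracted from one session."""

    s2_by_type: dict[TrialType, float]
    s2_diff: float
    s1_diff: float

    def to_frame(self) -> pd.DataFrame:
        row = {f"s2_{t.value}": v for t, v in self.s2_by_type.items()}
        row["s2_diff_UR_minus_UNR"] = self.s2_diff
        row["s1_diff"] = self.s1_diff
        return pd.DataFrame([row])


def endophenotype_output(session: SessionResult) -> EndophenotypeOutput:
    values = s2_by_type(session)
    return EndophenotypeOutput(
        s2_by_type=values,
        s2_diff=values[TrialType.UR] - values[TrialType.UNR],
        s1_diff=s1_output(session),
    )
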