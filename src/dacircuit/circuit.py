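"""Modified Brown-Bullock-Grossberg (BBG) opponent-pathway DA circuit.

The model simulates the phasic firing of midbrain dopamine cells as the
balance of two converging pathways:

* an **excitatory reward pathway** -- primary reward acts on the lateral
  hypothalamus (LH), driving the pedunculopontine tegmental nucleus (PPTN)
  both directly and via conditioned ventral-striatal (VS, nucleus accumbens)
  responses to working-memory stimulus representations; the PPTN excites the
  DA cells;
* an **inhibitory, temporally precise reward-prediction pathway** -- cortical
  working-memory representations drive an array of striatal striosomal cells
  with spectral timing: each cell is transiently active at its own delay after
  WM onset, so the array can learn to inhibit the DA cells exactly when a
  stimulus-predicted reward is due.

Plastic weights on both pathways change under a three-factor rule gated by the
phasic DA signal itself (burst ``N+`` above baseline, dip ``N-`` below it).
The WM representations follow a leaky charging equation so that they decay
only partially across the inter-stimulus gaps of a trial but fully between
trials, which re-arms the spectral-timing clock for the next stimulus
presentation.

Working memory dynamics and the WM gate (the model's own additions to the
original circuit) are::

    dx_i/dt = tau_x * ((M_x - x_i) * I_i - A_x * x_i)
    xx_i    = 1 if x_i > theta_x else 0

All other stages are leaky integrators with rectified-threshold outputs; the
DA firing rate is floored at zero, which makes the attainable phasic dip
(bounded by the low tonic baseline) much smaller than the attainable burst --
the circuit's basic excitatory/inhibitory asymmetry.

The model is noise-free: identical parameters and schedule give bit-identical
traces, and the emitted rates are deterministic expected spikes per bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np

from . import _kernels
from .analysis import FiringTrace, SessionResult, bin_rates
from .task import (
    StimulusTimeline,
    TimingConfig,
    TrialSchedule,
    TrialType,
    trial_timeline,
)

__all__ = [
    "ModelParameters",
    "DAState",
    "CircuitState",
    "CircuitIntegrationError",
    "timing_peaks",
    "timing_table",
    "wm_step",
    "wm_gate",
    "timing_activation",
    "vs_step",
    "pptn_step",
    "da_step",
    "learn_excitatory",
    "learn_inhibitory",
    "run_trial",
    "run_trial_reference",
    "run_session",
]


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter set of one simulated individual.

    The first block holds the biologically mapped parameters that the
    sensitivity analysis perturbs (weights and gains at numbered circuit
    locations, learning-rule constants).  The second block holds fixed
    structural constants: working-memory dynamics, thresholds, membrane and
    habituation rates, the DA spiking baseline/gain, learning gain scales and
    the spectral-timing array geometry.  Structural constants were calibrated
    once, with every mapped parameter at its population mean, so that the
    baseline individual's S2 outputs land near the reference operating point;
    they are configuration, not hard-coded.
    """

    # --- biologically mapped weights and gains (sweep targets) ----------
    w_pd: float = 5.0        # PPTN -> DA cells (location 1)
    w_sp: float = 2.0        # VS -(VP)-> PPTN, nett excitatory (location 5)
    w_rp: float = 0.8        # LH reward -> PPTN (location 6)
    w_rs: float = 1.5        # LH reward -> VS (location 7)
    w_max_s: float = 1.0     # VS weight ceiling / DA-burst efficacy at VS
    tau_ws: float = 1.0      # VS weight-change rate constant (location 4),
                             # multiplicative: larger = faster learning
    beta_ws: float = 0.5     # VS weight-decrease rate under N- (location 4)
    h_d: float = 6.0         # striosomal inhibition gain at DA cells (loc. 2)
    gamma_s: float = 100.0   # striosomal learning gain (location 3)
    alpha_z: float = 0.05    # striosomal weight-change rate (location 3)

    # --- working memory and thresholds ----------------------------------
    m_x: float = 1.0         # WM ceiling
    tau_x: float = 30.0      # WM rate constant (1/s)
    a_x: float = 0.02        # WM decay coefficient
    theta_x: float = 0.3     # WM gate threshold
    gamma_g: float = 0.495   # VS output threshold
    theta_s: float = 0.495   # VS post-synaptic learning threshold

    # --- membrane, habituation and spiking constants ---------------------
    baseline_rate: float = 2.5   # DA tonic rate, spikes/s
    da_gain: float = 18.0        # spikes/s per unit membrane drive
    lambda_s: float = 40.0       # VS membrane rate, 1/s
    lambda_p: float = 50.0       # PPTN membrane rate, 1/s
    lambda_d: float = 50.0       # DA membrane rate, 1/s
    tau_rec: float = 0.6         # PPTN habituation recovery, s
    tau_dep: float = 0.2        # PPTN habituation depression, s
    theta_pre: float = 0.5       # presynaptic eligibility threshold on x_i
    k_learn: float = 0.04        # VS learning gain (per spike/s of N+/-)
    k_z: float = 3.5e-4           # striosomal learning gain scale
    beta_z: float = 300.0         # striosomal weight-decrease gain under N-
    r_amp: float = 1.0           # LH primary-reward input amplitude
    z_max: float = 0.3           # striosomal weight ceiling

    # --- spectral-timing array geometry ----------------------------------
    n_timing: int = 40           # timing cells per stimulus node
    t_first: float = 0.35         # earliest peak delay, s
    t_last: float = 3.0          # latest peak delay, s
    sigma0: float = 0.02        # kernel width at zero delay, s
    sigma_slope: float = 0.015    # width growth per second of delay (Weber)

    def __post_init__(self) -> None:
        non_negative = (
            "w_pd", "w_sp", "w_rp", "w_rs", "tau_ws", "beta_ws",
            "h_d", "gamma_s", "alpha_z", "theta_s", "gamma_g",
            "baseline_rate", "da_gain", "k_learn", "k_z", "r_amp",
            "theta_pre", "beta_z",
        )
        for name in non_negative:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.w_max_s <= 0 or self.z_max <= 0:
            raise ValueError("weight ceilings must be > 0")
        if not 0 < self.theta_x < self.m_x:
            raise ValueError("theta_x must lie in (0, m_x)")
        if self.n_timing < 1 or self.t_first <= 0 or self.t_last <= self.t_first:
            raise ValueError("invalid spectral-timing geometry")
        if self.sigma0 <= 0 or self.sigma_slope < 0:
            raise ValueError("invalid spectral-timing kernel widths")

    # -- serialisation ----------------------------------------------------
    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, values: dict[str, float]) -> "ModelParameters":
        unknown = set(values) - set(cls.field_names())
        if unknown:
            raise ValueError(
                f"unknown parameter(s) {sorted(unknown)}; "
                f"valid names: {', '.join(cls.field_names())}"
            )
        return cls(**values)

    def with_value(self, name: str, value: float) -> "ModelParameters":
        if name not in self.field_names():
            raise ValueError(
                f"unknown parameter {name!r}; "
                f"valid names: {', '.join(self.field_names())}"
            )
        return replace(self, **{name: value})

    def to_vector(self) -> np.ndarray:
        return np.array(
            [getattr(self, name) for name in _kernels.PARAM_ORDER],
            dtype=np.float64,
        )


def timing_peaks(params: ModelParameters) -> np.ndarray:
    """Peak delays t_j of the spectral-timing cells (seconds)."""
    return np.linspace(params.t_first, params.t_last, params.n_timing)


def timing_sigmas(params: ModelParameters) -> np.ndarray:
    """Kernel widths; grow linearly with delay (scalar-timing property)."""
    return params.sigma0 + params.sigma_slope * timing_peaks(params)


def timing_table(params: ModelParameters, dt: float) -> np.ndarray:
    """Tabulate the Gaussian timing kernels on the integration grid.

    ``F[j, k]`` is cell j's activation at elapsed time ``k * dt`` since the WM
    gate crossed; each kernel has unit peak.  The table extends four widths
    past the last peak, after which activations are treated as zero.
    """
    peaks = timing_peaks(params)
    sigmas = timing_sigmas(params)
    horizon = params.t_last + 4.0 * sigmas[-1]
    k = np.arange(int(math.ceil(horizon / dt)) + 1)
    t = k * dt
    return np.exp(-((t[None, :] - peaks[:, None]) ** 2)
                  / (2.0 * sigmas[:, None] ** 2))


# ---------------------------------------------------------------------------
# Elementary operations (pure-Python reference forms)
# ---------------------------------------------------------------------------

def wm_step(x: float, stimulus_on: float, params: ModelParameters,
            dt: float) -> float:
    """One Euler step of the WM charging equation, clamped to [0, M_x]."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    x = x + dt * params.tau_x * (
        (params.m_x - x) * stimulus_on - params.a_x * x
    )
    return min(max(x, 0.0), params.m_x)


def wm_gate(x: float, params: ModelParameters) -> int:
    """Binary WM gate: 1 iff the activation strictly exceeds theta_x."""
    return 1 if x > params.theta_x else 0


def timing_activation(elapsed: float | None,
                      params: ModelParameters) -> np.ndarray:
    """Activations f_j of one node's timing cells at ``elapsed`` seconds.

    ``elapsed is None`` means the WM gate never crossed: all cells silent.
    """
    if elapsed is None:
        return np.zeros(params.n_timing)
    peaks = timing_peaks(params)
    sigmas = timing_sigmas(params)
    return np.exp(-((elapsed - peaks) ** 2) / (2.0 * sigmas**2))


def vs_step(s: np.ndarray, x: np.ndarray, w_s: np.ndarray, reward: float,
            params: ModelParameters, dt: float) -> tuple[np.ndarray, float]:
    """Leaky integration of the VS medium-spiny cells.

    One cell per stimulus node, each integrating the shared primary-reward
    drive plus its own conditioned cortical input; the pallidal-relay output
    is the summed rectified-threshold activity.  Returns (new S vector,
    output).
    """
    drive = params.w_rs * reward + w_s * x
    s = s + dt * params.lambda_s * (drive - s)
    return s, float(np.maximum(0.0, s - params.gamma_g).sum())


def pptn_step(p: float, habituation: float, s_out: float, reward: float,
              params: ModelParameters, dt: float) -> tuple[float, float, float]:
    """PPTN relay with onset habituation; returns (p, habituation, output P).

    The habituation variable depresses while *any* drive is present and
    recovers otherwise, so the response to a sustained input is phasic: a fast
    onset peak decaying toward a lower plateau.  Because depression depends
    only on the presence of drive, the integrated response stays linear in the
    drive amplitude.
    """
    drive = params.w_rp * reward + params.w_sp * s_out
    occupied = 1.0 if drive > 1e-6 else 0.0
    habituation = habituation + dt * (
        (1.0 - habituation) / params.tau_rec
        - occupied * habituation / params.tau_dep
    )
    habituation = min(max(habituation, 0.0), 1.0)
    p = p + dt * params.lambda_p * (drive * habituation - p)
    return p, habituation, p


@dataclass(frozen=True)
class DAState:
    """Instantaneous DA firing decomposed around the tonic baseline."""

    rate: float          # spikes/s, >= 0
    baseline: float      # tonic rate, spikes/s
    n_plus: float        # phasic burst magnitude above baseline
    n_minus: float       # phasic dip magnitude below baseline (<= baseline)


def da_step(d: float, pptn: float, strio: float, params: ModelParameters,
            dt: float) -> tuple[float, DAState]:
    """DA membrane step under opponent drive; rate floored at zero."""
    d = d + dt * params.lambda_d * (
        params.w_pd * pptn - params.h_d * strio - d
    )
    rate = max(0.0, params.baseline_rate + params.da_gain * d)
    return d, DAState(
        rate=rate,
        baseline=params.baseline_rate,
        n_plus=max(0.0, rate - params.baseline_rate),
        n_minus=max(0.0, params.baseline_rate - rate),
    )


def learn_excitatory(w_s: np.ndarray, x: np.ndarray, s: np.ndarray,
                     n_plus: float, n_minus: float,
                     params: ModelParameters, dt: float) -> np.ndarray:
    """Three-factor update of the cortico-accumbens weights.

    Requires presynaptic WM activity above ``theta_pre``, post-synaptic
    depolarization of the cell's own VS unit above ``theta_s``, and a phasic
    DA event; bursts drive the weight toward its ceiling, dips (scaled by
    beta_ws) toward zero.  ``s`` is the per-cell VS activation vector.
    """
    if n_plus == 0.0 and n_minus == 0.0:
        return w_s.copy()
    post = np.maximum(0.0, np.asarray(s) - params.theta_s)
    pre = np.maximum(x - params.theta_pre, 0.0)
    dw = (params.k_learn * params.tau_ws) * pre * post * (
        n_plus * (params.w_max_s - w_s) - params.beta_ws * n_minus * w_s
    ) * dt
    return np.clip(w_s + dw, 0.0, params.w_max_s)


def learn_inhibitory(z: np.ndarray, f: np.ndarray, n_plus: float,
                     n_minus: float, params: ModelParameters,
                     dt: float) -> np.ndarray:
    """Three-factor update of the striosomal timing weights.

    Only cells whose timing kernel is currently active (f above threshold)
    are eligible; the learning gain gamma_s scales burst-driven increases.
    """
    if n_plus == 0.0 and n_minus == 0.0:
        return z.copy()
    eligible = f > _kernels.F_EPS
    dz = params.alpha_z * params.k_z * f * (
        params.gamma_s * n_plus * (params.z_max - z)
        - params.beta_z * n_minus * z
    ) * dt
    return np.clip(z + np.where(eligible, dz, 0.0), 0.0, params.z_max)


# ---------------------------------------------------------------------------
# State container and integrators
# ---------------------------------------------------------------------------

class CircuitIntegrationError(RuntimeError):
    """A state variable became non-finite during integration."""


@dataclass
class CircuitState:
    """All dynamical variables and plastic weights of one individual.

    Node index 0 is the gold-bar stimulus, index 1 the lemons.  ``scalars``
    packs [S_gold, S_lemon (VS cell activations), h (PPTN habituation),
    p (PPTN output), d (DA membrane)].
    """

    x: np.ndarray                  # WM activations, shape (2,)
    active: np.ndarray             # timing clock armed, bool (2,)
    elapsed: np.ndarray            # timing clock, integration steps (2,)
    w_s: np.ndarray                # VS plastic weights (2,)
    z: np.ndarray                  # striosomal weights (2, n_timing)
    scalars: np.ndarray            # [S, h, p, d]
    clock: float = 0.0             # simulation time, s

    @classmethod
    def fresh(cls, params: ModelParameters) -> "CircuitState":
        return cls(
            x=np.zeros(2),
            active=np.zeros(2, dtype=np.bool_),
            elapsed=np.zeros(2, dtype=np.int64),
            w_s=np.zeros(2),
            z=np.zeros((2, params.n_timing)),
            scalars=np.array([0.0, 0.0, 1.0, 0.0, 0.0]),
        )

    def copy(self) -> "CircuitState":
        return CircuitState(
            x=self.x.copy(), active=self.active.copy(),
            elapsed=self.elapsed.copy(), w_s=self.w_s.copy(),
            z=self.z.copy(), scalars=self.scalars.copy(), clock=self.clock,
        )

    def to_dict(self) -> dict:
        return {
            "x": self.x.tolist(),
            "active": self.active.astype(int).tolist(),
            "elapsed": self.elapsed.tolist(),
            "w_s": self.w_s.tolist(),
            "z": self.z.tolist(),
            "scalars": self.scalars.tolist(),
            "clock": self.clock,
        }


def _integrate(state: CircuitState, timeline: StimulusTimeline,
               params: ModelParameters, table: np.ndarray) -> np.ndarray:
    rates = np.empty(timeline.n_steps)
    code = _kernels.integrate_trial(
        state.x, state.active, state.elapsed, state.w_s, state.z,
        state.scalars, timeline.i_gold, timeline.i_lemon, timeline.reward,
        table, params.to_vector(), timeline.dt, rates,
    )
    state.clock += timeline.n_steps * timeline.dt
    if code != 0:
        raise CircuitIntegrationError(
            f"non-finite state in {_kernels.ERROR_SUBSYSTEM[code]} "
            f"at t = {state.clock:.3f} s"
        )
    return rates


def run_trial(state: CircuitState, timeline: StimulusTimeline,
              params: ModelParameters, bin_width: float = 0.020,
              table: np.ndarray | None = None,
              ) -> tuple[FiringTrace, CircuitState]:
    """Integrate one trial, returning the binned DA trace and carried state."""
    if table is None:
        table = timing_table(params, timeline.dt)
    rates = _integrate(state, timeline, params, table)
    binned = bin_rates(rates, timeline.dt, bin_width)
    trace = FiringTrace(
        trial_type=timeline.trial_type,
        bin_start=np.arange(binned.shape[0]) * bin_width,
        rates=binned,
        bin_width=bin_width,
        events=dict(timeline.events),
    )
    return trace, state


def run_trial_reference(state: CircuitState, timeline: StimulusTimeline,
                        params: ModelParameters) -> np.ndarray:
    """Slow pure-Python integrator composed of the elementary operations.

    Exists as an independent cross-check of the compiled kernel; only suitable
    for short timelines.  Returns the instantaneous rate trace (spikes/s).
    """
    dt = timeline.dt
    peaks = timing_peaks(params)
    sigmas = timing_sigmas(params)
    horizon = params.t_last + 4.0 * sigmas[-1]
    rates = np.empty(timeline.n_steps)
    for t in range(timeline.n_steps):
        inputs = (timeline.i_gold[t], timeline.i_lemon[t])
        reward = timeline.reward[t]
        for i in range(2):
            self_x = wm_step(state.x[i], inputs[i], params, dt)
            state.x[i] = self_x
            if wm_gate(self_x, params):
                if state.active[i]:
                    state.elapsed[i] += 1
                else:
                    state.active[i] = True
                    state.elapsed[i] = 0
            else:
                state.active[i] = False
        s, s_out = vs_step(state.scalars[:2], state.x, state.w_s, reward,
                           params, dt)
        state.scalars[:2] = s
        f = np.zeros((2, params.n_timing))
        for i in range(2):
            elapsed_s = state.elapsed[i] * dt
            if state.active[i] and elapsed_s <= horizon:
                f[i] = timing_activation(elapsed_s, params)
        strio = float((state.z * f).sum())
        p, hab, pptn = pptn_step(state.scalars[3], state.scalars[2], s_out,
                                 reward, params, dt)
        state.scalars[2] = hab
        state.scalars[3] = p
        d, da = da_step(state.scalars[4], pptn, strio, params, dt)
        state.scalars[4] = d
        rates[t] = da.rate
        state.w_s = learn_excitatory(state.w_s, state.x, s, da.n_plus,
                                     da.n_minus, params, dt)
        for i in range(2):
            if state.active[i]:
                state.z[i] = learn_inhibitory(state.z[i], f[i], da.n_plus,
                                              da.n_minus, params, dt)
    state.clock += timeline.n_steps * dt
    return rates


def run_session(params: ModelParameters, schedule: TrialSchedule,
                timing: TimingConfig,
                state: CircuitState | None = None) -> SessionResult:
    """Run a full session with persistent learning across trials.

    Deterministic given (params, schedule, timing): the model is noise-free.
    """
    if state is None:
        state = CircuitState.fresh(params)
    table = timing_table(params, timing.dt)
    timelines = {
        trial_type: trial_timeline(trial_type, timing, r_amp=params.r_amp)
        for trial_type in TrialType
    }
    traces: list[FiringTrace] = []
    for index, trial_type in enumerate(schedule.trials):
        try:
            trace, state = run_trial(
                state, timelines[trial_type], params,
                bin_width=timing.bin_width, table=table,
            )
        except CircuitIntegrationError as err:
            raise CircuitIntegrationError(
                f"trial {index} ({trial_type.value}): {err}"
            ) from err
        traces.append(trace)
    return SessionResult(traces=traces, schedule=schedule, timing=timing,
                         final_state=state)
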