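# Model and methods

## The circuit

`dacircuit` simulates phasic firing of midbrain dopamine (DA) cells as the
balance of two opponent pathways converging on them, following the
Brown–Bullock–Grossberg (BBG) circuit architecture with a leaky
working-memory front end:

* **Excitatory reward pathway.** Primary reward acts on the lateral
  hypothalamus (LH), which excites the pedunculopontine tegmental nucleus
  (PPTN) directly (weight `w_rp`) and also drives ventral-striatal (VS)
  medium-spiny cells (weight `w_rs`). VS cells additionally receive
  cortical working-memory (WM) inputs through plastic weights `w_s[i]`, so
  conditioned stimuli acquire the ability to excite the PPTN through the
  (net-excitatory, via ventral pallidum) VS→PPTN relay (weight `w_sp`). The
  PPTN excites the DA cells (weight `w_pd`).
* **Inhibitory, timed reward-prediction pathway.** The same WM
  representations drive, per stimulus, an array of striosomal cells with
  *spectral timing*: cell *j* is transiently active around its own delay
  `t_j` after the WM gate opens. Plastic weights `z[i, j]` learn a
  temporally precise reward prediction whose summed output inhibits the DA
  cells with gain `h_d`.

A positive reward-prediction error (reward arriving unpredicted) therefore
produces a firing burst `N+`; a fully predicted reward is cancelled by the
timed inhibition; an omitted predicted reward produces a dip `N-`. Because
the tonic baseline is low (2.5 spikes/s by default) and the rate is floored
at zero, the attainable dip is much smaller than the attainable burst — the
circuit's built-in excitatory/inhibitory asymmetry.

### Working memory

Each stimulus has one WM node obeying

    dx/dt = tau_x * ((M_x - x) * I - A_x * x),        xx = [x > theta_x]

with `M_x = 1`, `tau_x = 30`, `A_x = 0.02`, `theta_x = 0.3`. With the
stimulus on, `x` charges to `M_x/(1+A_x) ≈ 0.98` within ~50 ms; with it
off, `x` decays with time constant `1/(tau_x*A_x) ≈ 1.7 s` — *partial*
decay across the within-trial gaps, full decay across the inter-trial
interval. The binary gate `xx` arms the spectral-timing clock: the clock
starts at the upward gate crossing and is disarmed (and re-armable) when
`x` falls back below `theta_x`. This is why the default inter-trial
interval is 2.0 s: anything much shorter leaves `x` above `theta_x` at the
next trial's S1, the gate never closes, and the timing clock cannot re-arm
for the next presentation.

### Spectral timing

Each node owns `n_timing = 40` cells with Gaussian activation kernels of
unit peak, peak delays tiling 0.35–3.0 s, and widths growing linearly with
delay (`sigma = 0.02 + 0.015 * t_j`; the scalar-timing property). The
first peak is late enough that a conditioned burst at stimulus onset cannot
train inhibition against itself; the earliest reliable predictor of reward
therefore keeps its burst, as observed in conditioning experiments.

### PPTN, DA cell

The PPTN is a leaky relay (rate `lambda_p`) with onset habituation: a
depression variable falls with time constant `tau_dep = 0.2 s` while any
drive is present and recovers with `tau_rec = 0.6 s`, so sustained drive
produces a phasic onset peak decaying toward a plateau. Depression is
gated by the *presence* of drive, not its amplitude, which keeps the
integrated response linear in the input weights. The DA membrane
integrates `w_pd * PPTN - h_d * G` with leak; the firing rate is
`max(0, baseline + da_gain * membrane)`.

### Three-factor learning

Both plastic pathways change only when a phasic DA event is present:

    dw_s[i] = k_learn * tau_ws * [x_i - theta_pre]+ * [S_i - theta_s]+
              * (N+ * (w_max_s - w_s[i]) - beta_ws * N- * w_s[i]) * dt
    dz[i,j] = alpha_z * k_z * f_ij
              * (gamma_s * N+ * (z_max - z[i,j]) - beta_z * N- * z[i,j]) * dt

The VS rule requires presynaptic WM activity above `theta_pre = 0.5` and
post-synaptic depolarization of that stimulus's own VS cell above
`theta_s = 0.495` (`theta_s` defaults to the VS output threshold
`gamma_g`). Both thresholds implement the depolarization requirements of
three-factor rules. They matter structurally: the presynaptic threshold is
what prevents the rarely-rewarded stimulus (lemons) from absorbing credit
at reward time (its WM trace has decayed to ~0.40 by then, versus ~0.72
for the recently-presented gold bar), and per-stimulus VS cells prevent it
from absorbing credit during the other stimulus's bursts. `tau_ws` is a
multiplicative rate constant (larger = faster learning), like `tau_x` in
the WM equation. `beta_z` plays the same role in the striosomal rule that
`beta_ws` plays in the VS rule; with the striosomal gain `gamma_s = 100` a
large `beta_z` (300) is needed for over-prediction dips to unwind the
timed inhibition at a comparable rate, which stabilises the conditioned
pathway over the session.

The striosomal ceiling is deliberately low (`z_max = 0.3`): the trained
timing cells saturate at their ceiling within roughly the first quarter of
the session, after which the timed inhibition is a fixed, capped quantity.
This is the mechanism behind the headline sensitivity result — once the
inhibition is saturated (and the deepest dips are floored at zero rate),
varying `h_d`, `gamma_s` or `alpha_z` across individuals barely moves the
simulated output, whereas the excitatory gains `w_pd`, `w_sp`, `w_max_s`
scale it directly.

## The task

A passive slot-machine paradigm: fixation (0.5 s), S1 (0.5 s), gap
(0.5 s), S2 (0.5 s), gap (0.5 s), outcome (1.0 s), inter-trial interval
(2.0 s). S1 predicts S2 with 80% validity; a gold bar at S2 is always
rewarded, lemons never. Default session: 196 PR, 196 PNR, 48 UR, 48 UNR
trials in a seeded uniform shuffle (488 trials; block structure is
configurable). Stimuli are square-wave drives in {0, 1}; reward is a
square wave of amplitude `r_amp = 1` during the outcome screen of rewarded
trials. Screen durations are defaults chosen to give the WM traces partial
decay across the gaps and are all configurable; the published task timings
are only available graphically, so these are this package's own choices.

## Outputs

Traces are collapsed to 20 ms bins (expected spikes per bin = mean rate in
the bin x bin width). The S2 output of a session is the mean over the
first 300 ms after S2 onset minus the mean over the 100 ms before S2,
computed on per-type condition averages (the operations are linear, so
per-trial normalization would give the same result), for UR minus UNR
trials. The S1 output applies the same windows at S1 onset to the
condition pairs (PR, UNR) minus (UR, PNR), with unweighted condition-level
means, mirroring how an ERP difference wave is formed.

## Sensitivity analysis

A cohort (default 50) of simulated individuals is built by replacing one
parameter with seeded draws from Normal(mean, sd) — redrawn while
non-positive, which preserves the nominal mean better than clipping — or
with a uniformly spaced grid. All other parameters are bit-identical
across individuals and the model is noise-free, so all output variance is
attributable to the varied parameter. Each cohort yields sample moments
(n-1 denominators), the parameter-output Pearson r, and a non-linearity
screen: flagged only when a single line explains < 95% of the output
variance *and* a two-segment fit cuts the residual sum of squares at least
four-fold (in a noise-free model a smooth monotone response is always
near-perfectly linear, so only genuine steps are flagged). Plausibility:
VSR requires |r| >= 0.90 with no disqualifying non-linearity; MV requires
an output SD of at least 0.03 spikes/bin (absolute mode) or half the
`w_pd` benchmark (relative mode). Both cut-offs are configurable; the
underlying psychometric argument gives no sharp threshold.

The expected trait-endophenotype correlation from the shared-cause
argument is `sqrt((rel_trait / m) * (rel_endo / p) * r_xy^2)` for `m`
equal independent causes of the trait, `p` of the endophenotype, and a
parameter-process correlation `r_xy` — 0.3 under the generous reference
assumptions (m=8, reliabilities 0.8/0.9, p=1, r_xy=1), 0.15 at r_xy=0.5.

## Calibration and operating point

The structural constants (baseline rate, DA gain, membrane and
habituation rates, learning gain scales, timing-array geometry, reward
amplitude) are not fixed by any published table available here; they were
calibrated once, with every mapped parameter at its population mean, and
then frozen as the defaults. The calibration targeted the qualitative
firing pattern of the four trial types, the strict S2 ordering
UR > PNR > PR > UNR, and the pathway asymmetry of the sensitivity
analysis. At the frozen defaults the baseline individual gives (spikes
per 20 ms bin, S2 window): UR +0.53, UNR -0.13, PR -0.037, PNR -0.034;
S2 difference (UR - UNR) 0.661; S1 difference 0.602.

Known limitations of this operating point:

* The unpredicted-reward S2 burst is larger than the reference value for
  this task family (~0.15), because keeping the conditioned weight pinned
  at its ceiling — which is what makes the learning-rate and
  inhibitory-pathway parameters insensitive, the headline asymmetry —
  leaves the fresh S2 burst mostly uncancelled. Consequently the S1
  difference wave, while of the same order, does not exceed the S2
  difference.
* For the same reason, once learning has saturated the S2 output no longer
  depends on the strength of the primary-reward input, so the wide-range
  `w_rp` sweep, although almost perfectly linear (r ≈ 0.99), produces
  little output variance and fails the MV criterion in this
  implementation.
* At the large-mean `tau_ws` replicate setting (mean 20) learning
  saturates within a few trials and the parameter-output slope is
  numerically degenerate; its correlation is reported but not meaningful.
* The model is noise-free by design; cohort statistics quantify parameter
  influence, not measurement noise, and say nothing about trial-to-trial
  variability in real recordings.

## Numerical choices

Explicit Euler at `dt = 1 ms`; halving `dt` changes the S2 difference
output by < 1%. The WM gate and all output thresholds are strict
inequalities; WM activations are clamped to [0, M_x] and plastic weights
to their ceilings after every step. Spectral-timing kernels are
pre-tabulated on the integration grid (activations below 1e-4 are treated
as zero, which also defines learning eligibility). The update order
within a step is WM → VS → striosomes → PPTN → DA → learning, with
learning using the same step's phasic DA signal. Integration state is
checked for finiteness after every trial; a non-finite value aborts with
the subsystem name and simulation time. The compiled (numba) inner loop
is mirrored by a pure-Python reference integrator composed of the public
single-step operations; the two agree to machine precision on fresh-state
trials and are cross-checked in the test suite.

## Problem sizes

The default session is 488 trials of 5.5 s at 1 ms resolution (~0.3 s of
wall time each after JIT compilation). The test suite runs one full
baseline session, several short sessions, and a 50-individual sweep of
the ten primary parameters plus the two grid rows; the acceptance script
runs the full 14-row sweep plan (~680 sessions).
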