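# dacircuit

A biologically mapped simulator of phasic midbrain dopamine firing in a
passive associative reward-learning task, plus a one-parameter-at-a-time
individual-differences sensitivity toolkit.

## Scientific problem

Phasic changes in midbrain dopamine (DA) cell firing behave like a reward
prediction error (RPE): unpredicted rewards produce bursts, omitted
predicted rewards produce dips. In EEG work, the feedback-related
negativity (FRN) — and in particular the FRN difference wave between
unpredicted-reward and unpredicted-non-reward trials of the passive
S1→S2→outcome "slot machine" task — is thought to be modulated by exactly
these DA firing changes, and correlates with extraversion across people.
Which psychobiological parameter could plausibly be the shared cause of
that trait–endophenotype covariance?

`dacircuit` addresses this in two steps:

1. **Circuit simulation.** A modified Brown–Bullock–Grossberg (BBG)
   opponent-pathway model: leaky working-memory traces
   `dx_i/dt = τ_x((M_x − x_i)I_i − A_x x_i)` drive both an excitatory
   route to the DA cells (cortex → ventral striatum → (pallidum) → PPTN →
   DA, plus the direct LH → PPTN reward input) and an inhibitory,
   spectrally timed striosomal route that learns *when* reward follows a
   stimulus. Both routes learn under a three-factor rule gated by the
   phasic DA signal itself (`N⁺` bursts, `N⁻` dips). The simulated
   endophenotype is the baseline-referenced S2-window firing difference,
   UR − UNR, in spikes per 20 ms bin.
2. **Differential sensitivity analysis.** Cohorts of simulated
   individuals are created by replacing one biologically mapped parameter
   (e.g. the PPTN→DA weight `w_PD`, the striosomal inhibition gain `h_D`)
   with a random normal variable, holding everything else fixed in a
   noise-free model. A parameter is a *plausible* source of
   trait–endophenotype covariance only if it correlates almost perfectly
   with the simulated output (**VSR** constraint) and creates substantial
   output variance (**MV** constraint).

The headline result this package reproduces: parameters on the excitatory
reward pathway (`w_PD`, `w_SP`, `w_max_S`) satisfy both constraints,
while inhibitory-pathway and learning-rate parameters (`h_D`, `γ_S`,
`α_Z`, `τ_WS`, `β_WS`) create at least five-fold less output variance and
fail MV — so variation in excitatory reward drive, not in timed
inhibition, is the plausible candidate.

## Worked example

```python
from dacircuit import (ModelParameters, TimingConfig, build_schedule,
                       run_session)
from dacircuit.analysis import endophenotype_output

params = ModelParameters()                    # the baseline individual
schedule = build_schedule(seed=1)             # 196/196/48/48 shuffled trials
session = run_session(params, schedule, TimingConfig())
out = endophenotype_output(session)
for trial_type, value in out.s2_by_type.items():
    print(f"S2 {trial_type.value:>4}: {value:+.4f} spikes/bin")
print(f"S2 diff (UR-UNR): {out.s2_diff:+.4f}   S1 diff: {out.s1_diff:+.4f}")
```

prints

```
S2   PR: -0.0375 spikes/bin
S2  PNR: -0.0342 spikes/bin
S2   UR: +0.5272 spikes/bin
S2  UNR: -0.1337 spikes/bin
S2 diff (UR-UNR): +0.6609   S1 diff: +0.6015
```

The unpredicted reward (UR) elicits the largest S2 burst, the unpredicted
non-reward (UNR) the deepest suppression, with the predicted conditions in
between (UR > PNR > PR > UNR) — the ordering of the FRN waves recorded
with this task. The S2 difference is the simulated endophenotype used in
all sensitivity sweeps.

From the shell, the same run plus a parameter sweep:

```bash
dacircuit simulate --out results/
dacircuit sweep w_pd --n 50 --seed 1 --out results/
dacircuit report-all --n 50 --seed 1 --out results/
```

`sweep w_pd` prints a line such as

```
w_PD: output mean 0.6529, SD 0.1186, r 1.000, verdict plausible
```

meaning: across 50 simulated individuals whose PPTN→DA weight was drawn
from Normal(5, 1), the endophenotype output averaged 0.65 spikes/bin with
SD 0.12, correlating r ≈ 1 with the parameter — `w_PD` passes both the
VSR and MV constraints. Running `sweep h_d` instead yields an output SD
more than five-fold smaller (verdict implausible): the inhibitory gain
cannot account for individual differences in the FRN difference wave.

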