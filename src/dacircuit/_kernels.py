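"""Numba-compiled inner loop of the circuit integrator.

The kernel advances every dynamical variable of one simulated individual
through one trial with explicit Euler steps.  Parameters arrive as a flat
float64 vector (see :data:`PARAM_ORDER`); the spectral-timing kernels arrive
pre-tabulated on the integration grid so the hot loop performs no
transcendental calls.

The math here is duplicated, op by op, in the pure-Python reference functions
of :mod:`dacircuit.circuit`; a test cross-checks the two routes on short
trials.
"""

from __future__ import annotations

import numba as nb
import numpy as np

#: Index layout of the parameter vector consumed by :func:`integrate_trial`.
PARAM_ORDER: tuple[str, ...] = (
    "m_x",
    "tau_x",
    "a_x",
    "theta_x",
    "gamma_g",
    "theta_s",
    "w_pd",
    "w_sp",
    "w_rp",
    "w_rs",
    "w_max_s",
    "tau_ws",
    "beta_ws",
    "h_d",
    "gamma_s",
    "alpha_z",
    "baseline_rate",
    "da_gain",
    "lambda_s",
    "lambda_p",
    "lambda_d",
    "tau_rec",
    "tau_dep",
    "k_learn",
    "k_z",
    "z_max",
    "theta_pre",
    "beta_z",
)
PARAM_INDEX: dict[str, int] = {name: i for i, name in enumerate(PARAM_ORDER)}

#: Striosomal kernel activations below this are treated as ineligible.
F_EPS = 1e-4

#: Error codes returned by the kernel when a state variable goes non-finite.
ERROR_SUBSYSTEM = {
    1: "working memory",
    2: "ventral striatum",
    3: "striosomal weights",
    4: "PPTN",
    5: "DA cell",
    6: "VS plastic weights",
}


@nb.njit(cache=True)
def integrate_trial(x, active, elapsed, w_s, z, scal,
                    i_gold, i_lemon, rew, F, prm, dt, rates):
    """Advance the full circuit state through one trial.

    Mutates ``x`` (WM activations), ``active``/``elapsed`` (spectral-timing
    clocks), ``w_s`` (VS plastic weights), ``z`` (striosomal weights) and
    ``scal`` = [S, h, p, D] in place; writes the instantaneous DA firing rate
    (spikes/s) into ``rates``.  Returns 0 on success or a subsystem error code
    (see :data:`ERROR_SUBSYSTEM`) if a variable became non-finite.
    """
    m_x = prm[0]; tau_x = prm[1]; a_x = prm[2]; theta_x = prm[3]
    gamma_g = prm[4]; theta_s = prm[5]
    w_pd = prm[6]; w_sp = prm[7]; w_rp = prm[8]; w_rs = prm[9]
    w_max_s = prm[10]; tau_ws = prm[11]; beta_ws = prm[12]
    h_d = prm[13]; gamma_s = prm[14]; alpha_z = prm[15]
    r0 = prm[16]; g_d = prm[17]
    lam_s = prm[18]; lam_p = prm[19]; lam_d = prm[20]
    tau_rec = prm[21]; tau_dep = prm[22]
    k_learn = prm[23]; k_z = prm[24]; z_max = prm[25]
    theta_pre = prm[26]; beta_z = prm[27]

    J = F.shape[0]
    K = F.shape[1]
    S0 = scal[0]; S1 = scal[1]; h = scal[2]; p = scal[3]; D = scal[4]
    n = i_gold.shape[0]

    for t in range(n):
        # --- working memory (leaky charge toward ceiling while stimulus on)
        x[0] += dt * tau_x * ((m_x - x[0]) * i_gold[t] - a_x * x[0])
        x[1] += dt * tau_x * ((m_x - x[1]) * i_lemon[t] - a_x * x[1])
        for i in range(2):
            if x[i] < 0.0:
                x[i] = 0.0
            elif x[i] > m_x:
                x[i] = m_x
            if x[i] > theta_x:
                if active[i]:
                    elapsed[i] += 1
                else:           # gate crossing re-arms the timing clock
                    active[i] = True
                    elapsed[i] = 0
            else:
                active[i] = False

        # --- ventral striatum: one medium-spiny cell per stimulus node,
        # each driven by the primary reward input plus its conditioned input
        S0 += dt * lam_s * (w_rs * rew[t] + w_s[0] * x[0] - S0)
        S1 += dt * lam_s * (w_rs * rew[t] + w_s[1] * x[1] - S1)
        s_out = 0.0
        if S0 > gamma_g:
            s_out += S0 - gamma_g
        if S1 > gamma_g:
            s_out += S1 - gamma_g

        # --- striosomal timed reward prediction
        G = 0.0
        for i in range(2):
            if active[i] and elapsed[i] < K:
                e = elapsed[i]
                for j in range(J):
                    G += z[i, j] * F[j, e]

        # --- PPTN relay (phasic onset response with habituation)
        U = w_rp * rew[t] + w_sp * s_out
        occ = 1.0 if U > 1e-6 else 0.0
        h += dt * ((1.0 - h) / tau_rec - occ * h / tau_dep)
        if h < 0.0:
            h = 0.0
        elif h > 1.0:
            h = 1.0
        p += dt * lam_p * (U * h - p)

        # --- DA cell: opponent excitation vs timed inhibition, floored rate
        D += dt * lam_d * (w_pd * p - h_d * G - D)
        rate = r0 + g_d * D
        if rate < 0.0:
            rate = 0.0
        rates[t] = rate
        n_plus = rate - r0
        n_minus = -n_plus
        if n_plus < 0.0:
            n_plus = 0.0
        if n_minus < 0.0:
            n_minus = 0.0

        # --- three-factor learning (only when a phasic DA event is present)
        if n_plus > 0.0 or n_minus > 0.0:
            for i in range(2):
                post = (S0 if i == 0 else S1) - theta_s
                if post <= 0.0:
                    continue
                pre = x[i] - theta_pre
                if pre <= 0.0:
                    continue
                dw = (k_learn * tau_ws) * pre * post * (
                    n_plus * (w_max_s - w_s[i])
                    - beta_ws * n_minus * w_s[i]
                ) * dt
                w_s[i] += dw
                if w_s[i] < 0.0:
                    w_s[i] = 0.0
                elif w_s[i] > w_max_s:
                    w_s[i] = w_max_s
            for i in range(2):
                if active[i] and elapsed[i] < K:
                    e = elapsed[i]
                    for j in range(J):
                        f = F[j, e]
                        if f > F_EPS:
                            dz = alpha_z * k_z * f * (
                                gamma_s * n_plus * (z_max - z[i, j])
                                - beta_z * n_minus * z[i, j]
                            ) * dt
                            z[i, j] += dz
                            if z[i, j] < 0.0:
                                z[i, j] = 0.0
                            elif z[i, j] > z_max:
                                z[i, j] = z_max

    scal[0] = S0; scal[1] = S1; scal[2] = h; scal[3] = p; scal[4] = D

    if not (np.isfinite(x[0]) and np.isfinite(x[1])):
        return 1
    if not (np.isfinite(S0) and np.isfinite(S1)):
        return 2
    for i in range(2):
        for j in range(J):
            if not np.isfinite(z[i, j]):
                return 3
    if not (np.isfinite(h) and np.isfinite(p)):
        return 4
    if not np.isfinite(D):
        return 5
    if not (np.isfinite(w_s[0]) and np.isfinite(w_s[1])):
        return 6
    return 0
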