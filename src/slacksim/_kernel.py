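"""Compiled inner loop of the compartmental integrator.

The whole time loop — exponential gate updates, Na⁺ pool update and the
Crank–Nicolson voltage solve (small dense Gaussian elimination per sweep)
— lives in one numba-jitted kernel so that protocol families integrate in
seconds.  The math is identical to the reference numpy implementation in
``simulate``; falls back to a numpy-object-mode-free pure-Python version
when numba is unavailable (slow but correct).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=False, fastmath=False)
def integrate(
    mode_vc, clamp_space, soma, dt, n_steps,
    A, c_nF, area,
    ch_comp, ch_gd, ch_erev, ch_carries_na, ch_is_kcnt1,
    ch_gate_ptr, ch_gate_idx,
    g_comp, g_is_hill, g_v50, g_slope, g_ec50, g_hill,
    g_tau0, g_tau_amp, g_tau_vpeak, g_tau_sigma, g_power,
    na_clamped, na_clamp_val, na_rest, tau_na, depth_um,
    cmd, V, Na, G,
    out_v, out_na, out_i, out_ik, out_ina, log_ch,
):
    S, n = V.shape
    ng = g_comp.shape[0]
    nch = ch_comp.shape[0]
    FARADAY = 96485.332
    na_decay = np.exp(-dt / tau_na)

    tgt = np.empty(ng)
    gch = np.empty(nch)
    M = np.empty((n, n))
    b = np.empty(n)
    i_na = np.empty(n)
    Gm = np.empty(n)
    GmE = np.empty(n)

    bad_sweep = -1
    bad_step = -1

    for s in range(S):
        # log initial state
        out_v[s, 0] = V[s, soma]
        out_na[s, 0] = Na[s, soma]
        out_i[s, 0] = 0.0

    for ti in range(n_steps):
        for s in range(S):
            # ---- gate update (exact exponential relaxation)
            for gi in range(ng):
                ci = g_comp[gi]
                if g_is_hill[gi]:
                    na = Na[s, ci]
                    if na < 0.0:
                        na = 0.0
                    r = (na / g_ec50[gi]) ** g_hill[gi]
                    target = r / (r + 1.0)
                else:
                    target = 1.0 / (1.0 + np.exp(-(V[s, ci] - g_v50[gi]) / g_slope[gi]))
                tau = g_tau0[gi]
                if g_tau_amp[gi] > 0.0:
                    x = (V[s, ci] - g_tau_vpeak[gi]) / g_tau_sigma[gi]
                    tau += g_tau_amp[gi] * np.exp(-x * x)
                if tau <= 0.0:
                    tgt[gi] = target
                else:
                    tgt[gi] = G[s, gi] + (target - G[s, gi]) * (
                        1.0 - np.exp(-dt / tau))
            for gi in range(ng):
                G[s, gi] = tgt[gi]

            # ---- channel conductances (density S/cm²) and Na+ current
            for ci in range(n):
                i_na[ci] = 0.0
                Gm[ci] = 0.0
                GmE[ci] = 0.0
            for k in range(nch):
                g = ch_gd[k]
                for jj in range(ch_gate_ptr[k], ch_gate_ptr[k + 1]):
                    gi = ch_gate_idx[jj]
                    p = g_power[gi]
                    gv = G[s, gi]
                    if p == 1:
                        g *= gv
                    elif p == 2:
                        g *= gv * gv
                    elif p == 3:
                        g *= gv * gv * gv
                    else:
                        g *= gv ** p
                gch[k] = g
                ci = ch_comp[k]
                if ch_carries_na[k]:
                    i_na[ci] += g * (V[s, ci] - ch_erev[k])  # mA/cm²
                g_uS = g * area[ci] * 1.0e6
                Gm[ci] += g_uS
                GmE[ci] += g_uS * ch_erev[k]

            # ---- Na pool (exact exponential update)
            if na_clamped:
                for ci in range(n):
                    Na[s, ci] = na_clamp_val
            else:
                for ci in range(n):
                    influx = -i_na[ci] * 1.0e4 / (FARADAY * depth_um)
                    na_inf = na_rest + influx * tau_na
                    val = na_inf + (Na[s, ci] - na_inf) * na_decay
                    Na[s, ci] = val if val > 0.0 else 0.0

            # ---- voltage update
            c_now = cmd[s, ti]
            c_next = cmd[s, ti + 1]
            if mode_vc and clamp_space:
                i_ion = 0.0
                c_sum = 0.0
                for ci in range(n):
                    V[s, ci] = c_next
                    i_ion += Gm[ci] * c_next - GmE[ci]
                    c_sum += c_nF[ci]
                i_clamp = i_ion + c_sum * (c_next - c_now) / dt
            else:
                for ci in range(n):
                    av = 0.0
                    for cj in range(n):
                        M[ci, cj] = -0.5 * A[ci, cj]
                        av += A[ci, cj] * V[s, cj]
                    M[ci, ci] += c_nF[ci] / dt + 0.5 * Gm[ci]
                    b[ci] = (c_nF[ci] / dt * V[s, ci]
                             + 0.5 * (-(Gm[ci] * V[s, ci]) + av) + GmE[ci])
                if mode_vc:
                    for cj in range(n):
                        M[soma, cj] = 0.0
                    M[soma, soma] = 1.0
                    b[soma] = c_next
                else:
                    b[soma] += c_now * 0.0 + c_next * 1.0e-3  # pA → nA injection

                # Gaussian elimination (no pivoting; diagonally dominant)
                for piv in range(n - 1):
                    for row in range(piv + 1, n):
                        if M[row, piv] != 0.0:
                            f = M[row, piv] / M[piv, piv]
                            for col in range(piv, n):
                                M[row, col] -= f * M[piv, col]
                            b[row] -= f * b[piv]
                for row in range(n - 1, -1, -1):
                    acc = b[row]
                    for col in range(row + 1, n):
                        acc -= M[row, col] * V[s, col]
                    V[s, row] = acc / M[row, row]

                if mode_vc:
                    axial_in = 0.0
                    for cj in range(n):
                        axial_in += A[soma, cj] * V[s, cj]
                    i_clamp = (c_nF[soma] * (c_next - c_now) / dt
                               + Gm[soma] * c_next - GmE[soma] - axial_in)
                else:
                    i_clamp = 0.0

            # ---- logging
            out_v[s, ti + 1] = V[s, soma]
            out_na[s, ti + 1] = Na[s, soma]
            out_i[s, ti + 1] = i_clamp * 1.0e3  # nA → pA
            if log_ch:
                ik = 0.0
                ina = 0.0
                for k in range(nch):
                    ci = ch_comp[k]
                    i_pA = gch[k] * (V[s, ci] - ch_erev[k]) * area[ci] * 1.0e9
                    if ch_is_kcnt1[k]:
                        ik += i_pA
                    if ch_carries_na[k]:
                        ina += i_pA
                out_ik[s, ti + 1] = ik
                out_ina[s, ti + 1] = ina

            vmax = 0.0
            for ci in range(n):
                av = abs(V[s, ci])
                if av > vmax:
                    vmax = av
            if vmax > 200.0 or np.isnan(vmax):
                bad_sweep = s
                bad_step = ti + 1
                return bad_sweep, bad_step

    return bad_sweep, bad_step
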