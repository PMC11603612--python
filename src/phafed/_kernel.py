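"""Numba inner loop for the λ-dynamics engine.

Everything here operates on flat float64/int64 arrays prepared by
:mod:`phafed.engine`; the readable reference implementation of the potential
lives in :mod:`phafed.model` and the two are cross-checked in the tests.

Layout conventions
------------------
λ block (``n_l``): site λ coordinates in site order (a multisite His
contributes three), followed by buffer λ coordinates.  Environment block
(``n_e``): one harmonic coordinate per site.  Gate block (``n_g``): one
double-well conformational coordinate per gated site, optionally driven by
a d-AFED extended variable ``s``.

Thermostat modes: 0 = massive Nosé–Hoover chains (one independent chain per
coordinate, velocity-Verlet "side" scheme), 1 = single stochastic
velocity-rescaling thermostat over the pooled kinetic energy, 2 = none (NVE).
"""

import math

import numpy as np
from numba import njit

MODE_NHC = 0
MODE_CSVR = 1
MODE_NVE = 2

# gate model constants (mirrors phafed.model)
GATE_CLOSED_BIAS = 25.0
GATE_SWITCH_CENTER = 0.7
GATE_SWITCH_WIDTH = 0.05

KB = 0.0083144621


@njit(cache=True)
def _forces(lam, x, g, s,
            c_ph, h_bar, env_idx, gate_idx, offset_l,
            kA, kB_c, xA, xB, gate_h,
            rest_idx, rest_amp, rest_flat, rest_sw,
            dafed_on, k_s,
            f_lam, f_x, f_g, f_s, terms):
    """Fill force arrays and the 7-component energy-term vector.

    terms = [total, ph, barrier, env, restraint, gate, coupling].
    """
    n_l = lam.shape[0]
    n_e = x.shape[0]
    n_g = g.shape[0]
    for i in range(n_l):
        f_lam[i] = 0.0
    for k in range(n_e):
        f_x[k] = 0.0
    for k in range(n_g):
        f_g[k] = 0.0
        f_s[k] = 0.0
    e_ph = 0.0
    e_bar = 0.0
    e_env = 0.0
    e_res = 0.0
    e_gate = 0.0
    e_cpl = 0.0

    # gate potentials and switches
    sw = np.empty(n_g)
    dsw = np.empty(n_g)
    for k in range(n_g):
        gk = g[k]
        e = math.exp((gk - GATE_SWITCH_CENTER) / GATE_SWITCH_WIDTH)
        s_k = 1.0 / (1.0 + e)
        sw[k] = s_k
        dsw[k] = -s_k * (1.0 - s_k) / GATE_SWITCH_WIDTH
        e_gate += 16.0 * gate_h[k] * gk * gk * (1.0 - gk) * (1.0 - gk) \
            + GATE_CLOSED_BIAS * s_k
        dgate = 16.0 * gate_h[k] * (2.0 * gk * (1.0 - gk) * (1.0 - gk)
                                    - 2.0 * gk * gk * (1.0 - gk))
        f_g[k] = -(dgate + GATE_CLOSED_BIAS * dsw[k])
        if dafed_on[k] != 0:
            # harmonic tether to the extended variable
            e_cpl += 0.5 * k_s[k] * (g[k] - s[k]) * (g[k] - s[k])
            f_g[k] += -k_s[k] * (g[k] - s[k])
            f_s[k] = -k_s[k] * (s[k] - g[k])

    # environment interpolation weights w_k = sum of λs bound to env k
    w = np.zeros(n_e)
    for i in range(n_l):
        k = env_idx[i]
        if k >= 0:
            w[k] += lam[i]
    va = np.empty(n_e)
    vb = np.empty(n_e)
    for k in range(n_e):
        dxa = x[k] - xA[k]
        dxb = x[k] - xB[k]
        va[k] = 0.5 * kA[k] * dxa * dxa
        vb[k] = 0.5 * kB_c[k] * dxb * dxb
        e_env += (1.0 - w[k]) * va[k] + w[k] * vb[k]
        f_x[k] = -((1.0 - w[k]) * kA[k] * dxa + w[k] * kB_c[k] * dxb)

    for i in range(n_l):
        li = lam[i]
        # pH term (linear) and barrier
        e_ph += c_ph[i] * li
        one = 1.0 - li
        e_bar += 16.0 * h_bar[i] * li * li * one * one
        dbar = 16.0 * h_bar[i] * (2.0 * li * one * one - 2.0 * li * li * one)
        f = -(c_ph[i] + dbar)
        k = env_idx[i]
        if k >= 0:
            off = offset_l[i]
            gk = gate_idx[i]
            if gk >= 0:
                off_eff = off * sw[gk]
                f_g[gk] += -li * off * dsw[gk]
            else:
                off_eff = off
            e_cpl += li * off_eff
            f += -(vb[k] - va[k] + off_eff)
        f_lam[i] += f

    # tanh restraints on tautomer triples
    n_r = rest_idx.shape[0]
    for r in range(n_r):
        ssum = 0.0
        for j in range(3):
            ssum += lam[rest_idx[r, j]]
        delta = ssum - 1.0
        ad = abs(delta)
        z = (ad - rest_flat[r]) / rest_sw[r]
        t = math.tanh(z)
        e_res += rest_amp[r] * 0.5 * (1.0 + t)
        if delta != 0.0:
            sech2 = 1.0 - t * t
            dres = rest_amp[r] * 0.5 * sech2 / rest_sw[r]
            if delta < 0.0:
                dres = -dres
            for j in range(3):
                f_lam[rest_idx[r, j]] += -dres

    terms[1] = e_ph
    terms[2] = e_bar
    terms[3] = e_env
    terms[4] = e_res
    terms[5] = e_gate
    terms[6] = e_cpl
    terms[0] = e_ph + e_bar + e_env + e_res + e_gate + e_cpl


@njit(cache=True)
def _nhc_scale(v, m, kT, peta, eta, Q, dt_half, sy_w, n_mts):
    """Massive-NHC velocity scale for one coordinate over dt/2.

    Standard Suzuki–Yoshida-factorized chain update; returns the scaled
    velocity and mutates the chain state in place.
    """
    M = peta.shape[0]
    akin = m * v * v
    scale = 1.0
    G = np.empty(M)
    G[0] = akin - kT
    for j in range(1, M):
        G[j] = peta[j - 1] * peta[j - 1] / Q[j - 1] - kT
    for _ in range(n_mts):
        for iw in range(sy_w.shape[0]):
            wdt = sy_w[iw] * dt_half / n_mts
            peta[M - 1] += 0.5 * wdt * G[M - 1]
            for j in range(M - 2, -1, -1):
                aa = math.exp(-0.25 * wdt * peta[j + 1] / Q[j + 1])
                peta[j] = peta[j] * aa * aa + 0.5 * wdt * G[j] * aa
            ss = math.exp(-wdt * peta[0] / Q[0])
            scale *= ss
            akin *= ss * ss
            G[0] = akin - kT
            for j in range(M):
                eta[j] += wdt * peta[j] / Q[j]
            for j in range(M - 1):
                aa = math.exp(-0.25 * wdt * peta[j + 1] / Q[j + 1])
                peta[j] = peta[j] * aa * aa + 0.5 * wdt * G[j] * aa
                G[j + 1] = peta[j] * peta[j] / Q[j] - kT
            peta[M - 1] += 0.5 * wdt * G[M - 1]
    return v * scale


@njit(cache=True)
def _csvr_scale(kin2, n_dof, kT, dt, tau):
    """Stochastic velocity-rescaling factor (canonical sampling thermostat).

    kin2 = 2 × total kinetic energy.  Exact Bussi propagation of the pooled
    kinetic energy; draws n_dof Gaussians from the global numba RNG stream.
    """
    if kin2 <= 0.0:
        return 1.0
    c = math.exp(-dt / tau)
    r1 = np.random.normal()
    ssum = 0.0
    for _ in range(n_dof - 1):
        rr = np.random.normal()
        ssum += rr * rr
    factor = (1.0 - c) * kT / kin2
    a2 = c + factor * (r1 * r1 + ssum) + 2.0 * r1 * math.sqrt(c * factor)
    if a2 < 0.0:
        a2 = 0.0
    return math.sqrt(a2)


@njit(cache=True)
def _shake(lam, alpha, inv_m, target):
    """Exact position projection onto the linear charge-constraint plane."""
    num = -target
    den = 0.0
    for i in range(lam.shape[0]):
        num += alpha[i] * lam[i]
        den += alpha[i] * alpha[i] * inv_m[i]
    zeta = num / den
    for i in range(lam.shape[0]):
        lam[i] -= zeta * alpha[i] * inv_m[i]


@njit(cache=True)
def _rattle(vlam, alpha, inv_m):
    """Remove the constraint-violating component of the λ velocities."""
    num = 0.0
    den = 0.0
    for i in range(vlam.shape[0]):
        num += alpha[i] * vlam[i]
        den += alpha[i] * alpha[i] * inv_m[i]
    zeta = num / den
    for i in range(vlam.shape[0]):
        vlam[i] -= zeta * alpha[i] * inv_m[i]


@njit(cache=True)
def run_kernel(n_steps, dt, stride, seed, mode, init_vel, n_site_lam,
               lam, vlam, m_l, T_l, c_ph, h_bar, env_idx, gate_idx, offset_l,
               x, vx, m_e, T_e, kA, kB_c, xA, xB,
               g, vg, m_g, T_g, gate_h,
               rest_idx, rest_amp, rest_flat, rest_sw,
               alpha, c_target, use_constraint,
               nhc_tau, sy_w, n_mts,
               eta_l, peta_l, eta_e, peta_e, eta_g, peta_g,
               csvr_tau,
               dafed_on, s, vs, k_s, m_s, T_s, gamma_s):
    """Propagate the full system and return sampled trajectory arrays.

    Returns (lam_traj, env_traj, gate_traj, s_traj, temps, energies,
    max_residual).  temps columns: site-λ group, buffer group, env, gate, s.
    energies columns: [pot_total, ph, barrier, env, restraint, gate,
    coupling, kin_lambda, kin_env, conserved].
    """
    np.random.seed(seed)
    n_l = lam.shape[0]
    n_e = x.shape[0]
    n_g = g.shape[0]
    n_buf = n_l - n_site_lam
    M = peta_l.shape[1]

    # chain masses Q_j = k_B T τ²
    Q_l = np.empty((n_l, M))
    for i in range(n_l):
        for j in range(M):
            Q_l[i, j] = KB * T_l[i] * nhc_tau * nhc_tau
    Q_e = np.empty((n_e, M))
    for k in range(n_e):
        for j in range(M):
            Q_e[k, j] = KB * T_e[k] * nhc_tau * nhc_tau
    Q_g = np.empty((n_g, M))
    for k in range(n_g):
        for j in range(M):
            Q_g[k, j] = KB * T_g[k] * nhc_tau * nhc_tau

    if init_vel != 0:
        for i in range(n_l):
            vlam[i] = math.sqrt(KB * T_l[i] / m_l[i]) * np.random.normal()
        for k in range(n_e):
            vx[k] = math.sqrt(KB * T_e[k] / m_e[k]) * np.random.normal()
        for k in range(n_g):
            vg[k] = math.sqrt(KB * T_g[k] / m_g[k]) * np.random.normal()
            if dafed_on[k] != 0:
                vs[k] = math.sqrt(KB * T_s[k] / m_s[k]) * np.random.normal()
        if use_constraint != 0:
            inv_m0 = np.empty(n_l)
            for i in range(n_l):
                inv_m0[i] = 1.0 / m_l[i]
            _rattle(vlam, alpha, inv_m0)

    inv_m = np.empty(n_l)
    for i in range(n_l):
        inv_m[i] = 1.0 / m_l[i]

    f_lam = np.zeros(n_l)
    f_x = np.zeros(n_e)
    f_g = np.zeros(n_g)
    f_s = np.zeros(n_g)
    terms = np.zeros(7)
    _forces(lam, x, g, s, c_ph, h_bar, env_idx, gate_idx, offset_l,
            kA, kB_c, xA, xB, gate_h, rest_idx, rest_amp, rest_flat, rest_sw,
            dafed_on, k_s, f_lam, f_x, f_g, f_s, terms)

    n_frames = n_steps // stride
    lam_traj = np.empty((n_frames, n_l))
    env_traj = np.empty((n_frames, n_e))
    gate_traj = np.empty((n_frames, n_g))
    s_traj = np.empty((n_frames, n_g))
    temps = np.zeros((n_frames, 5))
    energies = np.empty((n_frames, 10))
    max_res = 0.0
    dt_half = 0.5 * dt
    frame = 0

    # Ornstein-Uhlenbeck coefficients for the d-AFED Langevin pieces
    ou_c1 = np.empty(n_g)
    ou_c2 = np.empty(n_g)
    for k in range(n_g):
        if dafed_on[k] != 0 and gamma_s[k] > 0.0:
            ou_c1[k] = math.exp(-gamma_s[k] * dt)
            ou_c2[k] = math.sqrt(KB * T_s[k] / m_s[k] * (1.0 - ou_c1[k] * ou_c1[k]))
        else:
            ou_c1[k] = 1.0
            ou_c2[k] = 0.0

    for step in range(n_steps):
        # --- thermostat half-step ("side" scheme) ---
        if mode == MODE_NHC:
            for i in range(n_l):
                vlam[i] = _nhc_scale(vlam[i], m_l[i], KB * T_l[i],
                                     peta_l[i], eta_l[i], Q_l[i],
                                     dt_half, sy_w, n_mts)
            for k in range(n_e):
                vx[k] = _nhc_scale(vx[k], m_e[k], KB * T_e[k],
                                   peta_e[k], eta_e[k], Q_e[k],
                                   dt_half, sy_w, n_mts)
            for k in range(n_g):
                vg[k] = _nhc_scale(vg[k], m_g[k], KB * T_g[k],
                                   peta_g[k], eta_g[k], Q_g[k],
                                   dt_half, sy_w, n_mts)
            if use_constraint != 0:
                _rattle(vlam, alpha, inv_m)
        elif mode == MODE_CSVR:
            kin2 = 0.0
            for i in range(n_l):
                kin2 += m_l[i] * vlam[i] * vlam[i]
            for k in range(n_e):
                kin2 += m_e[k] * vx[k] * vx[k]
            for k in range(n_g):
                kin2 += m_g[k] * vg[k] * vg[k]
            sc = _csvr_scale(kin2, n_l + n_e + n_g, KB * T_e[0] if n_e > 0 else KB * T_l[0],
                             dt_half, csvr_tau)
            for i in range(n_l):
                vlam[i] *= sc
            for k in range(n_e):
                vx[k] *= sc
            for k in range(n_g):
                vg[k] *= sc
            if use_constraint != 0:
                _rattle(vlam, alpha, inv_m)

        # --- velocity-Verlet: half-kick, drift ---
        for i in range(n_l):
            vlam[i] += dt_half * f_lam[i] * inv_m[i]
        for k in range(n_e):
            vx[k] += dt_half * f_x[k] / m_e[k]
        for k in range(n_g):
            vg[k] += dt_half * f_g[k] / m_g[k]
        for i in range(n_l):
            lam[i] += dt * vlam[i]
        for k in range(n_e):
            x[k] += dt * vx[k]
        for k in range(n_g):
            g[k] += dt * vg[k]
        if use_constraint != 0:
            _shake(lam, alpha, inv_m, c_target)

        # --- d-AFED extended variables: BAOAB around the drift ---
        for k in range(n_g):
            if dafed_on[k] != 0:
                vs[k] += dt_half * f_s[k] / m_s[k]
                s[k] += dt_half * vs[k]
                vs[k] = ou_c1[k] * vs[k] + ou_c2[k] * np.random.normal()
                s[k] += dt_half * vs[k]

        # --- new forces, second half-kick ---
        _forces(lam, x, g, s, c_ph, h_bar, env_idx, gate_idx, offset_l,
                kA, kB_c, xA, xB, gate_h, rest_idx, rest_amp, rest_flat,
                rest_sw, dafed_on, k_s, f_lam, f_x, f_g, f_s, terms)
        for i in range(n_l):
            vlam[i] += dt_half * f_lam[i] * inv_m[i]
        for k in range(n_e):
            vx[k] += dt_half * f_x[k] / m_e[k]
        for k in range(n_g):
            vg[k] += dt_half * f_g[k] / m_g[k]
        for k in range(n_g):
            if dafed_on[k] != 0:
                vs[k] += dt_half * f_s[k] / m_s[k]
        if use_constraint != 0:
            _rattle(vlam, alpha, inv_m)

        # --- thermostat half-step ---
        if mode == MODE_NHC:
            for i in range(n_l):
                vlam[i] = _nhc_scale(vlam[i], m_l[i], KB * T_l[i],
                                     peta_l[i], eta_l[i], Q_l[i],
                                     dt_half, sy_w, n_mts)
            for k in range(n_e):
                vx[k] = _nhc_scale(vx[k], m_e[k], KB * T_e[k],
                                   peta_e[k], eta_e[k], Q_e[k],
                                   dt_half, sy_w, n_mts)
            for k in range(n_g):
                vg[k] = _nhc_scale(vg[k], m_g[k], KB * T_g[k],
                                   peta_g[k], eta_g[k], Q_g[k],
                                   dt_half, sy_w, n_mts)
            if use_constraint != 0:
                _rattle(vlam, alpha, inv_m)
        elif mode == MODE_CSVR:
            kin2 = 0.0
            for i in range(n_l):
                kin2 += m_l[i] * vlam[i] * vlam[i]
            for k in range(n_e):
                kin2 += m_e[k] * vx[k] * vx[k]
            for k in range(n_g):
                kin2 += m_g[k] * vg[k] * vg[k]
            sc = _csvr_scale(kin2, n_l + n_e + n_g, KB * T_e[0] if n_e > 0 else KB * T_l[0],
                             dt_half, csvr_tau)
            for i in range(n_l):
                vlam[i] *= sc
            for k in range(n_e):
                vx[k] *= sc
            for k in range(n_g):
                vg[k] *= sc
            if use_constraint != 0:
                _rattle(vlam, alpha, inv_m)

        if use_constraint != 0:
            res = -c_target
            for i in range(n_l):
                res += alpha[i] * lam[i]
            if abs(res) > max_res:
                max_res = abs(res)

        if not (math.isfinite(terms[0])):
            # abort: leave remaining frames as NaN markers
            for fr in range(frame, n_frames):
                for i in range(n_l):
                    lam_traj[fr, i] = np.nan
                energies[fr, 0] = np.nan
            return (lam_traj, env_traj, gate_traj, s_traj, temps, energies,
                    np.nan)

        # --- sampling ---
        if (step + 1) % stride == 0:
            kin_l = 0.0
            t_site = 0.0
            t_buf = 0.0
            for i in range(n_l):
                ke2 = m_l[i] * vlam[i] * vlam[i]
                kin_l += 0.5 * ke2
                if i < n_site_lam:
                    t_site += ke2 / KB
                else:
                    t_buf += ke2 / KB
            kin_e = 0.0
            t_env = 0.0
            for k in range(n_e):
                ke2 = m_e[k] * vx[k] * vx[k]
                kin_e += 0.5 * ke2
                t_env += ke2 / KB
            t_gate = 0.0
            t_s = 0.0
            for k in range(n_g):
                ke2 = m_g[k] * vg[k] * vg[k]
                kin_e += 0.5 * ke2
                t_gate += ke2 / KB
                if dafed_on[k] != 0:
                    t_s += m_s[k] * vs[k] * vs[k] / KB
            for i in range(n_l):
                lam_traj[frame, i] = lam[i]
            for k in range(n_e):
                env_traj[frame, k] = x[k]
            for k in range(n_g):
                gate_traj[frame, k] = g[k]
                s_traj[frame, k] = s[k]
            temps[frame, 0] = t_site / n_site_lam if n_site_lam > 0 else 0.0
            temps[frame, 1] = t_buf / n_buf if n_buf > 0 else 0.0
            temps[frame, 2] = t_env / n_e if n_e > 0 else 0.0
            temps[frame, 3] = t_gate / n_g if n_g > 0 else 0.0
            temps[frame, 4] = t_s / n_g if n_g > 0 else 0.0
            energies[frame, 0] = terms[0]
            for j in range(6):
                energies[frame, 1 + j] = terms[1 + j]
            energies[frame, 7] = kin_l
            energies[frame, 8] = kin_e
            # extended-system conserved quantity (NHC modes only)
            cons = terms[0] + kin_l + kin_e
            if mode == MODE_NHC:
                for i in range(n_l):
                    for j in range(M):
                        cons += 0.5 * peta_l[i, j] * peta_l[i, j] / Q_l[i, j]
                        cons += KB * T_l[i] * eta_l[i, j]
                for k in range(n_e):
                    for j in range(M):
                        cons += 0.5 * peta_e[k, j] * peta_e[k, j] / Q_e[k, j]
                        cons += KB * T_e[k] * eta_e[k, j]
                for k in range(n_g):
                    for j in range(M):
                        cons += 0.5 * peta_g[k, j] * peta_g[k, j] / Q_g[k, j]
                        cons += KB * T_g[k] * eta_g[k, j]
            energies[frame, 9] = cons
            frame += 1

    return lam_traj, env_traj, gate_traj, s_traj, temps, energies, max_res
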