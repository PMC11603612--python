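"""Propagation of λ, buffer, environment and gate coordinates.

Two operating modes mirror the two simulation protocols being compared:

``ph_afed``
    Massive Nosé–Hoover-chain thermostatting: every λ coordinate gets its
    own chain at its (high) fictitious temperature T_λ while environment
    coordinates stay at the physical temperature.  Chains are applied in a
    velocity-Verlet "side" scheme (half thermostat step before and after
    the Verlet update).

``standard``
    The conventional CpHMD baseline: one stochastic velocity-rescaling
    thermostat over the pooled kinetic energy of all coordinates at the
    physical temperature, with a light λ mass (m_λ = 5).

A SHAKE-like projection enforces the linear charge-neutrality constraint
Σ_i α_i λ_i = const after every position update, and a RATTLE-like
projection removes the constraint-violating velocity component (needed for
per-λ kinetic temperatures to be well defined).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Union

import numpy as np

from . import _kernel
from .constants import KB, LN10
from .model import HisSiteSpec, ModelSystem

__all__ = [
    "ThermoParams",
    "NHCState",
    "ConstraintSpec",
    "SimState",
    "Trajectory",
    "suzuki_yoshida_weights",
    "nhc_half_step",
    "apply_charge_constraint",
    "integrate_step",
    "run_simulation",
    "instantaneous_temperatures",
    "STANDARD_MODE_M_LAMBDA",
]

#: λ mass used by the standard-CpHMD baseline mode.
STANDARD_MODE_M_LAMBDA = 5.0


def suzuki_yoshida_weights(order: int) -> np.ndarray:
    """Suzuki–Yoshida factorization weights for the NHC propagator."""
    if order == 1:
        return np.array([1.0])
    if order == 4:
        w1 = 1.0 / (2.0 - 2.0 ** (1.0 / 3.0))
        return np.array([w1, 1.0 - 2.0 * w1, w1])
    if order == 6:
        w = np.array([
            0.784513610477560, 0.235573213359357, -1.17767998417887,
        ])
        mid = 1.0 - 2.0 * w.sum()
        return np.concatenate([w, [mid], w[::-1]])
    raise ValueError(f"unsupported Suzuki-Yoshida order {order} (use 1, 4 or 6)")


@dataclass
class ThermoParams:
    """Nosé–Hoover chain parameters (defaults follow common CpHMD practice)."""

    chain_length: int = 4
    time_constant: float = 0.5  # ps
    suzuki_yoshida_order: int = 4
    n_multiple_steps: int = 5
    target_T: float = 300.0

    def __post_init__(self) -> None:
        if self.chain_length < 1:
            raise ValueError("chain_length must be >= 1")
        if not (self.time_constant > 0):
            raise ValueError("time_constant must be > 0")
        suzuki_yoshida_weights(self.suzuki_yoshida_order)  # validates


@dataclass
class NHCState:
    """Per-degree-of-freedom thermostat chains ("massive" mode)."""

    eta: np.ndarray  # (n_dof, chain_length) chain positions
    p_eta: np.ndarray  # (n_dof, chain_length) chain momenta
    Q: np.ndarray  # (n_dof, chain_length) chain masses
    target_T: np.ndarray  # (n_dof,) per-dof target temperature

    @classmethod
    def initialize(cls, targets: np.ndarray, params: ThermoParams) -> "NHCState":
        targets = np.asarray(targets, dtype=float)
        n = targets.size
        M = params.chain_length
        Q = KB * targets[:, None] * params.time_constant ** 2 * np.ones((n, M))
        if np.any(Q <= 0):
            raise ValueError("chain masses must be positive")
        return cls(
            eta=np.zeros((n, M)),
            p_eta=np.zeros((n, M)),
            Q=Q,
            target_T=targets,
        )


@dataclass
class ConstraintSpec:
    """Linear charge-neutrality constraint Σ_i α_i λ_i = target."""

    alpha: np.ndarray
    target: float

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if not np.any(self.alpha != 0.0):
            raise ValueError(
                "charge constraint undefined: all α coefficients are zero"
            )


def apply_charge_constraint(lambda_u, velocity_u, spec: ConstraintSpec, masses):
    """SHAKE/RATTLE projection for the linear charge constraint.

    Positions: λ_i = λ_i^u − ζ α_i / m_i with
    ζ = (Σ α_i λ_i^u − target) / (Σ α_i² / m_i); velocities get the
    analogous projection that removes the constraint-violating component.
    """
    lam = np.array(lambda_u, dtype=float)
    vel = np.array(velocity_u, dtype=float)
    m = np.asarray(masses, dtype=float)
    inv_m = 1.0 / m
    den = float(np.sum(spec.alpha ** 2 * inv_m))
    zeta = (float(np.dot(spec.alpha, lam)) - spec.target) / den
    lam -= zeta * spec.alpha * inv_m
    zeta_v = float(np.dot(spec.alpha, vel)) / den
    vel -= zeta_v * spec.alpha * inv_m
    return lam, vel


def nhc_half_step(nhc: NHCState, velocities, masses, dt: float,
                  params: Optional[ThermoParams] = None):
    """Apply the Suzuki–Yoshida-factorized NHC velocity scaling for dt/2."""
    if not dt > 0:
        raise ValueError("dt must be > 0")
    if params is None:
        params = ThermoParams()
    v = np.array(velocities, dtype=float)
    m = np.asarray(masses, dtype=float)
    sy = suzuki_yoshida_weights(params.suzuki_yoshida_order)
    for i in range(v.size):
        v[i] = _kernel._nhc_scale(
            v[i], m[i], KB * nhc.target_T[i],
            nhc.p_eta[i], nhc.eta[i], nhc.Q[i],
            0.5 * dt, sy, params.n_multiple_steps,
        )
    return nhc, v


# ---------------------------------------------------------------------------
# System compilation: ModelSystem -> flat kernel arrays
# ---------------------------------------------------------------------------

from .dafed import ExtendedVariable  # noqa: E402  (avoids a circular import)


@dataclass
class _Compiled:
    """Flat array view of a ModelSystem for the numba kernel."""

    system: ModelSystem
    mode: str
    lambda_names: List[str]
    n_site_lam: int
    m_l: np.ndarray
    T_l: np.ndarray
    c_ph: np.ndarray
    h_bar: np.ndarray
    env_idx: np.ndarray
    gate_idx: np.ndarray
    offset_l: np.ndarray
    m_e: np.ndarray
    T_e: np.ndarray
    kA: np.ndarray
    kB_c: np.ndarray
    xA: np.ndarray
    xB: np.ndarray
    m_g: np.ndarray
    T_g: np.ndarray
    gate_h: np.ndarray
    gate_site: List[str]
    rest_idx: np.ndarray
    rest_amp: np.ndarray
    rest_flat: np.ndarray
    rest_sw: np.ndarray
    alpha: np.ndarray
    lam0: np.ndarray
    x0: np.ndarray
    g0: np.ndarray
    dafed_on: np.ndarray
    k_s: np.ndarray
    m_s: np.ndarray
    T_s: np.ndarray
    gamma_s: np.ndarray
    s0: np.ndarray


def compile_system(system: ModelSystem, mode: str = "ph_afed",
                   extended: Optional[Dict[str, ExtendedVariable]] = None) -> _Compiled:
    """Flatten a ModelSystem into the kernel's array layout."""
    if mode not in ("ph_afed", "standard"):
        raise ValueError(f"invalid mode {mode!r} (use 'ph_afed' or 'standard')")
    extended = extended or {}
    for sid in extended:
        if sid not in {s.site_id for s in system.sites}:
            raise KeyError(f"d-AFED CV selector names unknown site {sid!r}")

    names: List[str] = []
    m_l, T_l, c_ph, h_bar, env_idx, gate_idx, offset_l, alpha, lam0 = (
        [] for _ in range(9)
    )
    m_e, T_e, kA, kB_c, xA, xB, x0 = ([] for _ in range(7))
    m_g, T_g, gate_h, g0 = ([] for _ in range(4))
    gate_site: List[str] = []
    rest_rows, rest_amp, rest_flat, rest_sw = [], [], [], []
    dafed_on, k_s, m_s, T_s_arr, gamma_s, s0 = ([] for _ in range(6))
    T_phys = system.T_physical

    for k, site in enumerate(system.sites):
        env = system.envs[k]
        m_e.append(env.mass)
        T_e.append(T_phys)
        kA.append(env.curv_A)
        kB_c.append(env.curv_B)
        xA.append(env.min_A)
        xB.append(env.min_B)
        x0.append(env.min_A)
        gidx = -1
        if site.gate_height > 0:
            gidx = len(m_g)
            m_g.append(10.0)  # conformational coordinate: slower than env,
            # fast enough for the d-AFED variable to drive adiabatically
            T_g.append(T_phys)
            gate_h.append(site.gate_height)
            g0.append(0.0)  # gate starts closed
            gate_site.append(site.site_id)
            ev = extended.get(site.site_id)
            if ev is not None:
                dafed_on.append(1)
                k_s.append(ev.coupling_k)
                m_s.append(ev.mass)
                T_s_arr.append(ev.T_s)
                gamma_s.append(ev.friction_gamma)
                s0.append(0.0)
            else:
                dafed_on.append(0)
                k_s.append(0.0)
                m_s.append(1.0)
                T_s_arr.append(1.0)
                gamma_s.append(0.0)
                s0.append(0.0)

        if isinstance(site, HisSiteSpec):
            base = len(names)
            rest_rows.append([base, base + 1, base + 2])
            rest_amp.append(site.restraint.amplitude)
            rest_flat.append(site.restraint.flat_width)
            rest_sw.append(site.restraint.switch_width)
            for j, suffix in enumerate(("p", "c", "d")):
                names.append(f"lam_{site.site_id}_{suffix}")
                m_l.append(site.m_lambda)
                T_l.append(site.T_lambda)
                h_bar.append(site.barrier_height)
                if j == 0:
                    c_ph.append(0.0)  # protonated reference state: no pH term
                    env_idx.append(-1)
                    gate_idx.append(-1)
                    offset_l.append(0.0)
                    alpha.append(site.alpha)
                    lam0.append(1.0)  # start protonated
                else:
                    pka = site.pKa_micro[j - 1]
                    c_ph.append(LN10 * KB * T_phys * (pka - system.pH))
                    env_idx.append(k)
                    gate_idx.append(gidx)
                    offset_l.append(site.env_offset_dG)
                    alpha.append(0.0)
                    lam0.append(0.0)
        else:
            names.append(f"lam_{site.site_id}")
            m_l.append(site.m_lambda)
            T_l.append(site.T_lambda)
            c_ph.append(LN10 * KB * T_phys * (site.pKa_ref - system.pH))
            h_bar.append(site.barrier_height)
            env_idx.append(k)
            gate_idx.append(gidx)
            offset_l.append(site.env_offset_dG)
            alpha.append(site.alpha)
            lam0.append(0.0)  # acids start protonated

    n_site_lam = len(names)
    buf = system.buffers
    for b in range(buf.count):
        names.append(f"buf_{b}")
        m_l.append(buf.m_lambda)
        T_l.append(buf.T_lambda)
        c_ph.append(0.0)
        h_bar.append(0.0)
        env_idx.append(-1)
        gate_idx.append(-1)
        offset_l.append(0.0)
        alpha.append(buf.alpha_each)
        lam0.append(0.5)  # mid-range so charge can be absorbed either way

    if mode == "standard":
        m_l = [STANDARD_MODE_M_LAMBDA] * len(m_l)
        T_l = [T_phys] * len(T_l)

    def arr(v, dtype=float):
        return np.array(v, dtype=dtype)

    return _Compiled(
        system=system, mode=mode, lambda_names=names, n_site_lam=n_site_lam,
        m_l=arr(m_l), T_l=arr(T_l), c_ph=arr(c_ph), h_bar=arr(h_bar),
        env_idx=arr(env_idx, np.int64), gate_idx=arr(gate_idx, np.int64),
        offset_l=arr(offset_l),
        m_e=arr(m_e), T_e=arr(T_e), kA=arr(kA), kB_c=arr(kB_c),
        xA=arr(xA), xB=arr(xB),
        m_g=arr(m_g), T_g=arr(T_g), gate_h=arr(gate_h), gate_site=gate_site,
        rest_idx=(np.array(rest_rows, dtype=np.int64)
                  if rest_rows else np.empty((0, 3), dtype=np.int64)),
        rest_amp=arr(rest_amp), rest_flat=arr(rest_flat), rest_sw=arr(rest_sw),
        alpha=arr(alpha), lam0=arr(lam0), x0=arr(x0), g0=arr(g0),
        dafed_on=arr(dafed_on, np.int64), k_s=arr(k_s), m_s=arr(m_s),
        T_s=arr(T_s_arr), gamma_s=arr(gamma_s), s0=arr(s0),
    )


@dataclass
class SimState:
    """Instantaneous dynamical state (positions, velocities, thermostats)."""

    lam: np.ndarray
    vlam: np.ndarray
    env_x: np.ndarray
    env_v: np.ndarray
    gate_x: np.ndarray
    gate_v: np.ndarray
    s: np.ndarray
    s_v: np.ndarray
    nhc_lam: Optional[NHCState] = None
    nhc_env: Optional[NHCState] = None
    nhc_gate: Optional[NHCState] = None
    step: int = 0
    time: float = 0.0
    constraint: Optional[ConstraintSpec] = None
    # group bookkeeping for temperature diagnostics
    m_lam: Optional[np.ndarray] = None
    m_env: Optional[np.ndarray] = None
    m_gate: Optional[np.ndarray] = None
    m_s: Optional[np.ndarray] = None
    n_site_lam: int = 0


def initial_state(comp: _Compiled, params: ThermoParams,
                  constraint: bool = True) -> SimState:
    """Build the canonical starting state: protonated sites, env at A-minimum."""
    lam = comp.lam0.copy()
    alpha = comp.alpha
    spec = None
    if constraint and np.any(alpha != 0.0):
        spec = ConstraintSpec(alpha=alpha, target=float(np.dot(alpha, lam)))
    n_l = lam.size
    n_e = comp.x0.size
    n_g = comp.g0.size
    return SimState(
        lam=lam, vlam=np.zeros(n_l),
        env_x=comp.x0.copy(), env_v=np.zeros(n_e),
        gate_x=comp.g0.copy(), gate_v=np.zeros(n_g),
        s=comp.s0.copy(), s_v=np.zeros(n_g),
        nhc_lam=NHCState.initialize(comp.T_l, params),
        nhc_env=NHCState.initialize(comp.T_e, params),
        nhc_gate=NHCState.initialize(comp.T_g, params) if n_g else None,
        constraint=spec,
        m_lam=comp.m_l, m_env=comp.m_e, m_gate=comp.m_g, m_s=comp.m_s,
        n_site_lam=comp.n_site_lam,
    )


@dataclass
class Trajectory:
    """Sampled time series of a single run, with complete metadata."""

    times: np.ndarray  # ps
    lam: np.ndarray  # (n_frames, n_lambda)
    lambda_names: List[str]
    env: np.ndarray
    gate: np.ndarray
    s: np.ndarray
    temps: np.ndarray  # columns: site λ, buffer, env, gate, s
    energies: np.ndarray  # columns: see ENERGY_COLUMNS
    metadata: Dict[str, object] = field(default_factory=dict)
    max_constraint_residual: float = 0.0

    ENERGY_COLUMNS = (
        "pot_total", "e_ph", "e_barrier", "e_env", "e_restraint",
        "e_gate", "e_coupling", "kin_lambda", "kin_env", "conserved",
    )
    TEMP_COLUMNS = ("T_site_lambda", "T_buffer", "T_env", "T_gate", "T_s")

    def lambda_series(self, name: str) -> np.ndarray:
        try:
            j = self.lambda_names.index(name)
        except ValueError:
            raise KeyError(f"no λ column named {name!r}; have {self.lambda_names}")
        return self.lam[:, j]

    def site_columns(self, site_id: str) -> List[str]:
        pref = f"lam_{site_id}"
        cols = [n for n in self.lambda_names
                if n == pref or n.startswith(pref + "_")]
        if not cols:
            raise KeyError(f"site {site_id!r} not present in trajectory")
        return cols


def _kernel_args(comp: _Compiled, state: SimState, n_steps: int, dt: float,
                 stride: int, seed: int, mode_code: int, init_vel: bool,
                 use_constraint: bool, params: ThermoParams):
    sy = suzuki_yoshida_weights(params.suzuki_yoshida_order)
    n_g = comp.g0.size
    M = params.chain_length
    nhc_l = state.nhc_lam or NHCState.initialize(comp.T_l, params)
    nhc_e = state.nhc_env or NHCState.initialize(comp.T_e, params)
    nhc_g = state.nhc_gate or (NHCState.initialize(comp.T_g, params)
                               if n_g else NHCState(
                                   np.zeros((0, M)), np.zeros((0, M)),
                                   np.zeros((0, M)), np.zeros(0)))
    target = state.constraint.target if state.constraint is not None else 0.0
    return (
        n_steps, dt, stride, seed, mode_code, 1 if init_vel else 0,
        comp.n_site_lam,
        state.lam, state.vlam, comp.m_l, comp.T_l, comp.c_ph, comp.h_bar,
        comp.env_idx, comp.gate_idx, comp.offset_l,
        state.env_x, state.env_v, comp.m_e, comp.T_e, comp.kA, comp.kB_c,
        comp.xA, comp.xB,
        state.gate_x, state.gate_v, comp.m_g, comp.T_g, comp.gate_h,
        comp.rest_idx, comp.rest_amp, comp.rest_flat, comp.rest_sw,
        comp.alpha, target, 1 if use_constraint else 0,
        params.time_constant, sy, params.n_multiple_steps,
        nhc_l.eta, nhc_l.p_eta, nhc_e.eta, nhc_e.p_eta,
        nhc_g.eta, nhc_g.p_eta,
        params.time_constant,
        comp.dafed_on, state.s, state.s_v, comp.k_s, comp.m_s, comp.T_s,
        comp.gamma_s,
    )


def integrate_step(state: SimState, system: ModelSystem,
                   params: Optional[ThermoParams] = None, dt: float = 0.002,
                   mode: str = "ph_afed", thermostat: bool = True) -> SimState:
    """Advance the state by one velocity-Verlet step (in place) and return it.

    Step sequence: thermostat half-step → half-kick → drift → SHAKE →
    force evaluation → half-kick → RATTLE → thermostat half-step.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    params = params or ThermoParams(target_T=system.T_physical)
    comp = compile_system(system, mode)
    if not thermostat:
        mode_code = _kernel.MODE_NVE
    else:
        mode_code = _kernel.MODE_NHC if mode == "ph_afed" else _kernel.MODE_CSVR
    use_constraint = state.constraint is not None
    out = _kernel.run_kernel(*_kernel_args(
        comp, state, 1, dt, 1, 0, mode_code, False, use_constraint, params))
    if not math.isfinite(out[5][0, 0]):
        raise FloatingPointError(
            "non-finite energy encountered during integration step"
        )
    state.step += 1
    state.time += dt
    return state


def run_simulation(system: Union[ModelSystem, "object"], mode: str = "ph_afed",
                   n_steps: int = 200_000, dt: float = 0.002, seed: int = 0,
                   sample_stride: int = 10,
                   thermostat: bool = True, constraint: bool = True,
                   params: Optional[ThermoParams] = None,
                   extended: Optional[Dict[str, ExtendedVariable]] = None,
                   ) -> Trajectory:
    """Run a complete seeded simulation and return its Trajectory.

    Velocities are drawn from the Maxwell distribution at each coordinate's
    target temperature using the seeded stream, so identical (seed, config)
    pairs give bitwise-identical trajectories.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if sample_stride < 1 or sample_stride > n_steps:
        raise ValueError("sample_stride must be in [1, n_steps]")
    # allow a d-AFED-augmented system wrapper (see phafed.dafed)
    if hasattr(system, "base") and hasattr(system, "extended"):
        extended = dict(system.extended) if extended is None else extended
        system = system.base
    comp = compile_system(system, mode, extended)
    params = params or ThermoParams(target_T=system.T_physical)
    state = initial_state(comp, params, constraint=constraint)
    use_constraint = state.constraint is not None
    if thermostat:
        mode_code = _kernel.MODE_NHC if mode == "ph_afed" else _kernel.MODE_CSVR
    else:
        mode_code = _kernel.MODE_NVE
    seed = int(seed) % (2 ** 31)
    out = _kernel.run_kernel(*_kernel_args(
        comp, state, int(n_steps), float(dt), int(sample_stride), seed,
        mode_code, True, use_constraint, params))
    lam_t, env_t, gate_t, s_t, temps, energies, max_res = out
    if not np.isfinite(energies[:, 0]).all():
        raise FloatingPointError(
            "non-finite energy during run (first bad frame %d)"
            % int(np.flatnonzero(~np.isfinite(energies[:, 0]))[0])
        )
    n_frames = lam_t.shape[0]
    times = dt * sample_stride * np.arange(1, n_frames + 1)
    meta = {
        "pH": system.pH,
        "seed": seed,
        "mode": mode,
        "dt": dt,
        "sample_stride": sample_stride,
        "n_steps": int(n_steps),
        "T_physical": system.T_physical,
        "site_ids": [s.site_id for s in system.sites],
        "T_lambda": [s.T_lambda for s in system.sites],
        "thermostat": thermostat,
        "constraint": use_constraint,
        "dafed_sites": sorted(extended) if extended else [],
    }
    return Trajectory(
        times=times, lam=lam_t, lambda_names=comp.lambda_names,
        env=env_t, gate=gate_t, s=s_t, temps=temps, energies=energies,
        metadata=meta, max_constraint_residual=float(max_res),
    )


def instantaneous_temperatures(state: SimState) -> Dict[str, float]:
    """Per-group kinetic temperatures T = m v² / k_B (1-dof convention)."""
    out: Dict[str, float] = {}
    n_site = state.n_site_lam
    m_lam = state.m_lam
    if m_lam is not None and state.lam.size:
        ke = m_lam * state.vlam ** 2 / KB
        if n_site:
            out["site_lambda"] = float(ke[:n_site].mean())
        if state.lam.size > n_site:
            out["buffer"] = float(ke[n_site:].mean())
    if state.m_env is not None and state.env_x.size:
        out["env"] = float((state.m_env * state.env_v ** 2 / KB).mean())
    if state.m_gate is not None and state.gate_x.size:
        out["gate"] = float((state.m_gate * state.gate_v ** 2 / KB).mean())
    return out
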