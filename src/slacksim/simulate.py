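"""Deterministic integration of the compartmental cable equations.

The integrator advances the branched cable equation with a
Crank–Nicolson-style implicit update for the voltages (second order,
unconditionally stable) and exact exponential (closed-form) updates for
the gating variables and the submembrane Na⁺ pool, staggered in the usual
way: gates and Na⁺ advance on the state at the start of the step, then the
voltage solve uses the updated conductances.  The default time step is
0.025 ms.

Three stimulus protocols mirror standard patch-clamp practice:

* current-clamp step families (the "culture" variant: 500 ms pulses from
  −100 pA in 20 pA increments; the "slice" variant: 1 s pulses from
  −30 pA in 5 pA increments),
* a voltage-step family for K_Na measurement (hold −70 mV, 1 s steps from
  −80 to +50 mV in 10 mV increments), and
* a slow voltage ramp for persistent-Na⁺ isolation (hold −80 mV, 20 mV/s
  for 5 s, repeated every 10 s).

Virtual pharmacology is parameter substitution: a blocker removes a
fraction of the conductance of every channel it targets (TTX → both Na⁺
currents, VU170 → KCNT1).  Voltage clamp is ideal (zero series
resistance) and can be somatic (dendrites free, the whole-cell situation)
or space clamp (every compartment follows the command), the latter being
the configuration used for subtraction-current verification runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from . import channels as chn
from .channels import FARADAY_C_PER_MOL, GateSpec
from .neurons import NeuronModel

__all__ = [
    "Stimulus",
    "Protocol",
    "BlockerState",
    "Recording",
    "IntegrationError",
    "run_protocol",
    "make_current_step_protocol",
    "make_voltage_step_protocol",
    "make_ramp_protocol",
]


class IntegrationError(RuntimeError):
    """Raised when the membrane potential diverges during integration."""


@dataclass(frozen=True)
class Stimulus:
    """One sweep's stimulus: a square step or a linear ramp.

    ``amplitude`` is in pA for current clamp and mV (absolute command
    level) for voltage-clamp steps; ramps start at the holding level and
    climb at ``ramp_rate_mV_per_s``.
    """

    kind: str = "step"  # 'step' | 'ramp'
    amplitude: float = 0.0
    duration_ms: float = 500.0
    ramp_rate_mV_per_s: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("step", "ramp"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        if not np.isfinite(self.ramp_rate_mV_per_s):
            raise ValueError("ramp rate must be finite")


@dataclass(frozen=True)
class Protocol:
    """A stimulus family: mode, holding level and ordered sweeps."""

    mode: str  # 'current_clamp' | 'voltage_clamp'
    holding: float = 0.0  # pA (current clamp) or mV (voltage clamp)
    sweeps: tuple[Stimulus, ...] = ()
    dt_ms: float = 0.025
    pre_ms: float = 100.0
    post_ms: float = 300.0
    inter_sweep_s: float = 5.0
    settle_ms: float = 300.0
    clamp_mode: str = "soma"  # 'soma' | 'space' (voltage clamp only)
    record: tuple[str, ...] = ("v", "i", "na")
    decimate_khz: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("current_clamp", "voltage_clamp"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")
        if not self.sweeps:
            raise ValueError("sweep list must be non-empty")
        if self.clamp_mode not in ("soma", "space"):
            raise ValueError(f"unknown clamp mode {self.clamp_mode!r}")
        object.__setattr__(self, "sweeps", tuple(self.sweeps))

    @property
    def sweep_ms(self) -> float:
        return self.pre_ms + max(s.duration_ms for s in self.sweeps) + self.post_ms

    def amplitudes(self) -> np.ndarray:
        return np.array([s.amplitude for s in self.sweeps], dtype=float)


@dataclass(frozen=True)
class BlockerState:
    """A virtual bath drug at a blocked fraction of its target channels."""

    drug: str  # 'TTX' | 'VU170'
    fraction_blocked: float = 1.0
    onset_sweep: int = 0
    onset_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.drug not in ("TTX", "VU170"):
            raise ValueError(f"unknown drug {self.drug!r}")
        if not 0.0 <= self.fraction_blocked <= 1.0:
            raise ValueError("fraction_blocked must lie in [0, 1]")


@dataclass
class Recording:
    """Multi-sweep time-series output of one protocol run.

    All traces share ``time_ms`` and have shape (n_sweeps, n_samples).
    ``traces`` holds whatever was recorded: 'v' (somatic mV), 'i' (clamp
    or injected current, pA), 'na' (somatic [Na⁺]ᵢ, mM), 'i_kcnt1' and
    'i_na_ch' (total logged KCNT1 / Na⁺-carrying channel current, pA,
    outward positive) and 'command' (voltage-clamp command, mV).
    """

    time_ms: np.ndarray
    traces: dict[str, np.ndarray]
    stim_onset_ms: float
    stim_dur_ms: float
    amplitudes: np.ndarray
    mode: str
    holding: float
    dt_ms: float
    provenance: dict = field(default_factory=dict)

    @property
    def n_sweeps(self) -> int:
        return len(self.amplitudes)

    def sweep(self, key: str, i: int) -> np.ndarray:
        return self.traces[key][i]

    def to_dataframe(self):
        """Flat tabular export: one row per (sweep, sample)."""
        import pandas as pd

        n_s, n_t = next(iter(self.traces.values())).shape
        data = {
            "sweep": np.repeat(np.arange(n_s), n_t),
            "time_ms": np.tile(self.time_ms, n_s),
            "amplitude": np.repeat(self.amplitudes, n_t),
        }
        for key, arr in self.traces.items():
            data[key] = arr.reshape(-1)
        return pd.DataFrame(data)

    def to_hdf5(self, path) -> None:
        """Write one group per sweep plus shared metadata."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("time_ms", data=self.time_ms)
            f.attrs["mode"] = self.mode
            f.attrs["holding"] = self.holding
            f.attrs["dt_ms"] = self.dt_ms
            f.attrs["stim_onset_ms"] = self.stim_onset_ms
            f.attrs["stim_dur_ms"] = self.stim_dur_ms
            f.attrs["provenance"] = json.dumps(self.provenance)
            for i in range(self.n_sweeps):
                g = f.create_group(f"sweep{i:03d}")
                g.attrs["amplitude"] = self.amplitudes[i]
                for key, arr in self.traces.items():
                    g.create_dataset(key, data=arr[i])

    @classmethod
    def from_hdf5(cls, path) -> "Recording":
        import h5py

        with h5py.File(path, "r") as f:
            time_ms = f["time_ms"][...]
            names = sorted(k for k in f.keys() if k.startswith("sweep"))
            amplitudes = np.array([f[n].attrs["amplitude"] for n in names])
            keys = list(f[names[0]].keys())
            traces = {k: np.stack([f[n][k][...] for n in names]) for k in keys}
            return cls(
                time_ms=time_ms, traces=traces,
                stim_onset_ms=float(f.attrs["stim_onset_ms"]),
                stim_dur_ms=float(f.attrs["stim_dur_ms"]),
                amplitudes=amplitudes, mode=str(f.attrs["mode"]),
                holding=float(f.attrs["holding"]), dt_ms=float(f.attrs["dt_ms"]),
                provenance=json.loads(f.attrs["provenance"]),
            )


# ---------------------------------------------------------------------------
# Model compilation


class _Compiled:
    """Flat array representation of a NeuronModel for the integrator."""

    def __init__(self, neuron: NeuronModel, blockers: Sequence[BlockerState]):
        comps = list(neuron.compartments.values())
        order = {c.id: i for i, c in enumerate(comps)}
        n = len(comps)
        self.n = n
        self.soma = order[neuron.soma_id]
        self.area = np.array([c.area_cm2 for c in comps])  # cm²
        self.c_nF = np.array([c.cm_uF_per_cm2 * c.area_cm2 * 1e3 for c in comps])
        self.e_leak_guess = -70.0

        # Axial conductance matrix (µS), Laplacian form.
        A = np.zeros((n, n))
        for c in comps:
            if c.parent is None:
                continue
            i, j = order[c.id], order[c.parent]
            p = neuron.compartments[c.parent]
            # series resistance of the two half-cylinders, in ohms
            r = 0.0
            for seg in (c, p):
                ax_area_um2 = np.pi * seg.diameter_um ** 2 / 4.0
                r += seg.ra_ohm_cm * (seg.length_um / 2.0) / ax_area_um2 * 1e4
            g = 1e6 / r  # µS
            A[i, j] += g
            A[j, i] += g
            A[i, i] -= g
            A[j, j] -= g
        self.A = A

        block = {}
        for b in blockers:
            block[b.drug] = max(block.get(b.drug, 0.0), b.fraction_blocked)

        # Flatten channel and gate instances.
        ch_comp, ch_gd, ch_erev, ch_carries_na, ch_is_kcnt1 = [], [], [], [], []
        ch_gates: list[list[int]] = []
        g_specs: list[GateSpec] = []
        g_comp: list[int] = []
        for c in comps:
            ci = order[c.id]
            for name, dens in c.channels.items():
                spec = neuron.channel_library[name]
                factor = 1.0
                for drug, frac in block.items():
                    if drug in spec.blockable_by:
                        factor *= (1.0 - frac)
                ch_comp.append(ci)
                ch_gd.append(dens * factor)  # S/cm²
                ch_erev.append(spec.e_rev_mV)
                ch_carries_na.append(spec.carries_na)
                ch_is_kcnt1.append(name == chn.KCNT1)
                idxs = []
                for g in spec.gates:
                    idxs.append(len(g_specs))
                    g_specs.append(g)
                    g_comp.append(ci)
                ch_gates.append(idxs)
        self.ch_comp = np.array(ch_comp, dtype=np.int64)
        self.ch_gd = np.array(ch_gd)
        self.ch_erev = np.array(ch_erev)
        self.ch_carries_na = np.array(ch_carries_na, dtype=bool)
        self.ch_is_kcnt1 = np.array(ch_is_kcnt1, dtype=bool)
        self.ch_gates = ch_gates
        ptr = [0]
        flat: list[int] = []
        for idxs in ch_gates:
            flat.extend(idxs)
            ptr.append(len(flat))
        self.ch_gate_ptr = np.array(ptr, dtype=np.int64)
        self.ch_gate_idx = np.array(flat, dtype=np.int64)

        ng = len(g_specs)
        self.ng = ng
        self.g_comp = np.array(g_comp, dtype=int)
        self.g_is_hill = np.array([g.kind == "hill_na" for g in g_specs])
        self.g_v50 = np.array([g.v50_mV for g in g_specs])
        self.g_slope = np.array([g.slope_mV if g.kind == "boltzmann_v" else 1.0
                                 for g in g_specs])
        self.g_ec50 = np.array([g.ec50_mM if g.kind == "hill_na" else 1.0
                                for g in g_specs])
        self.g_hill = np.array([g.hill_coef if g.kind == "hill_na" else 1.0
                                for g in g_specs])
        self.g_tau0 = np.array([g.tau_ms for g in g_specs])
        self.g_tau_amp = np.array([g.tau_amp_ms for g in g_specs])
        self.g_tau_vpeak = np.array([g.tau_vpeak_mV for g in g_specs])
        self.g_tau_sigma = np.array([g.tau_sigma_mV for g in g_specs])
        self.g_power = np.array([g.power for g in g_specs], dtype=int)

        self.na_pool = neuron.na_pool

    # -- gate math (batched over sweeps) ------------------------------------

    def gate_targets(self, V: np.ndarray, Na: np.ndarray) -> np.ndarray:
        """Steady-state open fractions, shape (S, ng)."""
        v = V[:, self.g_comp]
        tgt = 1.0 / (1.0 + np.exp(-(v - self.g_v50) / self.g_slope))
        if self.g_is_hill.any():
            hi = self.g_is_hill
            na = Na[:, self.g_comp[hi]]
            r = np.power(np.maximum(na, 0.0) / self.g_ec50[hi], self.g_hill[hi])
            tgt[:, hi] = r / (r + 1.0)
        return tgt

    def gate_taus(self, V: np.ndarray) -> np.ndarray:
        v = V[:, self.g_comp]
        tau = self.g_tau0 + self.g_tau_amp * np.exp(
            -(((v - self.g_tau_vpeak) / self.g_tau_sigma) ** 2))
        return tau

    def init_state(self, v0: float, n_batch: int):
        V = np.full((n_batch, self.n), v0)
        na0 = (self.na_pool.clamp_to_mM if self.na_pool.clamp_to_mM is not None
               else self.na_pool.na_rest_mM)
        Na = np.full((n_batch, self.n), float(na0))
        G = self.gate_targets(V, Na)
        return V, Na, G

    def conductances(self, G: np.ndarray):
        """Per-channel open conductance density (S/cm²), shape (S, nch)."""
        nch = len(self.ch_gd)
        open_p = np.ones((G.shape[0], nch))
        for k, idxs in enumerate(self.ch_gates):
            for gi in idxs:
                p = self.g_power[gi]
                open_p[:, k] *= G[:, gi] ** p if p > 1 else G[:, gi]
        return open_p * self.ch_gd


def _model_hash(neuron: NeuronModel) -> str:
    parts = [neuron.subtype]
    for cid in sorted(neuron.compartments):
        c = neuron.compartments[cid]
        parts.append(f"{cid}:{c.region}:{c.length_um:.6g}:{c.diameter_um:.6g}:"
                     f"{sorted((k, round(v, 12)) for k, v in c.channels.items())}")
    for name in sorted(neuron.channel_library):
        parts.append(repr(neuron.channel_library[name]))
    parts.append(repr(neuron.na_pool))
    return hashlib.sha256("|".join(parts).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Integration


def _command_waveforms(protocol: Protocol, time_ms: np.ndarray) -> np.ndarray:
    """Per-sweep stimulus waveform on the time grid (pA or mV)."""
    S = len(protocol.sweeps)
    cmd = np.full((S, len(time_ms)), float(protocol.holding))
    on = protocol.pre_ms
    for i, s in enumerate(protocol.sweeps):
        m = (time_ms >= on) & (time_ms < on + s.duration_ms)
        if s.kind == "step":
            cmd[i, m] = s.amplitude if protocol.mode == "voltage_clamp" \
                else protocol.holding + s.amplitude
        else:
            t_rel = time_ms[m] - on
            base = protocol.holding
            cmd[i, m] = base + s.ramp_rate_mV_per_s * t_rel / 1000.0
            # after the ramp, return to holding
    return cmd


def _run_kernel(comp: _Compiled, cmd: np.ndarray, dt: float, vc: bool,
                clamp_mode: str, V, Na, G, log_ch: bool):
    from . import _kernel

    S, T = cmd.shape
    n_steps = T - 1
    out_v = np.zeros((S, T))
    out_na = np.zeros((S, T))
    out_i = np.zeros((S, T))
    out_ik = np.zeros((S, T))
    out_ina = np.zeros((S, T))
    pool = comp.na_pool
    bad_sweep, bad_step = _kernel.integrate(
        vc, clamp_mode == "space", comp.soma, dt, n_steps,
        comp.A, comp.c_nF, comp.area,
        comp.ch_comp, comp.ch_gd, comp.ch_erev, comp.ch_carries_na,
        comp.ch_is_kcnt1, comp.ch_gate_ptr, comp.ch_gate_idx,
        comp.g_comp.astype(np.int64), comp.g_is_hill, comp.g_v50,
        comp.g_slope, comp.g_ec50, comp.g_hill, comp.g_tau0, comp.g_tau_amp,
        comp.g_tau_vpeak, comp.g_tau_sigma, comp.g_power.astype(np.int64),
        pool.clamp_to_mM is not None,
        0.0 if pool.clamp_to_mM is None else float(pool.clamp_to_mM),
        pool.na_rest_mM, pool.tau_na_ms, pool.depth_um,
        cmd, V, Na, G,
        out_v, out_na, out_i, out_ik, out_ina, log_ch,
    )
    if log_ch and T > 1:
        out_ik[:, 0] = out_ik[:, 1]
        out_ina[:, 0] = out_ina[:, 1]
    return bad_sweep, bad_step, out_v, out_na, out_i, out_ik, out_ina


def run_protocol(neuron: NeuronModel, protocol: Protocol,
                 blockers: Sequence[BlockerState] = (),
                 engine: str = "auto") -> Recording:
    """Run one stimulus protocol on a model neuron.

    Deterministic in (neuron, protocol, blockers, dt).  All sweeps start
    from the same settled resting (or holding) state and are integrated in
    parallel.  Raises :class:`IntegrationError` if any voltage exceeds
    ±200 mV.  ``engine`` selects the compiled kernel ('kernel', default
    through 'auto') or the reference numpy stepper ('numpy', slow; used
    for cross-checks).
    """
    comp = _Compiled(neuron, blockers)
    dt = protocol.dt_ms
    vc = protocol.mode == "voltage_clamp"

    n_steps = int(round(protocol.sweep_ms / dt))
    time_ms = np.arange(n_steps + 1) * dt
    cmd = _command_waveforms(protocol, time_ms)
    S = cmd.shape[0]
    use_kernel = engine in ("auto", "kernel")
    if engine not in ("auto", "kernel", "numpy"):
        raise ValueError(f"unknown engine {engine!r}")

    # settle at rest / holding
    e_leak = neuron.channel_library[chn.LEAK].e_rev_mV \
        if chn.LEAK in neuron.channel_library else -70.0
    V, Na, G = comp.init_state(e_leak, 1)
    n_settle = int(round(protocol.settle_ms / dt))
    hold_cmd = np.full((1, n_settle + 1), float(protocol.holding))
    if use_kernel:
        _run_kernel(comp, hold_cmd, dt, vc, protocol.clamp_mode, V, Na, G, False)
    else:
        for ti in range(n_settle):
            if vc:
                V, Na, G, _ = _step_vclamp(comp, V, Na, G, hold_cmd[:, ti],
                                           hold_cmd[:, ti + 1], dt,
                                           protocol.clamp_mode)
            else:
                V, Na, G = _step_cclamp(comp, V, Na, G, hold_cmd[:, ti + 1], dt)

    V = np.repeat(V, S, axis=0)
    Na = np.repeat(Na, S, axis=0)
    G = np.repeat(G, S, axis=0)

    rec_keys = protocol.record
    want_ch = ("i_kcnt1" in rec_keys) or ("i_na_ch" in rec_keys)

    if use_kernel:
        bad_sweep, bad_step, out_v, out_na, out_i, out_ik, out_ina = \
            _run_kernel(comp, cmd, dt, vc, protocol.clamp_mode, V, Na, G,
                        want_ch)
        if bad_sweep >= 0:
            raise IntegrationError(
                f"voltage diverged (|V| > 200 mV) in sweep {bad_sweep} "
                f"at t = {time_ms[bad_step]:.3f} ms")
    else:
        out_v = np.empty((S, n_steps + 1))
        out_na = np.empty((S, n_steps + 1))
        out_i = np.zeros((S, n_steps + 1))
        out_ik = np.zeros((S, n_steps + 1))
        out_ina = np.zeros((S, n_steps + 1))

        def log(ti, i_clamp_pA=None):
            out_v[:, ti] = V[:, comp.soma]
            out_na[:, ti] = Na[:, comp.soma]
            if i_clamp_pA is not None:
                out_i[:, ti] = i_clamp_pA
            if want_ch:
                gd = comp.conductances(G)  # S/cm²
                i_ch = gd * (V[:, comp.ch_comp] - comp.ch_erev)  # mA/cm²
                i_ch_pA = i_ch * comp.area[comp.ch_comp] * 1e9
                out_ik[:, ti] = i_ch_pA[:, comp.ch_is_kcnt1].sum(axis=1)
                out_ina[:, ti] = i_ch_pA[:, comp.ch_carries_na].sum(axis=1)

        log(0, i_clamp_pA=np.zeros(S))
        for ti in range(n_steps):
            if vc:
                V, Na, G, i_clamp_nA = _step_vclamp(
                    comp, V, Na, G, cmd[:, ti], cmd[:, ti + 1], dt,
                    protocol.clamp_mode)
                log(ti + 1, i_clamp_pA=i_clamp_nA * 1e3)
            else:
                V, Na, G = _step_cclamp(comp, V, Na, G, cmd[:, ti + 1], dt)
                log(ti + 1)
            vmax = np.abs(V).max()
            if not np.isfinite(vmax) or vmax > 200.0:
                bad = int(np.abs(V).max(axis=1).argmax())
                raise IntegrationError(
                    f"voltage diverged (|V| > 200 mV) in sweep {bad} "
                    f"at t = {time_ms[ti + 1]:.3f} ms")
        if want_ch:
            out_ik[:, 0] = out_ik[:, 1]
            out_ina[:, 0] = out_ina[:, 1]

    out = {}
    if "v" in rec_keys:
        out["v"] = out_v
    if "na" in rec_keys:
        out["na"] = out_na
    if "i" in rec_keys:
        out["i"] = out_i if vc else cmd
    if "i_kcnt1" in rec_keys:
        out["i_kcnt1"] = out_ik
    if "i_na_ch" in rec_keys:
        out["i_na_ch"] = out_ina
    if vc and "command" in rec_keys:
        out["command"] = cmd

    if protocol.decimate_khz:
        stride = max(int(round(1.0 / (protocol.decimate_khz * dt))), 1)
        time_ms = time_ms[::stride]
        out = {k: v[:, ::stride] for k, v in out.items()}

    max_dur = max(s.duration_ms for s in protocol.sweeps)
    return Recording(
        time_ms=time_ms,
        traces=out,
        stim_onset_ms=protocol.pre_ms,
        stim_dur_ms=max_dur,
        amplitudes=protocol.amplitudes(),
        mode=protocol.mode,
        holding=protocol.holding,
        dt_ms=dt * (stride if protocol.decimate_khz else 1),
        provenance={
            "model_hash": _model_hash(neuron),
            "subtype": neuron.subtype,
            "blockers": [(b.drug, b.fraction_blocked) for b in blockers],
            "clamp_mode": protocol.clamp_mode,
        },
    )


def _advance_gates_and_na(comp: _Compiled, V, Na, G, dt):
    tgt = comp.gate_targets(V, Na)
    tau = comp.gate_taus(V)
    with np.errstate(divide="ignore"):
        f = -np.expm1(-dt / tau)
    f = np.where(tau <= 0.0, 1.0, f)
    G = G + (tgt - G) * f

    pool = comp.na_pool
    if pool.clamp_to_mM is not None:
        Na = np.full_like(Na, pool.clamp_to_mM)
        return G, Na
    gd = comp.conductances(G)
    i_ch = gd * (V[:, comp.ch_comp] - comp.ch_erev)  # mA/cm²
    i_na = np.zeros_like(V)
    mask = comp.ch_carries_na
    if mask.any():
        np.add.at(i_na.T, comp.ch_comp[mask], i_ch[:, mask].T)
    influx = -i_na * 1.0e4 / (FARADAY_C_PER_MOL * pool.depth_um)  # mM/ms
    na_inf = pool.na_rest_mM + influx * pool.tau_na_ms
    Na = na_inf + (Na - na_inf) * np.exp(-dt / pool.tau_na_ms)
    np.maximum(Na, 0.0, out=Na)
    return G, Na


def _membrane_terms(comp: _Compiled, V, G):
    """Total membrane conductance (µS) and g·E (nA) per compartment."""
    gd = comp.conductances(G)  # S/cm²
    g_uS = gd * comp.area[comp.ch_comp] * 1e6
    Gm = np.zeros_like(V)
    GmE = np.zeros_like(V)
    np.add.at(Gm.T, comp.ch_comp, g_uS.T)
    np.add.at(GmE.T, comp.ch_comp, (g_uS * comp.ch_erev).T)
    return Gm, GmE


def _step_cclamp(comp: _Compiled, V, Na, G, inj_pA, dt):
    G, Na = _advance_gates_and_na(comp, V, Na, G, dt)
    Gm, GmE = _membrane_terms(comp, V, G)
    S, n = V.shape
    Cdt = comp.c_nF / dt
    Iinj = np.zeros_like(V)
    Iinj[:, comp.soma] = np.asarray(inj_pA) * 1e-3  # pA → nA

    M = np.broadcast_to(-0.5 * comp.A, (S, n, n)).copy()
    M[:, np.arange(n), np.arange(n)] += Cdt + 0.5 * Gm
    b = (Cdt * V + 0.5 * (-(Gm * V) + V @ comp.A.T) + GmE + Iinj)
    V_new = np.linalg.solve(M, b[..., None])[..., 0]
    return V_new, Na, G


def _step_vclamp(comp: _Compiled, V, Na, G, cmd_now, cmd_next, dt, clamp_mode):
    G, Na = _advance_gates_and_na(comp, V, Na, G, dt)
    Gm, GmE = _membrane_terms(comp, V, G)
    S, n = V.shape
    cmd_now = np.asarray(cmd_now, dtype=float)
    cmd_next = np.asarray(cmd_next, dtype=float)

    if clamp_mode == "space":
        V_new = np.repeat(cmd_next[:, None], n, axis=1)
        i_ion = (Gm * V_new - GmE).sum(axis=1)  # nA
        i_cap = comp.c_nF.sum() * (cmd_next - cmd_now) / dt
        return V_new, Na, G, i_ion + i_cap

    Cdt = comp.c_nF / dt
    M = np.broadcast_to(-0.5 * comp.A, (S, n, n)).copy()
    M[:, np.arange(n), np.arange(n)] += Cdt + 0.5 * Gm
    b = (Cdt * V + 0.5 * (-(Gm * V) + V @ comp.A.T) + GmE)
    # Dirichlet condition at the soma: V_soma = command.
    M[:, comp.soma, :] = 0.0
    M[:, comp.soma, comp.soma] = 1.0
    b[:, comp.soma] = cmd_next
    V_new = np.linalg.solve(M, b[..., None])[..., 0]

    s = comp.soma
    axial_in = (V_new @ comp.A.T)[:, s]  # nA into the soma
    i_ion_soma = Gm[:, s] * V_new[:, s] - GmE[:, s]
    i_cap = comp.c_nF[s] * (cmd_next - cmd_now) / dt
    i_clamp = i_cap + i_ion_soma - axial_in
    return V_new, Na, G, i_clamp


# ---------------------------------------------------------------------------
# Protocol builders


def make_current_step_protocol(variant: str = "culture",
                               max_pA: float = 400.0,
                               dt_ms: float = 0.025,
                               record: Iterable[str] = ("v", "i", "na"),
                               ) -> Protocol:
    """Current-clamp step family.

    ``culture``: 500 ms pulses from −100 pA in 20 pA increments;
    ``slice``: 1 s pulses from −30 pA in 5 pA increments.  Sweeps ascend
    to ``max_pA``.
    """
    if variant == "culture":
        start, inc, dur = -100.0, 20.0, 500.0
    elif variant == "slice":
        start, inc, dur = -30.0, 5.0, 1000.0
    else:
        raise ValueError(f"unknown variant {variant!r}")
    amps = np.arange(start, max_pA + inc / 2, inc)
    sweeps = tuple(Stimulus(kind="step", amplitude=a, duration_ms=dur)
                   for a in amps)
    return Protocol(mode="current_clamp", holding=0.0, sweeps=sweeps,
                    dt_ms=dt_ms, pre_ms=100.0, post_ms=300.0,
                    record=tuple(record))


def make_voltage_step_protocol(dt_ms: float = 0.025,
                               clamp_mode: str = "space",
                               record: Iterable[str] = ("v", "i", "na",
                                                        "i_kcnt1", "command"),
                               ) -> Protocol:
    """K_Na measurement family: hold −70 mV, 1 s steps −80 … +50 mV."""
    amps = np.arange(-80.0, 50.0 + 5.0, 10.0)
    sweeps = tuple(Stimulus(kind="step", amplitude=a, duration_ms=1000.0)
                   for a in amps)
    return Protocol(mode="voltage_clamp", holding=-70.0, sweeps=sweeps,
                    dt_ms=dt_ms, pre_ms=100.0, post_ms=200.0,
                    clamp_mode=clamp_mode, record=tuple(record))


def make_ramp_protocol(n_sweeps: int = 1, dt_ms: float = 0.025,
                       clamp_mode: str = "space",
                       record: Iterable[str] = ("v", "i", "na", "command"),
                       ) -> Protocol:
    """I_NaP isolation ramp: hold −80 mV, +20 mV/s for 5 s, every 10 s."""
    sweeps = tuple(Stimulus(kind="ramp", duration_ms=5000.0,
                            ramp_rate_mV_per_s=20.0)
                   for _ in range(n_sweeps))
    return Protocol(mode="voltage_clamp", holding=-80.0, sweeps=sweeps,
                    dt_ms=dt_ms, pre_ms=100.0, post_ms=100.0,
                    inter_sweep_s=5.0, clamp_mode=clamp_mode,
                    record=tuple(record))
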