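"""Membrane conductance definitions and gating mathematics.

The central object is the KCNT1 (Slack) sodium-activated potassium
conductance: a Hodgkin–Huxley-style channel whose open probability is the
product of an instantaneous Hill-type gate driven by intracellular Na⁺ and
a Boltzmann voltage gate that relaxes mono-exponentially toward its steady
state.  Gain-of-function (GOF) variants are modelled as an increase in Na⁺
sensitivity, i.e. a reduction of the Hill gate's EC50 from its wild-type
value of 40 mM to 35 or 30 mM.

The same gate machinery also describes the transient Na⁺ current (m³h),
the persistent Na⁺ current (I_NaP, a single non-inactivating activation
gate), and the delayed-rectifier K⁺ current, so one integrator serves the
whole channel library.  A submembrane Na⁺ pool converts Na⁺-carrying
current density into the concentration seen by the KCNT1 Hill gate.

Units follow the slicer-room conventions used throughout the package:
voltages in mV, time in ms, concentrations in mM, conductance densities in
S/cm² and current densities in mA/cm² (outward positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Optional

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .neurons import NeuronModel

__all__ = [
    "GateSpec",
    "ChannelSpec",
    "NaPoolParams",
    "hill_open_fraction",
    "boltzmann_open_fraction",
    "relax_gate",
    "gate_steady_state",
    "gate_tau",
    "kcnt1_current_density",
    "apply_gof",
    "set_inap_density",
    "step_na_pool",
    "kcnt1_spec",
    "nat_spec",
    "nap_spec",
    "kdr_spec",
    "leak_spec",
    "GOF_EC50_MM",
    "FARADAY_C_PER_MOL",
    "KCNT1",
    "NA_T",
    "NA_P",
    "K_DR",
    "LEAK",
]

# Canonical channel names used across the package.
KCNT1 = "kcnt1"
NA_T = "na_t"
NA_P = "na_p"
K_DR = "k_dr"
LEAK = "leak"

FARADAY_C_PER_MOL = 96485.332

#: EC50 of the KCNT1 Na⁺ gate per genotype level. ``wt`` is the wild-type
#: sensitivity; the two GOF levels mimic increased Na⁺ sensitivity of the
#: pathogenic variant.
GOF_EC50_MM = {"wt": 40.0, "gof35": 35.0, "gof30": 30.0}


@dataclass(frozen=True)
class GateSpec:
    """One multiplicative gating variable of a conductance.

    ``kind`` selects the steady-state law:

    ``hill_na``
        Hill function of intracellular Na⁺:
        ``na^h / (na^h + ec50^h)`` with midpoint ``ec50_mM`` and Hill
        coefficient ``hill_coef``.
    ``boltzmann_v``
        Boltzmann function of membrane voltage:
        ``1 / (1 + exp(-(v - v50)/slope))``.  A positive ``slope_mV``
        gives an activating gate, a negative one an inactivating gate.

    ``tau_ms`` is the relaxation time constant toward steady state; 0
    means the gate is instantaneous.  For Hodgkin–Huxley-style gates the
    time constant may additionally be voltage dependent, modelled as a
    Gaussian bump ``tau(v) = tau_ms + tau_amp_ms * exp(-((v -
    tau_vpeak_mV)/tau_sigma_mV)^2)`` — sufficient to shape spike width,
    refractoriness and recovery without rate equations.

    ``power`` is the exponent of the gate in the open probability
    (e.g. 3 for the m³ activation of the transient Na⁺ current).
    """

    kind: str
    ec50_mM: float = 0.0
    hill_coef: float = 0.0
    v50_mV: float = 0.0
    slope_mV: float = 0.0
    tau_ms: float = 0.0
    tau_amp_ms: float = 0.0
    tau_vpeak_mV: float = 0.0
    tau_sigma_mV: float = 20.0
    power: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("hill_na", "boltzmann_v"):
            raise ValueError(f"unknown gate kind {self.kind!r}")
        if self.kind == "hill_na":
            if self.ec50_mM <= 0:
                raise ValueError("hill_na gate requires ec50_mM > 0")
            if self.hill_coef <= 0:
                raise ValueError("hill_na gate requires hill_coef > 0")
        else:
            if self.slope_mV == 0:
                raise ValueError("boltzmann_v gate requires slope_mV != 0")
        if self.tau_ms < 0 or self.tau_amp_ms < 0:
            raise ValueError("time constants must be non-negative")
        if self.power < 1:
            raise ValueError("gate power must be >= 1")


@dataclass(frozen=True)
class ChannelSpec:
    """A membrane conductance: maximal density, reversal and gate list.

    ``carries_na`` marks channels whose current feeds the submembrane Na⁺
    pool (the transient and persistent Na⁺ currents).  ``blockable_by``
    names the virtual drugs that remove the conductance: TTX for both Na⁺
    currents, VU170 for KCNT1.
    """

    name: str
    gbar_S_per_cm2: float
    e_rev_mV: float
    gates: tuple[GateSpec, ...] = ()
    carries_na: bool = False
    blockable_by: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.gbar_S_per_cm2 < 0:
            raise ValueError("gbar must be non-negative")
        object.__setattr__(self, "gates", tuple(self.gates))
        object.__setattr__(self, "blockable_by", frozenset(self.blockable_by))

    def gate_of_kind(self, kind: str) -> GateSpec:
        for g in self.gates:
            if g.kind == kind:
                return g
        raise ValueError(f"channel {self.name!r} has no {kind} gate")

    def has_gate_kind(self, kind: str) -> bool:
        return any(g.kind == kind for g in self.gates)


@dataclass(frozen=True)
class NaPoolParams:
    """Submembrane Na⁺ shell converting Na⁺ current into concentration.

    d[Na]/dt = -i_Na/(F·depth) - ([Na] - na_rest)/tau_na.  ``clamp_to_mM``
    pins the concentration (dynamics disabled); the 10 mM and 0 mM
    fixed-concentration verification runs use this mode.
    """

    na_rest_mM: float = 10.0
    tau_na_ms: float = 300.0
    depth_um: float = 0.3
    clamp_to_mM: Optional[float] = None

    def __post_init__(self) -> None:
        if self.na_rest_mM < 0:
            raise ValueError("na_rest_mM must be >= 0")
        if self.tau_na_ms <= 0:
            raise ValueError("tau_na_ms must be > 0")
        if self.depth_um <= 0:
            raise ValueError("depth_um must be > 0")


def hill_open_fraction(na_mM, ec50_mM: float, hill_coef: float):
    """Steady-state open fraction of the Na⁺ gate.

    ``na^h / (na^h + ec50^h)``; 0.5 at the EC50 and strictly increasing
    in [Na⁺].  Accepts scalars or arrays of concentration.
    """
    na = np.asarray(na_mM, dtype=float)
    if np.any(na < 0):
        raise ValueError("Na+ concentration must be non-negative")
    if ec50_mM <= 0:
        raise ValueError("ec50_mM must be positive")
    if hill_coef <= 0:
        raise ValueError("hill_coef must be positive")
    # (na/ec50)^h form avoids overflow for large concentrations.
    r = np.power(na / ec50_mM, hill_coef)
    out = r / (r + 1.0)
    return float(out) if np.isscalar(na_mM) else out


def boltzmann_open_fraction(v_mV, v50_mV: float, slope_mV: float):
    """Steady-state open fraction of the voltage gate.

    ``1 / (1 + exp(-(v - v50)/slope))``; 0.5 at V50.  ``slope_mV`` > 0
    activates with depolarization, < 0 inactivates.
    """
    if slope_mV == 0:
        raise ValueError("slope_mV must be non-zero")
    v = np.asarray(v_mV, dtype=float)
    out = 1.0 / (1.0 + np.exp(-(v - v50_mV) / slope_mV))
    return float(out) if np.isscalar(v_mV) else out


def relax_gate(current, target, tau_ms: float, dt_ms: float):
    """Exact mono-exponential relaxation of a gate over one time step.

    Returns ``target`` for an instantaneous gate (tau = 0); otherwise the
    closed-form update ``current + (target - current)·(1 - e^(-dt/tau))``,
    which makes the integration of the gate ODE exact for any dt.
    """
    if dt_ms < 0:
        raise ValueError("dt_ms must be >= 0")
    if tau_ms < 0:
        raise ValueError("tau_ms must be >= 0")
    if tau_ms == 0.0:
        return target
    f = -np.expm1(-dt_ms / tau_ms)
    return current + (np.asarray(target) - current) * f


def gate_steady_state(gate: GateSpec, v_mV, na_mM):
    """Steady-state open fraction of ``gate`` at the given state."""
    if gate.kind == "hill_na":
        return hill_open_fraction(na_mM, gate.ec50_mM, gate.hill_coef)
    return boltzmann_open_fraction(v_mV, gate.v50_mV, gate.slope_mV)


def gate_tau(gate: GateSpec, v_mV):
    """Relaxation time constant of ``gate`` at voltage ``v_mV`` (ms)."""
    if gate.tau_amp_ms == 0.0:
        return gate.tau_ms if np.isscalar(v_mV) else np.full_like(
            np.asarray(v_mV, dtype=float), gate.tau_ms)
    v = np.asarray(v_mV, dtype=float)
    tau = gate.tau_ms + gate.tau_amp_ms * np.exp(
        -(((v - gate.tau_vpeak_mV) / gate.tau_sigma_mV) ** 2))
    return float(tau) if np.isscalar(v_mV) else tau


def kcnt1_current_density(v_mV, a_na, a_v, spec: ChannelSpec):
    """KCNT1 current density in mA/cm² (outward positive).

    Ohmic product ``gbar · a_na · a_v · (v - e_rev)`` with the two gate
    open fractions supplied explicitly; S/cm² × mV = mA/cm².
    """
    a_na = np.asarray(a_na, dtype=float)
    a_v = np.asarray(a_v, dtype=float)
    if np.any((a_na < 0) | (a_na > 1)) or np.any((a_v < 0) | (a_v > 1)):
        raise ValueError("gate fractions must lie in [0, 1]")
    out = spec.gbar_S_per_cm2 * a_na * a_v * (np.asarray(v_mV, float) - spec.e_rev_mV)
    return float(out) if np.isscalar(v_mV) and a_na.ndim == 0 and a_v.ndim == 0 else out


def apply_gof(spec: ChannelSpec, level: str) -> ChannelSpec:
    """Return a copy of a KCNT1 spec at the given genotype level.

    ``level`` is one of ``wt`` (EC50 = 40 mM), ``gof35`` (35 mM) or
    ``gof30`` (30 mM); only the Hill gate's EC50 changes.
    """
    if level not in GOF_EC50_MM:
        raise ValueError(f"unknown GOF level {level!r}; expected one of {sorted(GOF_EC50_MM)}")
    if not spec.has_gate_kind("hill_na"):
        raise ValueError(f"channel {spec.name!r} has no hill_na gate to modify")
    new_gates = tuple(
        replace(g, ec50_mM=GOF_EC50_MM[level]) if g.kind == "hill_na" else g
        for g in spec.gates
    )
    return replace(spec, gates=new_gates)


def set_inap_density(neuron: "NeuronModel", scale: float) -> "NeuronModel":
    """Set the persistent Na⁺ conductance relative to the transient one.

    In every compartment carrying the transient Na⁺ current the
    persistent-current density becomes ``scale × 0.001 × g_NaT``:
    scale = 1 is the control condition, scale = 2 the twofold increase
    used to probe the rescue of fast-spiking excitability, scale = 0
    removes I_NaP.
    """
    if scale < 0:
        raise ValueError("scale must be non-negative")
    new_comps = {}
    touched = False
    for cid, comp in neuron.compartments.items():
        if NA_T in comp.channels:
            ch = dict(comp.channels)
            g = scale * 0.001 * ch[NA_T]
            if scale == 0.0:
                ch.pop(NA_P, None)
            else:
                ch[NA_P] = g
            new_comps[cid] = replace(comp, channels=ch)
            touched = True
        else:
            new_comps[cid] = comp
    if not touched:
        raise ValueError("neuron has no transient Na+ channel to scale I_NaP against")
    lib = dict(neuron.channel_library)
    if scale > 0 and NA_P not in lib:
        lib[NA_P] = nap_spec()
    return replace(neuron, compartments=new_comps, channel_library=lib)


def step_na_pool(
    na_mM: float,
    i_na_density_mA_cm2: float,
    params: NaPoolParams,
    dt_ms: float,
    depth_um: Optional[float] = None,
):
    """Advance the submembrane Na⁺ concentration by one time step.

    Influx is the inward Na⁺ current converted to a concentration rate in
    the shell of depth ``depth_um``; removal relaxes back to rest with
    ``tau_na_ms``.  The linear ODE is integrated with its exact
    exponential solution, and the result is floored at zero.  In clamped
    mode the configured concentration is returned unchanged.
    """
    if dt_ms < 0:
        raise ValueError("dt_ms must be >= 0")
    if params.clamp_to_mM is not None:
        return params.clamp_to_mM
    depth = params.depth_um if depth_um is None else depth_um
    # mA/cm² → mM/ms in a shell of `depth` µm: factor 1e4/(F·depth_um).
    influx = -i_na_density_mA_cm2 * 1.0e4 / (FARADAY_C_PER_MOL * depth)
    na_inf = params.na_rest_mM + influx * params.tau_na_ms
    decay = np.exp(-dt_ms / params.tau_na_ms)
    out = na_inf + (na_mM - na_inf) * decay
    return np.maximum(out, 0.0)


# ---------------------------------------------------------------------------
# Channel library builders


def kcnt1_spec(
    v50_mV: float,
    slope_mV: float,
    tau_v_ms: float = 5.0,
    gbar_S_per_cm2: float = 0.03,
    e_rev_mV: float = -90.0,
    ec50_mM: float = 40.0,
    hill_coef: float = 3.5,
) -> ChannelSpec:
    """KCNT1 K_Na conductance: Hill Na⁺ gate × Boltzmann voltage gate.

    Defaults carry the wild-type Na⁺ sensitivity (EC50 = 40 mM, Hill
    slope 3.5) and the standard insertion density of 0.03 S/cm².  The
    Na⁺ gate is instantaneous; the voltage gate relaxes with the
    patch-measured onset time constant ``tau_v_ms``.  V50 and slope are
    per-neuron-type calibration parameters.
    """
    return ChannelSpec(
        name=KCNT1,
        gbar_S_per_cm2=gbar_S_per_cm2,
        e_rev_mV=e_rev_mV,
        gates=(
            GateSpec(kind="hill_na", ec50_mM=ec50_mM, hill_coef=hill_coef, tau_ms=0.0),
            GateSpec(kind="boltzmann_v", v50_mV=v50_mV, slope_mV=slope_mV, tau_ms=tau_v_ms),
        ),
        carries_na=False,
        blockable_by=frozenset({"VU170"}),
    )


def nat_spec(
    gbar_S_per_cm2: float = 0.05,
    m_v50_mV: float = -32.0,
    m_slope_mV: float = 6.0,
    h_v50_mV: float = -55.0,
    h_slope_mV: float = -7.0,
    h_tau_min_ms: float = 0.4,
    h_tau_amp_ms: float = 6.0,
    h_tau_vpeak_mV: float = -60.0,
    h_tau_sigma_mV: float = 18.0,
    e_rev_mV: float = 55.0,
) -> ChannelSpec:
    """Transient Na⁺ current, m³h with near-instantaneous activation."""
    return ChannelSpec(
        name=NA_T,
        gbar_S_per_cm2=gbar_S_per_cm2,
        e_rev_mV=e_rev_mV,
        gates=(
            GateSpec(kind="boltzmann_v", v50_mV=m_v50_mV, slope_mV=m_slope_mV,
                     tau_ms=0.05, power=3),
            GateSpec(kind="boltzmann_v", v50_mV=h_v50_mV, slope_mV=h_slope_mV,
                     tau_ms=h_tau_min_ms, tau_amp_ms=h_tau_amp_ms,
                     tau_vpeak_mV=h_tau_vpeak_mV, tau_sigma_mV=h_tau_sigma_mV),
        ),
        carries_na=True,
        blockable_by=frozenset({"TTX"}),
    )


def nap_spec(
    gbar_S_per_cm2: float = 0.0,
    v50_mV: float = -50.0,
    slope_mV: float = 5.0,
    e_rev_mV: float = 55.0,
) -> ChannelSpec:
    """Persistent (non-inactivating) Na⁺ current, single activation gate.

    The density is set per compartment as a fraction of the transient
    Na⁺ conductance (see :func:`set_inap_density`), so the channel-level
    gbar defaults to 0; the per-compartment density is authoritative.
    """
    return ChannelSpec(
        name=NA_P,
        gbar_S_per_cm2=gbar_S_per_cm2,
        e_rev_mV=e_rev_mV,
        gates=(
            GateSpec(kind="boltzmann_v", v50_mV=v50_mV, slope_mV=slope_mV, tau_ms=1.0),
        ),
        carries_na=True,
        blockable_by=frozenset({"TTX"}),
    )


def kdr_spec(
    gbar_S_per_cm2: float = 0.03,
    n_v50_mV: float = -30.0,
    n_slope_mV: float = 9.0,
    n_tau_min_ms: float = 0.6,
    n_tau_amp_ms: float = 2.0,
    n_tau_vpeak_mV: float = -50.0,
    n_tau_sigma_mV: float = 25.0,
    e_rev_mV: float = -90.0,
) -> ChannelSpec:
    """Delayed-rectifier K⁺ current, n² activation."""
    return ChannelSpec(
        name=K_DR,
        gbar_S_per_cm2=gbar_S_per_cm2,
        e_rev_mV=e_rev_mV,
        gates=(
            GateSpec(kind="boltzmann_v", v50_mV=n_v50_mV, slope_mV=n_slope_mV,
                     tau_ms=n_tau_min_ms, tau_amp_ms=n_tau_amp_ms,
                     tau_vpeak_mV=n_tau_vpeak_mV, tau_sigma_mV=n_tau_sigma_mV,
                     power=2),
        ),
    )


def leak_spec(gbar_S_per_cm2: float = 1.0e-4, e_rev_mV: float = -70.0) -> ChannelSpec:
    """Ohmic leak conductance."""
    return ChannelSpec(name=LEAK, gbar_S_per_cm2=gbar_S_per_cm2, e_rev_mV=e_rev_mV)
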