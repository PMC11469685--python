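"""Trace measurements: passive properties, AP features, subtraction currents.

Every measurement follows the whole-cell patch-clamp definitions used
throughout the package:

* resting potential from a 50-ms average before current injection; input
  resistance from the regression of steady-state voltage deflection
  against injected current over the hyperpolarizing steps (steady state =
  mean over the last 100 ms of the step); membrane time constant from a
  single-exponential fit over 200 ms after stimulus offset; capacitance =
  τ / R_in;
* AP threshold at the inflection point of the rising phase,
  operationalized as the first sample where dV/dt exceeds a criterion
  (default 20 mV/ms); amplitude = peak − threshold; half-width at
  half-maximal amplitude; AHP = threshold − minimum V within 50 ms after
  the peak;
* rheobase as the smallest step current evoking at least one AP;
* fast-spiking (FS) classification when the maximum mean firing rate
  exceeds 60 Hz and AP half-width broadens by less than 25% during
  sustained firing, non-fast-spiking (NFS) otherwise;
* drug-subtraction I–V curves averaged over the final 100 ms of each
  voltage step, Boltzmann fits of the derived conductance, and the
  slow-ramp persistent-Na⁺ difference current binned at 5 mV intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .simulate import Recording

__all__ = [
    "PassiveProperties",
    "APFeatures",
    "FICurve",
    "IVCurve",
    "ActivationFit",
    "OnsetFit",
    "MissingDataError",
    "FitError",
    "ProtocolMismatchError",
    "passive_properties",
    "detect_aps",
    "ap_features",
    "rheobase",
    "fi_curve_and_class",
    "subtraction_iv",
    "fit_activation",
    "fit_exponential_onset",
    "inap_iv",
]


class MissingDataError(ValueError):
    """The recording lacks the sweeps a measurement requires."""


class FitError(RuntimeError):
    """A least-squares fit failed to converge or is degenerate."""


class ProtocolMismatchError(ValueError):
    """Two recordings that must share a protocol do not."""


@dataclass(frozen=True)
class PassiveProperties:
    v_rest_mV: float
    r_in_MOhm: float
    tau_ms: float
    cm_pF: float


@dataclass(frozen=True)
class APFeatures:
    spike_time_ms: float
    threshold_mV: float
    peak_mV: float
    amplitude_mV: float
    half_width_ms: float
    ahp_mV: float
    valid: bool = True


@dataclass(frozen=True)
class FICurve:
    amplitudes_pA: np.ndarray
    counts: np.ndarray
    rates_Hz: np.ndarray

    @property
    def max_rate_Hz(self) -> float:
        return float(self.rates_Hz.max()) if len(self.rates_Hz) else 0.0


@dataclass(frozen=True)
class IVCurve:
    voltages_mV: np.ndarray
    current: np.ndarray
    dispersion: Optional[np.ndarray] = None
    normalization: str = "raw_pA"  # 'raw_pA' | 'pA_per_pF'
    peak_negative: Optional[float] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages_mV, dtype=float)
        if np.any(np.diff(v) <= 0):
            raise ValueError("voltages must be strictly increasing")
        if len(v) != len(self.current):
            raise ValueError("voltage and current lengths must match")


@dataclass(frozen=True)
class ActivationFit:
    v50_mV: float
    slope_mV: float
    gmax: float
    fit_rms: float


@dataclass(frozen=True)
class OnsetFit:
    tau_ms: float
    rms: float


# ---------------------------------------------------------------------------


def _stim_window(rec: Recording):
    t = rec.time_ms
    on = rec.stim_onset_ms
    off = on + rec.stim_dur_ms
    return t, on, off


def passive_properties(family: Recording, steady_ms: float = 100.0,
                       fit_ms: float = 200.0) -> PassiveProperties:
    """Passive membrane properties from a current-clamp step family.

    Uses every hyperpolarizing sweep: V_rest from the 50 ms before
    stimulus onset, R_in from the regression of steady-state deflection
    on injected current, τ from a single-exponential fit of the voltage
    relaxation over ``fit_ms`` after stimulus offset (most hyperpolarized
    sweep), and C_m = τ / R_in.
    """
    if family.mode != "current_clamp":
        raise MissingDataError("passive properties need a current-clamp family")
    t, on, off = _stim_window(family)
    hyp = np.where(family.amplitudes < 0)[0]
    if len(hyp) == 0:
        raise MissingDataError("no hyperpolarizing sweeps in family")

    pre = (t >= on - 50.0) & (t < on)
    ss = (t >= off - steady_ms) & (t < off)
    v = family.traces["v"]
    v_rest = float(np.mean(v[:, pre]))
    dv = v[hyp][:, ss].mean(axis=1) - v[hyp][:, pre].mean(axis=1)
    amps = family.amplitudes[hyp]
    if len(hyp) == 1:
        r_gohm = float(dv[0] / amps[0])
    else:
        r_gohm = float(np.polyfit(amps, dv, 1)[0])  # mV/pA = GΩ
    r_in = r_gohm * 1e3  # MΩ
    if r_in <= 0:
        raise MissingDataError("non-positive input resistance; family unusable")

    # τ from the relaxation after stimulus offset.  For a linear membrane
    # the decay scales with the step amplitude, so all hyperpolarizing
    # sweeps are pooled (amplitude-weighted regression at each sample)
    # before the single-exponential fit; this keeps the estimate stable on
    # low-resistance cells where a single sweep's decay is barely above
    # the noise floor.
    m = (t >= off) & (t < off + fit_ms)
    ts = t[m] - off
    decays = v[hyp][:, m] - v_rest
    a_ref = amps[np.argmin(amps)]
    vs = v_rest + (decays * amps[:, None]).sum(axis=0) \
        / np.sum(amps ** 2) * a_ref

    def expdec(x, a, b, tau):
        return a + b * np.exp(-x / tau)

    try:
        p0 = (vs[-1], vs[0] - vs[-1], max((ts[-1] - ts[0]) / 5.0, 1.0))
        popt, _ = curve_fit(expdec, ts, vs, p0=p0, maxfev=5000,
                            bounds=([-150.0, -500.0, 0.01],
                                    [100.0, 500.0, 1000.0]))
    except (RuntimeError, ValueError) as e:
        raise FitError(f"membrane time-constant fit failed: {e}") from None
    tau = float(abs(popt[2]))
    cm_pF = tau / r_in * 1e3  # ms/MΩ = nF → pF
    return PassiveProperties(v_rest_mV=v_rest, r_in_MOhm=r_in, tau_ms=tau,
                             cm_pF=cm_pF)


def detect_aps(trace: np.ndarray, time_ms: np.ndarray,
               dvdt_threshold: float = 20.0, peak_min_mV: float = -10.0,
               merge_ms: float = 2.0) -> np.ndarray:
    """Detect action potentials in a voltage trace.

    One event per upward crossing of dV/dt ≥ ``dvdt_threshold`` (mV/ms)
    that is followed by a voltage peak above ``peak_min_mV`` within 10 ms;
    crossings closer than ``merge_ms`` are merged.  Returns the crossing
    times in ms.
    """
    trace = np.asarray(trace, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    dt = time_ms[1] - time_ms[0]
    dvdt = np.diff(trace) / dt
    above = dvdt >= dvdt_threshold
    crossings = np.where(above & ~np.concatenate(([False], above[:-1])))[0]
    win = max(int(round(10.0 / dt)), 2)
    # associate each crossing with the first subsequent local maximum above
    # the peak criterion; several crossings pointing at the same peak (noise
    # wobble on the approach to a spike) collapse to the latest one, which
    # is the actual upstroke
    peak_of: dict[int, int] = {}
    for idx in crossings:
        stop = min(idx + win, len(trace) - 1)
        pk = -1
        for j in range(idx + 1, stop):
            if (trace[j] >= peak_min_mV and trace[j] >= trace[j - 1]
                    and trace[j] >= trace[j + 1]):
                pk = j
                break
        if pk < 0 and stop == len(trace) - 1 and trace[stop] >= peak_min_mV:
            pk = stop  # rising edge clipped at trace end
        if pk >= 0:
            peak_of[pk] = idx  # later crossings overwrite earlier ones
    events = []
    last = -np.inf
    for pk in sorted(peak_of):
        tc = time_ms[peak_of[pk]]
        if tc - last < merge_ms:
            continue
        events.append(tc)
        last = tc
    return np.array(events)


def ap_features(trace: np.ndarray, time_ms: np.ndarray, spike_time_ms: float,
                dvdt_threshold: float = 20.0, ahp_window_ms: float = 50.0,
                ) -> APFeatures:
    """Shape features of one detected AP.

    Threshold is the voltage at the detection crossing; the peak is the
    first local maximum after it; half-width is measured at threshold +
    amplitude/2 with linear interpolation of the flank crossings; the AHP
    is the drop below threshold within ``ahp_window_ms`` after the peak.
    A waveform clipped by the end of the trace is flagged invalid.
    """
    trace = np.asarray(trace, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    dt = time_ms[1] - time_ms[0]
    i0 = int(np.searchsorted(time_ms, spike_time_ms))
    i0 = min(i0, len(trace) - 1)
    threshold = float(trace[i0])

    win = max(int(round(10.0 / dt)), 2)
    seg = trace[i0:i0 + win]
    ipk_rel = int(np.argmax(seg))
    ipk = i0 + ipk_rel
    peak = float(trace[ipk])
    clipped = ipk >= len(trace) - 1
    amplitude = peak - threshold
    half_level = threshold + amplitude / 2.0

    def interp_cross(i_lo, i_hi, level):
        v0, v1 = trace[i_lo], trace[i_hi]
        if v1 == v0:
            return time_ms[i_lo]
        return time_ms[i_lo] + (level - v0) / (v1 - v0) * dt

    # rising flank crossing
    t_rise = None
    for i in range(i0, ipk):
        if trace[i] < half_level <= trace[i + 1]:
            t_rise = interp_cross(i, i + 1, half_level)
            break
    # falling flank crossing
    t_fall = None
    for i in range(ipk, min(ipk + win, len(trace) - 1)):
        if trace[i] >= half_level > trace[i + 1]:
            t_fall = interp_cross(i, i + 1, half_level)
            break
    valid = not clipped and t_rise is not None and t_fall is not None
    half_width = (t_fall - t_rise) if valid else np.nan

    iend = min(ipk + int(round(ahp_window_ms / dt)) + 1, len(trace))
    if iend <= ipk + 1:
        valid = False
        ahp = np.nan
    else:
        vmin = float(np.min(trace[ipk:iend]))
        ahp = threshold - vmin
    return APFeatures(spike_time_ms=float(spike_time_ms), threshold_mV=threshold,
                      peak_mV=peak, amplitude_mV=amplitude,
                      half_width_ms=half_width, ahp_mV=ahp, valid=valid)


def _sweep_spikes(family: Recording, i: int, dvdt_threshold: float):
    t, on, off = _stim_window(family)
    spikes = detect_aps(family.traces["v"][i], t, dvdt_threshold)
    return spikes[(spikes >= on) & (spikes < off)]


def rheobase(family: Recording, dvdt_threshold: float = 20.0,
             ) -> Optional[float]:
    """Minimum step current (pA) evoking at least one AP.

    Sweeps are scanned in order of ascending amplitude; returns None when
    no sweep evokes a spike (not evocable — distinct from 0 pA).
    """
    order = np.argsort(family.amplitudes)
    for i in order:
        if family.amplitudes[i] <= 0:
            continue
        if len(_sweep_spikes(family, i, dvdt_threshold)) > 0:
            return float(family.amplitudes[i])
    return None


def fi_curve_and_class(family: Recording, dvdt_threshold: float = 20.0,
                       rate_threshold_Hz: float = 60.0,
                       broadening_limit: float = 0.25):
    """F–I curve and FS/NFS classification of a step family.

    AP counts per depolarizing step, converted to mean rates over the
    step duration.  FS requires a maximum mean rate above 60 Hz and
    half-width broadening (last vs first AP of the maximal-rate sweep)
    under 25%; all other cells are NFS.
    """
    t, on, off = _stim_window(family)
    dep = np.where(family.amplitudes > 0)[0]
    dur_s = family.stim_dur_ms / 1e3
    amps, counts = [], []
    spikes_per = {}
    for i in dep:
        sp = _sweep_spikes(family, i, dvdt_threshold)
        amps.append(family.amplitudes[i])
        counts.append(len(sp))
        spikes_per[i] = sp
    amps = np.array(amps)
    counts = np.array(counts, dtype=int)
    rates = counts / dur_s
    fi = FICurve(amplitudes_pA=amps, counts=counts, rates_Hz=rates)

    label = "NFS"
    if len(rates) and rates.max() > rate_threshold_Hz:
        imax = dep[int(np.argmax(rates))]
        sp = spikes_per[imax]
        broadening = 0.0
        if len(sp) >= 2:
            v = family.traces["v"][imax]
            f0 = ap_features(v, t, sp[0], dvdt_threshold)
            f1 = ap_features(v, t, sp[-1], dvdt_threshold)
            if f0.valid and f1.valid and f0.half_width_ms > 0:
                broadening = (f1.half_width_ms - f0.half_width_ms) / f0.half_width_ms
        if broadening < broadening_limit:
            label = "FS"
    return fi, label


def subtraction_iv(control: Recording, drug: Recording,
                   window_ms: float = 100.0) -> IVCurve:
    """Drug-subtraction steady-state I–V from paired voltage-step families.

    The drug-condition current is subtracted from the control current
    sweep by sweep; the mean difference over the final ``window_ms`` of
    each voltage pulse is the steady-state drug-sensitive current.
    """
    if control.mode != "voltage_clamp" or drug.mode != "voltage_clamp":
        raise ProtocolMismatchError("subtraction needs two voltage-clamp families")
    if (control.n_sweeps != drug.n_sweeps
            or not np.allclose(control.amplitudes, drug.amplitudes)
            or len(control.time_ms) != len(drug.time_ms)
            or not np.isclose(control.stim_dur_ms, drug.stim_dur_ms)):
        raise ProtocolMismatchError("control and drug protocols differ")
    t, on, off = _stim_window(control)
    m = (t >= off - window_ms) & (t < off)
    diff = control.traces["i"] - drug.traces["i"]
    iv = diff[:, m].mean(axis=1)
    order = np.argsort(control.amplitudes)
    return IVCurve(voltages_mV=control.amplitudes[order], current=iv[order])


def fit_activation(iv: IVCurve, e_rev_mV: float,
                   min_points: int = 5) -> ActivationFit:
    """Boltzmann fit of the conductance derived from a subtraction I–V.

    G(V) = I/(V − E_rev) for steps depolarized from the reversal; the
    normalized conductance is fit with G = gmax / (1 + exp(−(V−V50)/k)).
    """
    v = np.asarray(iv.voltages_mV, dtype=float)
    i = np.asarray(iv.current, dtype=float)
    m = v > e_rev_mV + 5.0
    if m.sum() < min_points:
        raise MissingDataError(
            f"need ≥ {min_points} points depolarized from E_rev, have {int(m.sum())}")
    g = i[m] / (v[m] - e_rev_mV)
    vv = v[m]
    gmax0 = float(np.max(np.abs(g)))
    if gmax0 <= 0 or not np.any(np.abs(g) > 0):
        raise FitError("all-zero conductance; nothing to fit")

    def boltz(x, gmax, v50, k):
        return gmax / (1.0 + np.exp(-(x - v50) / k))

    try:
        popt, _ = curve_fit(boltz, vv, g, p0=(gmax0, np.median(vv), 8.0),
                            maxfev=10000)
    except RuntimeError as e:
        raise FitError(f"activation fit did not converge: {e}") from None
    gmax, v50, k = (float(x) for x in popt)
    if k < 0:  # mirror solution; normalize sign convention
        raise FitError("activation fit converged to a deactivating branch")
    if gmax <= 0:
        raise FitError("activation fit converged to non-positive gmax")
    rms = float(np.sqrt(np.mean((boltz(vv, *popt) - g) ** 2)))
    return ActivationFit(v50_mV=v50, slope_mV=k, gmax=gmax, fit_rms=rms)


def fit_exponential_onset(trace: np.ndarray, time_ms: np.ndarray,
                          reject_rms_frac: float = 0.5) -> OnsetFit:
    """Single-exponential time constant of a current-onset segment.

    Fits ``I(t) = a + b·exp(−t/τ)`` to the supplied onset segment and
    returns τ with the fit RMS.  Raises :class:`FitError` when the
    optimizer fails or the residual exceeds ``reject_rms_frac`` of the
    onset amplitude (pure-noise rejection).
    """
    y = np.asarray(trace, dtype=float)
    t = np.asarray(time_ms, dtype=float) - time_ms[0]
    span = float(y[-1] - y[0])

    def expon(x, a, b, tau):
        return a + b * np.exp(-x / tau)

    try:
        p0 = (y[-1], -span, max(t[-1] / 5.0, 1e-3))
        popt, _ = curve_fit(expon, t, y, p0=p0, maxfev=10000,
                            bounds=([-np.inf, -np.inf, 1e-3],
                                    [np.inf, np.inf, 1e6]))
    except (RuntimeError, ValueError) as e:
        raise FitError(f"onset fit did not converge: {e}") from None
    tau = float(abs(popt[2]))
    rms = float(np.sqrt(np.mean((expon(t, *popt) - y) ** 2)))
    scale = max(abs(span), abs(float(popt[1])), 1e-12)
    if rms > reject_rms_frac * scale:
        raise FitError(f"onset fit rejected: rms {rms:.3g} exceeds "
                       f"{reject_rms_frac:.0%} of onset amplitude {scale:.3g}")
    return OnsetFit(tau_ms=tau, rms=rms)


def inap_iv(control: Recording, first_post_ttx: Recording,
            cm_pF: Optional[float] = None, bin_mV: float = 5.0) -> IVCurve:
    """Persistent-Na⁺ ramp I–V by TTX subtraction and 5-mV binning.

    The first post-TTX ramp sweep is subtracted from the average of the
    control ramp sweeps; the difference current is binned by the ramp
    command voltage into half-open ``[v, v + 5)`` mV intervals (bin
    centers reported).  When a capacitance is given the result is
    normalized to pA/pF.  ``peak_negative`` holds the most negative bin
    value.
    """
    if cm_pF is not None and cm_pF <= 0:
        raise ValueError("cm_pF must be positive")
    if control.mode != "voltage_clamp" or first_post_ttx.mode != "voltage_clamp":
        raise ProtocolMismatchError("ramp subtraction needs voltage-clamp recordings")
    if len(control.time_ms) != len(first_post_ttx.time_ms):
        raise ProtocolMismatchError("control and TTX recordings differ in length")
    cmd = control.traces.get("command")
    if cmd is None:
        raise MissingDataError("control recording lacks the command trace")
    diff = control.traces["i"].mean(axis=0) - first_post_ttx.traces["i"][0]
    vcmd = cmd[0]

    t, on, off = _stim_window(control)
    m = (t >= on) & (t < off)
    diff, vcmd = diff[m], vcmd[m]
    v0 = bin_mV * np.floor(vcmd.min() / bin_mV)
    edges = np.arange(v0, vcmd.max() + bin_mV, bin_mV)
    idx = np.digitize(vcmd, edges) - 1
    centers, means, sems = [], [], []
    for b in range(len(edges) - 1 + 1):
        sel = idx == b
        if not sel.any():
            continue
        centers.append(edges[b] + bin_mV / 2.0)
        means.append(float(diff[sel].mean()))
        sems.append(float(diff[sel].std(ddof=1) / np.sqrt(sel.sum()))
                    if sel.sum() > 1 else 0.0)
    means = np.array(means)
    norm = "raw_pA"
    if cm_pF is not None:
        means = means / cm_pF
        sems = list(np.array(sems) / cm_pF)
        norm = "pA_per_pF"
    return IVCurve(voltages_mV=np.array(centers), current=means,
                   dispersion=np.array(sems), normalization=norm,
                   peak_negative=float(means.min()) if len(means) else 0.0)
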