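"""Seeded synthetic-data generators with known ground truth.

Every input class the analysis consumes can be generated here without a
rig or a simulator run: current-clamp step families with an RC membrane
and a stylized spike generator, voltage-clamp step families embedding a
Boltzmann-gated K_Na current plus an inward persistent Na⁺ component,
slow-ramp families with progressive TTX block, spontaneous PSC trains,
and paired recordings realizing each connection motif.  Each generator
returns its recording(s) together with a ground-truth dictionary, so
closed-loop tests compare analysis output against the generating
parameters rather than against constants.

All randomness flows through ``numpy.random.default_rng(seed)``; the same
config always produces the identical dataset.  The noise model is
additive Gaussian on voltages/currents (with an optional 1/f component),
with default SDs chosen to sit near the visual noise floor of
room-temperature whole-cell recordings: 0.2 mV on voltage, a few pA on
current.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .simulate import Recording
from .synaptic import PairBlock, PairRecording, psc_template

__all__ = [
    "StepFamilyConfig",
    "KnaFamilyConfig",
    "RampInapConfig",
    "PscTrainConfig",
    "PairConfig",
    "gen_current_clamp_family",
    "gen_voltage_clamp_kna",
    "gen_ramp_inap",
    "gen_psc_train",
    "gen_pair",
    "gen_pair_batch",
    "save_ground_truth",
]


def save_ground_truth(gt: dict, path) -> None:
    """Serialize a ground-truth dictionary next to its dataset."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"cannot serialize {type(o)}")

    with open(path, "w") as f:
        json.dump(gt, f, indent=2, default=default)


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Approximate 1/f noise by spectral shaping of white noise."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.arange(len(spec), dtype=float)
    f[0] = 1.0
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n)
    return out / out.std() * sd


# ---------------------------------------------------------------------------
# Current-clamp step families


@dataclass(frozen=True)
class StepFamilyConfig:
    """Ground truth for a synthetic current-clamp step family.

    The membrane is a single RC compartment (``r_MOhm``, ``tau_ms``); a
    stylized AP waveform (linear flanks, so half-width equals the flank
    duration) is inserted on suprathreshold sweeps at a rate set by
    ``fi_gain_Hz_per_pA`` above the true rheobase.  Genotype/subtype
    effect templates are expressed by choosing these parameters.
    """

    seed: int = 0
    r_MOhm: float = 200.0
    tau_ms: float = 20.0
    v_rest_mV: float = -65.0
    rheobase_pA: float = 60.0
    fi_gain_Hz_per_pA: float = 0.25
    max_rate_Hz: float = 80.0
    ap_threshold_mV: float = -40.0
    ap_peak_mV: float = 20.0
    ap_half_width_ms: float = 1.0
    ap_ahp_mV: float = 25.0
    variant: str = "culture"
    max_pA: float = 300.0
    dt_ms: float = 0.05
    noise_sd_mV: float = 0.2
    pink_sd_mV: float = 0.0


def _ap_waveform(cfg: StepFamilyConfig, dt: float) -> np.ndarray:
    """Stylized spike relative to local baseline: up, down, AHP, recovery."""
    thr, peak = cfg.ap_threshold_mV, cfg.ap_peak_mV
    amp = peak - thr
    hw = cfg.ap_half_width_ms
    ahp_v = thr - cfg.ap_ahp_mV
    up = np.linspace(0.0, amp, max(int(hw / dt), 2), endpoint=False)
    down = np.linspace(amp, ahp_v - thr, max(int(hw / dt), 2), endpoint=False)
    # recovery long enough to decay to numerical zero; overlapping later
    # spikes simply overwrite it, so no step discontinuity is created
    rec_n = max(int(60.0 / dt), 2)
    recov = (ahp_v - thr) * np.exp(-np.arange(rec_n) * dt / 4.0)
    return np.concatenate([up, down, recov])


def gen_current_clamp_family(config: StepFamilyConfig) -> tuple[Recording, dict]:
    """Generate an RC + spike-generator current-clamp family."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    if cfg.variant == "culture":
        start, inc, dur = -100.0, 20.0, 500.0
    elif cfg.variant == "slice":
        start, inc, dur = -30.0, 5.0, 1000.0
    else:
        raise ValueError(f"unknown variant {cfg.variant!r}")
    amps = np.arange(start, cfg.max_pA + inc / 2, inc)
    pre, post = 100.0, 300.0
    dt = cfg.dt_ms
    t = np.arange(0.0, pre + dur + post + dt / 2, dt)
    on, off = pre, pre + dur
    r_gohm = cfg.r_MOhm / 1e3

    wave = _ap_waveform(cfg, dt)
    v = np.empty((len(amps), len(t)))
    n_spikes_true = []
    for k, amp in enumerate(amps):
        vk = np.full_like(t, cfg.v_rest_mV)
        m_on = (t >= on) & (t < off)
        vk[m_on] += amp * r_gohm * (1.0 - np.exp(-(t[m_on] - on) / cfg.tau_ms))
        v_end = amp * r_gohm * (1.0 - np.exp(-dur / cfg.tau_ms))
        m_off = t >= off
        vk[m_off] += v_end * np.exp(-(t[m_off] - off) / cfg.tau_ms)
        # A spiking membrane never sits above threshold between APs: cap the
        # subthreshold trajectory there (keeps dV/dt transients physical).
        np.minimum(vk, cfg.ap_threshold_mV, out=vk)

        n_sp = 0
        if amp >= cfg.rheobase_pA:
            rate = min(1.0 / (dur / 1e3)
                       + cfg.fi_gain_Hz_per_pA * (amp - cfg.rheobase_pA),
                       cfg.max_rate_Hz)
            n_sp = max(int(round(rate * dur / 1e3)), 1)
            times = on + 5.0 + np.arange(n_sp) * (dur - 10.0) / n_sp
            for ts in times:
                i0 = int(round(ts / dt))
                seg = slice(i0, min(i0 + len(wave), len(t)))
                base = cfg.ap_threshold_mV
                vk[seg] = base + wave[: seg.stop - seg.start]
        n_spikes_true.append(n_sp)
        v[k] = vk

    v += rng.normal(0.0, cfg.noise_sd_mV, size=v.shape)
    if cfg.pink_sd_mV:
        for k in range(len(amps)):
            v[k] += _pink_noise(rng, len(t), cfg.pink_sd_mV)

    i_tr = np.zeros_like(v)
    i_tr[:, (t >= on) & (t < off)] = amps[:, None]
    rec = Recording(
        time_ms=t, traces={"v": v, "i": i_tr}, stim_onset_ms=on,
        stim_dur_ms=dur, amplitudes=amps, mode="current_clamp", holding=0.0,
        dt_ms=dt, provenance={"generator": "gen_current_clamp_family",
                              "seed": cfg.seed})
    grid_rheo = amps[amps >= cfg.rheobase_pA]
    gt = asdict(cfg)
    gt.update(n_spikes_per_sweep=n_spikes_true,
              rheobase_on_grid_pA=float(grid_rheo[0]) if len(grid_rheo) else None)
    return rec, gt


# ---------------------------------------------------------------------------
# Voltage-clamp K_Na families


@dataclass(frozen=True)
class KnaFamilyConfig:
    """Embedded Boltzmann × ohmic K_Na current plus leak and inward Na⁺."""

    seed: int = 0
    v50_mV: float = -30.0
    slope_mV: float = 8.0
    gmax_nS: float = 6.0
    e_k_mV: float = -90.0
    tau_on_ms: float = 5.0
    g_leak_nS: float = 2.0
    e_leak_mV: float = -70.0
    na_gmax_nS: float = 0.0
    na_v50_mV: float = -45.0
    na_slope_mV: float = 5.0
    e_na_mV: float = 55.0
    drug: str = "VU170"  # which blocker the paired recording models
    noise_frac: float = 0.0
    noise_sd_pA: float = 0.0
    dt_ms: float = 0.1


def _boltz(v, v50, k):
    return 1.0 / (1.0 + np.exp(-(v - v50) / k))


def gen_voltage_clamp_kna(config: KnaFamilyConfig,
                          ) -> tuple[Recording, Recording, dict]:
    """Paired control/drug voltage-step families with known K_Na I–V.

    The control current is leak + K_Na + (optionally) an inward
    persistent Na⁺ component.  A VU170 recording removes only the K_Na
    component; a TTX recording removes both the Na⁺ component and — Na⁺
    influx being abolished — the K_Na current, so the TTX-subtraction
    current is net inward at subthreshold potentials when the Na⁺
    component is present.
    """
    cfg = config
    if cfg.drug not in ("VU170", "TTX"):
        raise ValueError("drug must be 'VU170' or 'TTX'")
    rng = np.random.default_rng(cfg.seed)
    amps = np.arange(-80.0, 55.0, 10.0)
    pre, dur, post = 100.0, 1000.0, 200.0
    hold = -70.0
    dt = cfg.dt_ms
    t = np.arange(0.0, pre + dur + post + dt / 2, dt)
    on, off = pre, pre + dur

    def kna_current(v_step, t_rel):
        a0 = _boltz(hold, cfg.v50_mV, cfg.slope_mV)
        a1 = _boltz(v_step, cfg.v50_mV, cfg.slope_mV)
        a = a1 + (a0 - a1) * np.exp(-t_rel / cfg.tau_on_ms)
        return cfg.gmax_nS * a * (v_step - cfg.e_k_mV)  # nS·mV = pA

    def na_current(v):
        return cfg.na_gmax_nS * _boltz(v, cfg.na_v50_mV, cfg.na_slope_mV) \
            * (v - cfg.e_na_mV)

    def leak(v):
        return cfg.g_leak_nS * (v - cfg.e_leak_mV)

    i_ctrl = np.empty((len(amps), len(t)))
    i_drug = np.empty_like(i_ctrl)
    cmd = np.full((len(amps), len(t)), hold)
    plateau = []
    for k, vs in enumerate(amps):
        m = (t >= on) & (t < off)
        cmd[k, m] = vs
        v_tr = cmd[k]
        base = leak(v_tr) + na_current(v_tr)
        ic = base.copy()
        ic[m] += kna_current(vs, t[m] - on)
        ic[~m] += kna_current(hold, np.full((~m).sum(), 1e9))
        if cfg.drug == "VU170":
            idr = base.copy()  # K_Na gone, Na intact
        else:
            idr = leak(v_tr)  # TTX: Na and (Na-deprived) K_Na both gone
        i_ctrl[k] = ic
        i_drug[k] = idr
        a1 = _boltz(vs, cfg.v50_mV, cfg.slope_mV)
        plateau.append(cfg.gmax_nS * a1 * (vs - cfg.e_k_mV))

    for arr in (i_ctrl, i_drug):
        if cfg.noise_frac:
            arr *= rng.normal(1.0, cfg.noise_frac, size=arr.shape)
        if cfg.noise_sd_pA:
            arr += rng.normal(0.0, cfg.noise_sd_pA, size=arr.shape)

    def pack(i_arr):
        return Recording(
            time_ms=t, traces={"i": i_arr, "command": cmd},
            stim_onset_ms=on, stim_dur_ms=dur, amplitudes=amps,
            mode="voltage_clamp", holding=hold, dt_ms=dt,
            provenance={"generator": "gen_voltage_clamp_kna", "seed": cfg.seed})

    gt = asdict(cfg)
    gt.update(kna_plateau_pA=plateau, step_mV=list(amps))
    return pack(i_ctrl), pack(i_drug), gt


# ---------------------------------------------------------------------------
# Slow-ramp I_NaP families


@dataclass(frozen=True)
class RampInapConfig:
    """Ramp recordings with an inward Gaussian I_NaP and progressive TTX.

    The persistent Na⁺ current appears along the voltage ramp as an
    inward Gaussian centred at ``inap_peak_mV`` with amplitude
    ``inap_peak_pA`` (reported negative).  TTX blocks I_NaP immediately;
    the K_Na component declines slowly, by ``kna_decline_per_sweep`` per
    post-TTX sweep, so the first post-TTX sweep isolates I_NaP.
    """

    seed: int = 0
    inap_peak_pA: float = 100.0
    inap_peak_mV: float = -40.0
    inap_sigma_mV: float = 8.0
    kna_gmax_nS: float = 3.0
    kna_v50_mV: float = -35.0
    kna_slope_mV: float = 10.0
    e_k_mV: float = -90.0
    g_leak_nS: float = 2.0
    e_leak_mV: float = -80.0
    n_control: int = 5
    n_post_ttx: int = 3
    kna_decline_per_sweep: float = 0.3
    noise_sd_pA: float = 2.0
    dt_ms: float = 0.2


def gen_ramp_inap(config: RampInapConfig) -> tuple[Recording, Recording, dict]:
    """Control ramps and a post-TTX ramp sequence with known I_NaP."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    pre, dur, post = 100.0, 5000.0, 100.0
    hold, rate = -80.0, 20.0  # mV, mV/s
    dt = cfg.dt_ms
    t = np.arange(0.0, pre + dur + post + dt / 2, dt)
    on, off = pre, pre + dur
    m = (t >= on) & (t < off)
    vcmd = np.full_like(t, hold)
    vcmd[m] = hold + rate * (t[m] - on) / 1e3

    def leak(v):
        return cfg.g_leak_nS * (v - cfg.e_leak_mV)

    def kna(v, frac=1.0):
        return frac * cfg.kna_gmax_nS * _boltz(v, cfg.kna_v50_mV, cfg.kna_slope_mV) \
            * (v - cfg.e_k_mV)

    def inap(v):
        return -cfg.inap_peak_pA * np.exp(
            -((v - cfg.inap_peak_mV) ** 2) / (2 * cfg.inap_sigma_mV ** 2))

    base = leak(vcmd)
    ctrl = np.stack([
        base + kna(vcmd) + inap(vcmd)
        + rng.normal(0.0, cfg.noise_sd_pA, size=len(t))
        for _ in range(cfg.n_control)
    ])
    ttx = np.stack([
        base + kna(vcmd, frac=max(1.0 - cfg.kna_decline_per_sweep * k, 0.0))
        + rng.normal(0.0, cfg.noise_sd_pA, size=len(t))
        for k in range(cfg.n_post_ttx)
    ])
    cmd_c = np.tile(vcmd, (cfg.n_control, 1))
    cmd_t = np.tile(vcmd, (cfg.n_post_ttx, 1))

    def pack(i_arr, cmd, n):
        return Recording(
            time_ms=t, traces={"i": i_arr, "command": cmd},
            stim_onset_ms=on, stim_dur_ms=dur,
            amplitudes=np.arange(n, dtype=float),
            mode="voltage_clamp", holding=hold, dt_ms=dt,
            provenance={"generator": "gen_ramp_inap", "seed": cfg.seed})

    gt = asdict(cfg)
    gt.update(true_peak_pA=-cfg.inap_peak_pA)
    return pack(ctrl, cmd_c, cfg.n_control), pack(ttx, cmd_t, cfg.n_post_ttx), gt


# ---------------------------------------------------------------------------
# Spontaneous PSC trains and paired recordings


@dataclass(frozen=True)
class PscTrainConfig:
    """A Poisson train of template-shaped PSCs in Gaussian noise."""

    seed: int = 0
    duration_s: float = 60.0
    rate_Hz: float = 5.0
    amp_mean_pA: float = 30.0
    amp_sd_pA: float = 5.0
    polarity: str = "negative"
    rise_ms: float = 0.5
    decay_ms: float = 3.0
    noise_sd_pA: float = 5.0
    dt_ms: float = 0.1


def gen_psc_train(config: PscTrainConfig) -> tuple[np.ndarray, np.ndarray, dict]:
    """Generate (time_ms, current_pA, ground truth) for one sPSC trace."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * 1e3 / cfg.dt_ms))
    t = np.arange(n) * cfg.dt_ms
    trace = rng.normal(0.0, cfg.noise_sd_pA, size=n)
    w = psc_template(cfg.dt_ms, cfg.rise_ms, cfg.decay_ms)
    sign = -1.0 if cfg.polarity == "negative" else 1.0
    n_ev = rng.poisson(cfg.rate_Hz * cfg.duration_s)
    onsets = np.sort(rng.uniform(600.0, t[-1] - 50.0, size=n_ev))
    amps = np.maximum(rng.normal(cfg.amp_mean_pA, cfg.amp_sd_pA, size=n_ev), 1.0)
    for on, a in zip(onsets, amps):
        i0 = int(round(on / cfg.dt_ms))
        seg = slice(i0, min(i0 + len(w), n))
        trace[seg] += sign * a * w[: seg.stop - seg.start]
    gt = asdict(cfg)
    gt.update(event_times_ms=onsets, event_amps_pA=sign * amps, n_events=n_ev)
    return t, trace, gt


@dataclass(frozen=True)
class PairConfig:
    """One paired recording realizing a requested coupling motif.

    ``motif`` ∈ {not_coupled, chemical_one_way, chemical_two_way,
    electrical}.  Chemical coupling produces IPSCs time-locked (latency
    ~2 ms) to presynaptic APs; electrical coupling produces step-evoked
    deflections scaled by ``coupling_coeff`` in both directions plus
    AP-evoked spikelets.
    """

    seed: int = 0
    motif: str = "not_coupled"
    coupling_coeff: float = 0.05
    step_pA: float = 100.0
    pre_r_MOhm: float = 200.0
    ipsc_amp_pA: float = 50.0
    ipsc_latency_ms: float = 2.0
    ipsc_jitter_ms: float = 0.3
    spikelet_amp_pA: float = 25.0
    n_aps: int = 10
    noise_sd_mV: float = 0.1
    noise_sd_pA: float = 4.0
    dt_ms: float = 0.1

    def __post_init__(self) -> None:
        if self.motif not in ("not_coupled", "chemical_one_way",
                              "chemical_two_way", "electrical"):
            raise ValueError(f"unknown motif {self.motif!r}")


def _ap_train_trace(t, ap_times, v_rest=-65.0):
    v = np.full_like(t, v_rest)
    dt = t[1] - t[0]
    up = np.linspace(0.0, 90.0, max(int(0.6 / dt), 2), endpoint=False)
    down = np.linspace(90.0, -10.0, max(int(0.8 / dt), 2), endpoint=False)
    recov = -10.0 * np.exp(-np.arange(int(8.0 / dt)) * dt / 4.0)
    wave = np.concatenate([up, down, recov])  # relative to threshold -40ish
    for ta in ap_times:
        i0 = int(round(ta / dt))
        seg = slice(i0, min(i0 + len(wave), len(t)))
        v[seg] = v_rest + 20.0 + wave[: seg.stop - seg.start]
    return v


def gen_pair(config: PairConfig) -> tuple[PairRecording, dict]:
    """Generate one four-block paired recording for a requested motif."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.dt_ms

    # --- step blocks: 700 ms, step at 100–600 ms
    t_s = np.arange(0.0, 700.0, dt)
    on, off = 100.0, 600.0
    m = (t_s >= on) & (t_s < off)
    chem_ab = cfg.motif in ("chemical_one_way", "chemical_two_way")
    chem_ba = cfg.motif == "chemical_two_way"
    elec = cfg.motif == "electrical"

    def step_block():
        pre = np.full_like(t_s, -65.0)
        defl = cfg.step_pA * cfg.pre_r_MOhm / 1e3  # mV
        pre[m] += defl * (1.0 - np.exp(-(t_s[m] - on) / 15.0))
        post = np.full_like(t_s, -65.0)
        if elec:
            post[m] += cfg.coupling_coeff * defl * (
                1.0 - np.exp(-(t_s[m] - on) / 25.0))
        pre = pre + rng.normal(0.0, cfg.noise_sd_mV, len(t_s))
        post = post + rng.normal(0.0, cfg.noise_sd_mV, len(t_s))
        return PairBlock(kind="step", time_ms=t_s, pre=pre, post=post,
                         step_window_ms=(on, off))

    # --- AP-train blocks: 1200 ms, APs every 60 ms from 200 ms
    t_a = np.arange(0.0, 1200.0, dt)
    ap_times = 200.0 + 60.0 * np.arange(cfg.n_aps)

    def ap_block(chemical: bool):
        pre = _ap_train_trace(t_a, ap_times)
        post = rng.normal(0.0, cfg.noise_sd_pA, len(t_a))
        w = psc_template(dt)
        if chemical:
            for ta in ap_times:
                lat = cfg.ipsc_latency_ms + rng.normal(0.0, cfg.ipsc_jitter_ms)
                i0 = int(round((ta + max(lat, 0.5)) / dt))
                seg = slice(i0, min(i0 + len(w), len(t_a)))
                amp = max(rng.normal(cfg.ipsc_amp_pA, cfg.ipsc_amp_pA / 5), 5.0)
                post[seg] += -amp * w[: seg.stop - seg.start]
        if elec:
            # junction current: low-pass filtered AP, biphasic vs baseline
            v_dev = pre - pre[0]
            alpha = dt / (dt + 2.0)
            filt = np.empty_like(v_dev)
            acc = 0.0
            for i, x in enumerate(v_dev):
                acc += alpha * (x - acc)
                filt[i] = acc
            filt = filt - np.mean(filt[: int(100.0 / dt)])
            scale = cfg.spikelet_amp_pA / max(filt.max(), 1e-9)
            post += scale * filt
        return PairBlock(kind="ap_train", time_ms=t_a, pre=pre, post=post,
                         pre_ap_times_ms=ap_times)

    pair = PairRecording(
        a_to_b_step=step_block(), b_to_a_step=step_block(),
        a_to_b_ap=ap_block(chem_ab), b_to_a_ap=ap_block(chem_ba),
    )
    gt = asdict(cfg)
    return pair, gt


def gen_pair_batch(n_pairs: int, motif_counts: dict[str, int], seed: int = 0,
                   base: Optional[PairConfig] = None,
                   ) -> tuple[list[PairRecording], dict]:
    """A batch of paired recordings drawn from specified motif counts.

    ``motif_counts`` maps motif names to counts and must sum to
    ``n_pairs`` (e.g. 15 connected of 40: ``{"chemical_one_way": 10,
    "chemical_two_way": 3, "electrical": 2, "not_coupled": 25}``).
    """
    if sum(motif_counts.values()) != n_pairs:
        raise ValueError("motif counts must sum to n_pairs")
    base = base or PairConfig()
    rng = np.random.default_rng(seed)
    motifs = [m for m, c in motif_counts.items() for _ in range(c)]
    rng.shuffle(motifs)
    pairs, gts = [], []
    for k, motif in enumerate(motifs):
        from dataclasses import replace

        cfg = replace(base, motif=motif, seed=int(rng.integers(2 ** 31)))
        p, g = gen_pair(cfg)
        pairs.append(p)
        gts.append(g)
    return pairs, {"motifs": motifs, "configs": gts, "seed": seed}
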