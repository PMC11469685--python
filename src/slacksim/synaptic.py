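"""Spontaneous PSC detection, the E/I balance statistic and paired motifs.

Spontaneous postsynaptic currents are found with the classic sliding
template method: a difference-of-exponentials template (0.5 ms rise,
3 ms decay) is optimally scaled at every lag and an event is called
where the fitted template amplitude exceeds three times the baseline
noise SD.  The E/I ratio summarizes excitatory drive as
(sEPSC frequency × charge) / (sEPSC frequency × charge + sIPSC
frequency × charge).

Paired recordings — bidirectional current steps and AP trains between
two simultaneously patched neurons — are classified into the four
connection motifs: not coupled, chemical one-way, chemical two-way, or
electrical.  Chemical coupling is evidenced by PSCs time-locked to
presynaptic APs without step-evoked voltage deflections; electrical
(gap-junction) coupling by simultaneous step-evoked deflections in the
non-injected cell, often accompanied by low-pass-filtered AP spikelets.
Electrical evidence takes precedence in the call; the per-direction
evidence is retained for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "PSCEvent",
    "PSCDetectionParams",
    "PairBlock",
    "PairRecording",
    "MotifCriteria",
    "MotifCall",
    "psc_template",
    "detect_pscs",
    "ei_ratio",
    "classify_pair",
    "connection_probability",
]


@dataclass(frozen=True)
class PSCEvent:
    onset_ms: float
    amplitude_pA: float
    charge_pC: float


@dataclass(frozen=True)
class PSCDetectionParams:
    """Sliding-template detection settings.

    ``threshold_sd`` scales the baseline noise SD into the amplitude
    criterion; template kinetics default to the standard 0.5 ms rise /
    3 ms decay miniature-event template.
    """

    rise_ms: float = 0.5
    decay_ms: float = 3.0
    threshold_sd: float = 3.0
    template_span_decay: float = 5.0
    baseline_ms: float = 500.0


def psc_template(dt_ms: float, rise_ms: float = 0.5, decay_ms: float = 3.0,
                 span_decay: float = 5.0) -> np.ndarray:
    """Unit-peak difference-of-exponentials PSC template."""
    t = np.arange(0.0, span_decay * decay_ms, dt_ms)
    w = (1.0 - np.exp(-t / rise_ms)) * np.exp(-t / decay_ms)
    return w / w.max()


def detect_pscs(trace: np.ndarray, time_ms: np.ndarray, polarity: str = "negative",
                params: PSCDetectionParams = PSCDetectionParams(),
                ) -> list[PSCEvent]:
    """Detect spontaneous PSCs by optimally scaled template matching.

    The template is least-squares fitted (scale + offset) at every lag;
    an event is called at local maxima of the fitted amplitude exceeding
    ``threshold_sd`` × baseline SD, with events closer than the template
    duration merged.  Charge integrates the baseline-subtracted trace
    from onset until return to baseline or five decay constants,
    whichever comes first.

    ``polarity`` declares the PSC direction ('negative' for inward
    currents at a hyperpolarized holding potential, 'positive' for
    outward); the trace is flipped internally so detection always runs
    on positive deflections.
    """
    trace = np.asarray(trace, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    dt = time_ms[1] - time_ms[0]
    n_base = int(round(params.baseline_ms / dt))
    if n_base < int(round(100.0 / dt)):
        raise ValueError("baseline segment must be at least 100 ms")
    if polarity not in ("negative", "positive"):
        raise ValueError("polarity must be 'negative' or 'positive'")
    sign = -1.0 if polarity == "negative" else 1.0
    y = sign * trace

    base = y[:n_base]
    # robust SD: detrended by the median, iterated once to drop events
    sd = float(np.std(base - np.median(base)))
    w = psc_template(dt, params.rise_ms, params.decay_ms,
                     params.template_span_decay)
    nw = len(w)
    if nw >= len(y):
        return []

    # sliding least-squares fit of y ≈ a*w + c over each window
    sw = float(w.sum())
    sww = float((w * w).sum())
    ones = np.ones(nw)
    sy = np.convolve(y, ones[::-1], mode="valid")
    swy = np.convolve(y, w[::-1], mode="valid")
    denom = sww - sw * sw / nw
    amp = (swy - sw * sy / nw) / denom  # fitted template amplitude at each lag

    thr = params.threshold_sd * sd
    above = amp > thr
    events: list[PSCEvent] = []
    i = 0
    last_end = -nw
    while i < len(amp):
        if above[i]:
            j = i
            while j < len(amp) and above[j]:
                j += 1
            k = i + int(np.argmax(amp[i:j]))
            if k - last_end >= nw // 2:
                onset = time_ms[k]
                a = float(amp[k])
                # charge: integrate above local baseline to return or 5τ
                c0 = float(np.median(y[max(k - nw, 0):k])) if k > 0 else 0.0
                span = min(nw, len(y) - k)
                seg = y[k:k + span] - c0
                below = np.where(seg[int(params.rise_ms / dt) + 1:] <= 0)[0]
                end = (below[0] + int(params.rise_ms / dt) + 1) if len(below) else span
                charge = float(seg[:end].sum() * dt) / 1e3  # pA·ms → pC
                events.append(PSCEvent(onset_ms=float(onset),
                                       amplitude_pA=sign * a,
                                       charge_pC=sign * charge))
                last_end = k
            i = j
        else:
            i += 1
    return events


def ei_ratio(e_freq_Hz: float, e_charge_pC: float,
             i_freq_Hz: float, i_charge_pC: float) -> float:
    """Excitation/inhibition balance in [0, 1].

    (sEPSC frequency × charge) / (sEPSC frequency × charge + sIPSC
    frequency × charge); charge magnitudes are used.  Returns NaN when
    both products vanish (undefined balance).
    """
    vals = [e_freq_Hz, abs(e_charge_pC), i_freq_Hz, abs(i_charge_pC)]
    if any(v < 0 for v in vals):
        raise ValueError("frequencies and charges must be non-negative")
    e = vals[0] * vals[1]
    i = vals[2] * vals[3]
    if e + i == 0:
        return float("nan")
    return e / (e + i)


# ---------------------------------------------------------------------------
# Paired recordings


@dataclass(frozen=True)
class PairBlock:
    """One stimulus-response block of a paired recording.

    ``kind`` is 'step' (current step in the presynaptic cell, postsynaptic
    membrane potential recorded) or 'ap_train' (APs evoked presynaptically,
    postsynaptic current recorded under voltage clamp).
    """

    kind: str
    time_ms: np.ndarray
    pre: np.ndarray
    post: np.ndarray
    step_window_ms: Optional[tuple[float, float]] = None
    pre_ap_times_ms: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kind not in ("step", "ap_train"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.kind == "step" and self.step_window_ms is None:
            raise ValueError("step block requires step_window_ms")


@dataclass(frozen=True)
class PairRecording:
    """Four stimulus-response blocks between neurons A and B."""

    a_to_b_step: PairBlock
    b_to_a_step: PairBlock
    a_to_b_ap: PairBlock
    b_to_a_ap: PairBlock

    def __post_init__(self) -> None:
        for name in ("a_to_b_step", "b_to_a_step"):
            if getattr(self, name).kind != "step":
                raise ValueError(f"{name} must be a step block")
        for name in ("a_to_b_ap", "b_to_a_ap"):
            if getattr(self, name).kind != "ap_train":
                raise ValueError(f"{name} must be an ap_train block")


@dataclass(frozen=True)
class MotifCriteria:
    """Decision thresholds for the motif classification."""

    deflection_sd: float = 5.0
    lock_window_ms: tuple[float, float] = (1.0, 10.0)
    min_locked_fraction: float = 0.3
    min_locked_events: int = 2
    psc_polarity: str = "negative"
    psc_params: PSCDetectionParams = field(
        default_factory=lambda: PSCDetectionParams(baseline_ms=100.0))
    spikelet_sd: float = 3.0


@dataclass(frozen=True)
class MotifCall:
    """The motif label plus per-direction evidence for audit."""

    motif: str  # not_coupled | chemical_one_way | chemical_two_way | electrical
    evidence: dict


def _step_deflection(block: PairBlock, n_sd: float) -> bool:
    t = block.time_ms
    on, off = block.step_window_ms
    base = block.post[t < on]
    if len(base) < 10:
        raise ValueError("step block lacks a pre-step baseline")
    sd = float(np.std(base))
    sd = max(sd, 1e-9)
    defl = abs(float(np.mean(block.post[(t >= on) & (t < off)]) - np.mean(base)))
    return defl > n_sd * sd


def _pre_ap_times(block: PairBlock) -> np.ndarray:
    if block.pre_ap_times_ms is not None:
        return np.asarray(block.pre_ap_times_ms, dtype=float)
    from .features import detect_aps

    return detect_aps(block.pre, block.time_ms)


def _chemical_evidence(block: PairBlock, crit: MotifCriteria) -> bool:
    aps = _pre_ap_times(block)
    if len(aps) == 0:
        return False
    events = detect_pscs(block.post, block.time_ms, crit.psc_polarity,
                         crit.psc_params)
    if not events:
        return False
    onsets = np.array([e.onset_ms for e in events])
    lo, hi = crit.lock_window_ms
    locked = sum(bool(np.any((onsets >= t + lo) & (onsets <= t + hi)))
                 for t in aps)
    return (locked >= crit.min_locked_events
            and locked / len(aps) >= crit.min_locked_fraction)


def _spikelet_evidence(block: PairBlock, crit: MotifCriteria) -> bool:
    """Time-locked biphasic fast transients after presynaptic APs.

    A spikelet is a low-pass-filtered AP: through a gap junction both the
    fast depolarizing lobe and the slower AHP lobe appear in the
    postsynaptic record, so the signature is a biphasic deflection within
    ~15 ms of the AP, with both lobes above the noise floor.
    """
    aps = _pre_ap_times(block)
    if len(aps) == 0:
        return False
    t = block.time_ms
    dt = t[1] - t[0]
    base = block.post[t < (aps[0] - 5.0)] if aps[0] > 10.0 else block.post[:max(
        int(50.0 / dt), 10)]
    sd = max(float(np.std(base)), 1e-9)
    mu = float(np.mean(base))
    hits = 0
    for ta in aps:
        m = (t >= ta) & (t <= ta + 15.0)
        if not m.any():
            continue
        seg = block.post[m] - mu
        if seg.max() > crit.spikelet_sd * sd and seg.min() < -1.5 * sd:
            hits += 1
    return hits >= max(1, len(aps) // 2)


def classify_pair(pair: PairRecording,
                  criteria: MotifCriteria = MotifCriteria()) -> MotifCall:
    """Classify a paired recording into one of the four coupling motifs.

    Electrical evidence (step-evoked deflection in either direction)
    takes precedence; otherwise chemical evidence in both directions
    gives chemical_two_way, in exactly one chemical_one_way, and in
    neither not_coupled.  Every input yields exactly one call.
    """
    ev = {
        "a_to_b": {
            "deflection": _step_deflection(pair.a_to_b_step, criteria.deflection_sd),
            "psc": _chemical_evidence(pair.a_to_b_ap, criteria),
            "spikelet": _spikelet_evidence(pair.a_to_b_ap, criteria),
        },
        "b_to_a": {
            "deflection": _step_deflection(pair.b_to_a_step, criteria.deflection_sd),
            "psc": _chemical_evidence(pair.b_to_a_ap, criteria),
            "spikelet": _spikelet_evidence(pair.b_to_a_ap, criteria),
        },
    }
    if ev["a_to_b"]["deflection"] or ev["b_to_a"]["deflection"]:
        motif = "electrical"
    else:
        n_chem = int(ev["a_to_b"]["psc"]) + int(ev["b_to_a"]["psc"])
        motif = {0: "not_coupled", 1: "chemical_one_way",
                 2: "chemical_two_way"}[n_chem]
    return MotifCall(motif=motif, evidence=ev)


def connection_probability(n_connected: int, n_tested: int,
                           conf: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Connection proportion with an exact (Clopper–Pearson) interval."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    if not 0 <= n_connected <= n_tested:
        raise ValueError("n_connected must lie in [0, n_tested]")
    p = n_connected / n_tested
    alpha = 1.0 - conf
    lo = 0.0 if n_connected == 0 else float(
        stats.beta.ppf(alpha / 2, n_connected, n_tested - n_connected + 1))
    hi = 1.0 if n_connected == n_tested else float(
        stats.beta.ppf(1 - alpha / 2, n_connected + 1, n_tested - n_connected))
    return p, (lo, hi)
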