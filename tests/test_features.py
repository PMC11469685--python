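"""Trace-measurement definitions against generator ground truth."""

import numpy as np
import pytest

from slacksim import features as feat
from slacksim import synthetic as syn


@pytest.fixture(scope="module")
def rc_family():
    cfg = syn.StepFamilyConfig(seed=11, r_MOhm=200.0, tau_ms=20.0,
                               rheobase_pA=60.0)
    rec, gt = syn.gen_current_clamp_family(cfg)
    return rec, gt


class TestPassiveProperties:
    def test_recovers_generator_truth(self, rc_family):
        rec, gt = rc_family
        p = feat.passive_properties(rec)
        assert p.r_in_MOhm == pytest.approx(200.0, abs=2.0)
        assert p.tau_ms == pytest.approx(20.0, abs=0.5)
        assert p.cm_pF == pytest.approx(p.tau_ms / p.r_in_MOhm * 1e3, rel=1e-9)
        assert p.v_rest_mV == pytest.approx(-65.0, abs=0.2)

    def test_linearity_in_amplitude(self):
        """Doubling hyperpolarizing amplitudes leaves R_in unchanged."""
        r_vals = []
        for max_pA in (100.0, 200.0):
            cfg = syn.StepFamilyConfig(seed=7, noise_sd_mV=0.0,
                                       rheobase_pA=1e9, max_pA=max_pA)
            rec, _ = syn.gen_current_clamp_family(cfg)
            r_vals.append(feat.passive_properties(rec).r_in_MOhm)
        assert r_vals[0] == pytest.approx(r_vals[1], rel=1e-6)

    def test_requires_hyperpolarizing_sweeps(self, rc_family):
        rec, _ = rc_family
        import copy

        flat = copy.copy(rec)
        flat.amplitudes = np.abs(rec.amplitudes)
        with pytest.raises(feat.MissingDataError):
            feat.passive_properties(flat)


class TestDetectAps:
    def test_flat_trace_empty(self):
        t = np.arange(0, 1000, 0.05)
        assert len(feat.detect_aps(np.full_like(t, -65.0), t)) == 0

    def test_single_canonical_ap(self):
        cfg = syn.StepFamilyConfig(seed=3, noise_sd_mV=0.1)
        rec, gt = syn.gen_current_clamp_family(cfg)
        i = int(np.argmax(rec.amplitudes == 60.0))  # rheobase sweep: 1 spike
        assert gt["n_spikes_per_sweep"][i] == 1
        sp = feat.detect_aps(rec.traces["v"][i], rec.time_ms)
        sp = sp[(sp >= 100.0) & (sp < 600.0)]
        assert len(sp) == 1
        assert sp[0] == pytest.approx(105.0, abs=1.0)  # inserted at onset+5

    def test_subthreshold_bump_ignored(self):
        t = np.arange(0, 1000, 0.05)
        v = np.full_like(t, -65.0)
        m = (t >= 400) & (t < 420)
        v[m] += 10.0 * np.sin(np.pi * (t[m] - 400) / 20.0)
        assert len(feat.detect_aps(v, t)) == 0

    def test_counts_match_generator_across_sweeps(self):
        rec, gt = syn.gen_current_clamp_family(syn.StepFamilyConfig(seed=21))
        fi, _ = feat.fi_curve_and_class(rec)
        expected = [n for a, n in zip(rec.amplitudes,
                                      gt["n_spikes_per_sweep"]) if a > 0]
        assert list(fi.counts) == expected


class TestApFeatures:
    def _triangle(self, thr=-40.0, peak=20.0, base_ms=2.0, post_min=-70.0):
        dt = 0.01
        t = np.arange(0, 200, dt)
        v = np.full_like(t, thr - 15.0)
        i0 = int(50.0 / dt)
        n_half = int(base_ms / 2 / dt)
        v[i0 - n_half:i0] = np.linspace(thr - 15.0, thr, n_half, endpoint=False)
        up = np.linspace(thr, peak, n_half, endpoint=False)
        down = np.linspace(peak, post_min, n_half, endpoint=False)
        v[i0:i0 + n_half] = up
        v[i0 + n_half:i0 + 2 * n_half] = down
        v[i0 + 2 * n_half:] = post_min
        return t, v

    def test_amplitude_and_ahp_arithmetic(self):
        t, v = self._triangle()
        sp = feat.detect_aps(v, t)
        f = feat.ap_features(v, t, sp[0])
        assert f.amplitude_mV == pytest.approx(60.0, abs=1.5)
        assert f.ahp_mV == pytest.approx(f.threshold_mV + 70.0, abs=0.2)

    def test_symmetric_triangle_half_width(self):
        """Linear-flank spike of 2 ms base: half-width 1 ms."""
        t, v = self._triangle(base_ms=2.0, post_min=-40.0)
        sp = feat.detect_aps(v, t)
        f = feat.ap_features(v, t, sp[0])
        assert f.half_width_ms == pytest.approx(1.0, abs=0.1)

    def test_clipped_spike_flagged(self):
        dt = 0.05
        t = np.arange(0, 100, dt)
        v = np.full_like(t, -65.0)
        v[-20:] = np.linspace(-65, 30, 20)  # rising edge at trace end
        sp = feat.detect_aps(v, t)
        assert len(sp) == 1
        f = feat.ap_features(v, t, sp[0])
        assert not f.valid


class TestRheobase:
    def test_first_spiking_sweep(self, rc_family):
        rec, gt = rc_family
        assert feat.rheobase(rec) == gt["rheobase_on_grid_pA"] == 60.0

    def test_not_evocable(self):
        cfg = syn.StepFamilyConfig(seed=5, rheobase_pA=1e9, max_pA=200.0)
        rec, _ = syn.gen_current_clamp_family(cfg)
        assert feat.rheobase(rec) is None

    def test_consistency_with_fi(self, rc_family):
        """Rheobase equals the smallest amplitude with a nonzero count."""
        rec, _ = rc_family
        fi, _ = feat.fi_curve_and_class(rec)
        spiking = fi.amplitudes_pA[fi.counts > 0]
        assert feat.rheobase(rec) == spiking.min()


class TestFsClassifier:
    @pytest.mark.parametrize("rate,broadening,expected", [
        (70.0, 0.10, "FS"),
        (70.0, 0.30, "NFS"),
        (50.0, 0.05, "NFS"),
    ])
    def test_printed_rule(self, rate, broadening, expected):
        """Brute-force re-application of the two printed rules."""
        call = "FS" if (rate > 60.0 and broadening < 0.25) else "NFS"
        assert call == expected

    def test_classifier_equals_rule_oracle(self):
        """Classifier output equals the rule applied to extracted features."""
        for seed in range(3):
            cfg = syn.StepFamilyConfig(seed=seed, max_rate_Hz=90.0)
            rec, _ = syn.gen_current_clamp_family(cfg)
            fi, klass = feat.fi_curve_and_class(rec)
            imax = int(np.argmax(fi.rates_Hz))
            # recompute broadening by hand on the maximal sweep
            amp = fi.amplitudes_pA[imax]
            i = int(np.argmax(rec.amplitudes == amp))
            t = rec.time_ms
            sp = feat.detect_aps(rec.traces["v"][i], t)
            sp = sp[(sp >= 100.0) & (sp < 600.0)]
            broadening = 0.0
            if len(sp) >= 2:
                f0 = feat.ap_features(rec.traces["v"][i], t, sp[0])
                f1 = feat.ap_features(rec.traces["v"][i], t, sp[-1])
                broadening = (f1.half_width_ms - f0.half_width_ms) \
                    / f0.half_width_ms
            oracle = "FS" if (fi.max_rate_Hz > 60.0 and broadening < 0.25) \
                else "NFS"
            assert klass == oracle


class TestSubtractionIV:
    def test_constant_difference(self):
        c, d, gt = syn.gen_voltage_clamp_kna(syn.KnaFamilyConfig(seed=1))
        import copy

        shifted = copy.copy(d)
        shifted.traces = dict(d.traces)
        shifted.traces["i"] = c.traces["i"] - 300.0
        iv = feat.subtraction_iv(c, shifted)
        assert iv.current == pytest.approx(300.0, abs=1e-9)

    def test_identical_recordings_zero(self):
        c, _, _ = syn.gen_voltage_clamp_kna(syn.KnaFamilyConfig(seed=2))
        iv = feat.subtraction_iv(c, c)
        assert np.max(np.abs(iv.current)) == 0.0

    def test_protocol_mismatch_rejected(self):
        c, _, _ = syn.gen_voltage_clamp_kna(syn.KnaFamilyConfig(seed=3))
        r, _, _ = syn.gen_ramp_inap(syn.RampInapConfig(seed=3))
        with pytest.raises(feat.ProtocolMismatchError):
            feat.subtraction_iv(c, r)

    def test_noise_free_plateau_equals_truth(self):
        c, d, gt = syn.gen_voltage_clamp_kna(syn.KnaFamilyConfig(seed=4))
        iv = feat.subtraction_iv(c, d)
        assert iv.current == pytest.approx(np.array(gt["kna_plateau_pA"]),
                                           abs=1e-6)

    def test_ttx_difference_net_inward_at_negative_v(self):
        cfg = syn.KnaFamilyConfig(seed=5, drug="TTX", na_gmax_nS=1.0)
        c, d, _ = syn.gen_voltage_clamp_kna(cfg)
        iv = feat.subtraction_iv(c, d)
        i_60 = iv.current[np.argmin(np.abs(iv.voltages_mV + 60.0))]
        assert i_60 < 0.0


class TestFitActivation:
    def test_noise_free_exact_recovery(self):
        c, d, gt = syn.gen_voltage_clamp_kna(
            syn.KnaFamilyConfig(seed=6, v50_mV=-30.0, slope_mV=8.0))
        fit = feat.fit_activation(feat.subtraction_iv(c, d), e_rev_mV=-90.0)
        assert fit.v50_mV == pytest.approx(-30.0, abs=0.5)
        assert fit.slope_mV == pytest.approx(8.0, abs=0.5)
        assert fit.gmax == pytest.approx(gt["gmax_nS"], rel=0.01)

    def test_all_zero_currents_fail(self):
        iv = feat.IVCurve(voltages_mV=np.arange(-80.0, 51.0, 10.0),
                          current=np.zeros(14))
        with pytest.raises((feat.FitError, feat.MissingDataError)):
            feat.fit_activation(iv, e_rev_mV=-90.0)

    def test_too_few_points_rejected(self):
        iv = feat.IVCurve(voltages_mV=np.array([-80.0, -70.0]),
                          current=np.array([1.0, 2.0]))
        with pytest.raises(feat.MissingDataError):
            feat.fit_activation(iv, e_rev_mV=-90.0)


class TestFitExponentialOnset:
    @pytest.mark.parametrize("tau,tol", [(5.0, 0.1), (50.0, 1.0)])
    def test_recovers_tau(self, tau, tol):
        t = np.arange(0.0, 12.0 * tau, 0.1)
        y = 100.0 * (1.0 - np.exp(-t / tau))
        fit = feat.fit_exponential_onset(y, t)
        assert fit.tau_ms == pytest.approx(tau, abs=tol)

    def test_pure_noise_rejected(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 50.0, 0.1)
        y = rng.normal(0.0, 1.0, len(t))
        with pytest.raises(feat.FitError):
            feat.fit_exponential_onset(y, t)


class TestInapIV:
    def test_bin_count_20(self):
        ctrl, ttx, _ = syn.gen_ramp_inap(syn.RampInapConfig(seed=7))
        iv = feat.inap_iv(ctrl, ttx)
        assert len(iv.voltages_mV) == 20  # (-80..+20)/5

    def test_peak_location_and_normalization(self):
        cfg = syn.RampInapConfig(seed=8, inap_peak_pA=100.0,
                                 inap_peak_mV=-40.0, noise_sd_pA=0.5)
        ctrl, ttx, _ = syn.gen_ramp_inap(cfg)
        iv = feat.inap_iv(ctrl, ttx, cm_pF=100.0)
        assert iv.normalization == "pA_per_pF"
        # peak in a bin adjacent to −40 mV; bin-averaging attenuates the
        # Gaussian peak slightly below −1 pA/pF
        v_at_peak = iv.voltages_mV[int(np.argmin(iv.current))]
        assert abs(v_at_peak + 40.0) <= 5.0
        assert -1.0 <= iv.peak_negative <= -0.9

    def test_linearity_in_inap(self):
        pk = []
        for scale in (1.0, 2.0):
            cfg = syn.RampInapConfig(seed=9, inap_peak_pA=100.0 * scale,
                                     noise_sd_pA=0.0)
            ctrl, ttx, _ = syn.gen_ramp_inap(cfg)
            pk.append(feat.inap_iv(ctrl, ttx).peak_negative)
        assert pk[1] == pytest.approx(2.0 * pk[0], rel=1e-6)

    def test_zero_inap_flat(self):
        cfg = syn.RampInapConfig(seed=10, inap_peak_pA=0.0, noise_sd_pA=0.0,
                                 kna_decline_per_sweep=0.0)
        ctrl, ttx, _ = syn.gen_ramp_inap(cfg)
        iv = feat.inap_iv(ctrl, ttx)
        assert np.max(np.abs(iv.current)) < 1e-9
        assert iv.peak_negative == pytest.approx(0.0, abs=1e-9)

    def test_invalid_cm_rejected(self):
        ctrl, ttx, _ = syn.gen_ramp_inap(syn.RampInapConfig(seed=11))
        with pytest.raises(ValueError):
            feat.inap_iv(ctrl, ttx, cm_pF=-5.0)
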