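"""Integrator correctness, protocols, virtual pharmacology, provenance."""

import numpy as np
import pytest

from slacksim import channels as ch
from slacksim import experiments as ex
from slacksim import features as feat
from slacksim import neurons as nr
from slacksim import simulate as sim


def rc_step_protocol(amp=-100.0, dt=0.025):
    return sim.Protocol(
        mode="current_clamp", holding=0.0,
        sweeps=(sim.Stimulus(kind="step", amplitude=amp, duration_ms=500.0),),
        dt_ms=dt)


class TestPassiveIntegration:
    def test_rc_step_matches_analytic(self, passive_cell, passive_analytic):
        """Voltage follows V = Vrest − I·R·(1 − e^(−t/τ)) within 0.5%."""
        r_ohm, tau = passive_analytic
        rec = sim.run_protocol(passive_cell, rc_step_protocol())
        t, v = rec.time_ms, rec.traces["v"][0]
        m = (t >= 100.0) & (t < 600.0)
        v_an = -70.0 - 100e-12 * r_ohm * 1e3 * (
            1.0 - np.exp(-(t[m] - 100.0) / tau))
        steady = abs(100e-12 * r_ohm * 1e3)
        assert np.max(np.abs(v[m] - v_an)) / steady < 0.005

    def test_zero_amplitude_flat(self, passive_cell):
        rec = sim.run_protocol(passive_cell, rc_step_protocol(amp=0.0))
        assert np.max(np.abs(rec.traces["v"] + 70.0)) < 1e-6

    def test_dt_halving_convergence(self, passive_cell):
        r1 = sim.run_protocol(passive_cell, rc_step_protocol(dt=0.025))
        r2 = sim.run_protocol(passive_cell, rc_step_protocol(dt=0.0125))
        v2 = r2.traces["v"][0][::2]
        assert np.max(np.abs(r1.traces["v"][0] - v2)) < 0.1

    def test_kernel_matches_numpy_reference(self, passive_cell):
        p = rc_step_protocol(dt=0.05)
        a = sim.run_protocol(passive_cell, p, engine="kernel")
        b = sim.run_protocol(passive_cell, p, engine="numpy")
        assert np.array_equal(a.traces["v"], b.traces["v"])


class TestActiveIntegration:
    def test_pv_suprathreshold_spikes(self):
        m = nr.build_preset_neuron("PV", 0)
        proto = sim.Protocol(
            mode="current_clamp",
            sweeps=(sim.Stimulus(amplitude=400.0, duration_ms=300.0),),
            dt_ms=0.025)
        rec = sim.run_protocol(m, proto)
        spikes = feat.detect_aps(rec.traces["v"][0], rec.time_ms)
        assert len(spikes) >= 1

    def test_dt_halving_on_active_model_subthreshold(self):
        m = nr.build_preset_neuron("SST", 0)
        proto = sim.Protocol(
            mode="current_clamp",
            sweeps=(sim.Stimulus(amplitude=-60.0, duration_ms=300.0),),
            dt_ms=0.025, post_ms=100.0)
        v1 = sim.run_protocol(m, proto).traces["v"][0]
        proto2 = sim.Protocol(
            mode="current_clamp",
            sweeps=(sim.Stimulus(amplitude=-60.0, duration_ms=300.0),),
            dt_ms=0.0125, post_ms=100.0)
        v2 = sim.run_protocol(m, proto2).traces["v"][0][::2]
        assert np.max(np.abs(v1 - v2)) < 0.1

    def test_determinism(self):
        m = nr.build_preset_neuron("SST", 1)
        proto = sim.make_current_step_protocol("culture", max_pA=100)
        a = sim.run_protocol(m, proto)
        b = sim.run_protocol(m, proto)
        assert np.array_equal(a.traces["v"], b.traces["v"])
        assert a.provenance["model_hash"] == b.provenance["model_hash"]


class TestVoltageClamp:
    def test_charge_conservation_space_clamp(self, passive_cell):
        """Clamp current equals ionic + capacitive current exactly."""
        proto = sim.make_voltage_step_protocol(clamp_mode="space")
        rec = sim.run_protocol(passive_cell, proto)
        comp = passive_cell.compartments["soma"]
        t = rec.time_ms
        # plateau samples: ionic only, capacitive is zero
        m = (t >= 600.0) & (t < 1000.0)
        g_nS = 1e-4 * comp.area_cm2 * 1e9
        for i, amp in enumerate(rec.amplitudes):
            expect = g_nS * (amp + 70.0) * 1e-3 * 1e3  # pA
            assert rec.traces["i"][i][m] == pytest.approx(expect, abs=1e-6)

    def test_kcnt1_zero_with_zero_internal_na(self):
        """With [Na]ᵢ clamped to 0 mM the KCNT1 current vanishes."""
        m = nr.build_preset_neuron("SST", 0)
        from dataclasses import replace

        m = replace(m, na_pool=ch.NaPoolParams(clamp_to_mM=0.0))
        rec = sim.run_protocol(m, sim.make_voltage_step_protocol())
        assert np.max(np.abs(rec.traces["i_kcnt1"])) < 1e-9

    def test_vu170_subtraction_equals_logged_kcnt1(self):
        m = nr.build_preset_neuron("SST", 0)
        proto = sim.make_voltage_step_protocol()
        ctrl = sim.run_protocol(m, proto)
        drug = sim.run_protocol(m, proto,
                                blockers=[sim.BlockerState("VU170", 1.0)])
        iv = feat.subtraction_iv(ctrl, drug)
        t = ctrl.time_ms
        win = (t >= 1000.0) & (t < 1100.0)
        logged = ctrl.traces["i_kcnt1"][:, win].mean(axis=1)
        order = np.argsort(ctrl.amplitudes)
        big = np.abs(logged[order]) > 1.0
        rel = np.abs(iv.current[big] - logged[order][big]) / np.abs(
            logged[order][big])
        assert rel.max() < 0.02

    def test_gof_acts_only_through_kcnt1(self):
        """Without KCNT1, wt and gof30 parameterizations are identical."""
        base = nr.build_preset_neuron("SST", 0)
        comps = {}
        from dataclasses import replace

        for cid, c in base.compartments.items():
            chans = {k: v for k, v in c.channels.items() if k != ch.KCNT1}
            comps[cid] = replace(c, channels=chans)
        for level in ("wt", "gof30"):
            lib = dict(base.channel_library)
            lib[ch.KCNT1] = ch.apply_gof(lib[ch.KCNT1], level)
            m = nr.NeuronModel(subtype="SST", compartments=comps,
                               channel_library=lib, na_pool=base.na_pool)
            rec = sim.run_protocol(
                m, sim.make_current_step_protocol("culture", max_pA=100))
            if level == "wt":
                ref = rec.traces["v"]
            else:
                assert np.array_equal(rec.traces["v"], ref)

    def test_ttx_blocks_both_na_channels(self):
        m = nr.build_preset_neuron("PV", 0)
        rec = sim.run_protocol(
            m, sim.make_voltage_step_protocol(
                record=("v", "i", "na", "i_na_ch", "command")),
            blockers=[sim.BlockerState("TTX", 1.0)])
        assert np.max(np.abs(rec.traces["i_na_ch"])) < 1e-9

    def test_divergence_raises(self, passive_cell):
        proto = sim.Protocol(
            mode="current_clamp",
            sweeps=(sim.Stimulus(amplitude=1e7, duration_ms=50.0),),
            dt_ms=0.05, post_ms=10.0)
        with pytest.raises(sim.IntegrationError, match="sweep 0"):
            sim.run_protocol(passive_cell, proto)


class TestProtocolBuilders:
    def test_culture_steps(self):
        p = sim.make_current_step_protocol("culture")
        assert p.sweeps[0].amplitude == -100.0
        assert p.sweeps[0].duration_ms == 500.0
        assert p.sweeps[1].amplitude - p.sweeps[0].amplitude == 20.0

    def test_slice_steps(self):
        p = sim.make_current_step_protocol("slice")
        assert p.sweeps[0].amplitude == -30.0
        assert p.sweeps[0].duration_ms == 1000.0
        assert p.sweeps[1].amplitude - p.sweeps[0].amplitude == 5.0

    def test_voltage_steps(self):
        p = sim.make_voltage_step_protocol()
        amps = p.amplitudes()
        assert len(amps) == 14
        assert amps[0] == -80.0 and amps[-1] == 50.0
        assert p.holding == -70.0
        assert p.sweeps[0].duration_ms == 1000.0

    def test_ramp(self):
        p = sim.make_ramp_protocol()
        s = p.sweeps[0]
        assert p.holding == -80.0
        assert s.ramp_rate_mV_per_s == 20.0
        assert s.duration_ms == 5000.0
        # final command voltage +20 mV
        assert p.holding + s.ramp_rate_mV_per_s * s.duration_ms / 1e3 == 20.0
        assert p.inter_sweep_s == 5.0


class TestRecordingIO:
    def test_hdf5_roundtrip(self, tmp_path, passive_cell):
        rec = sim.run_protocol(passive_cell, rc_step_protocol(dt=0.1))
        path = tmp_path / "rec.h5"
        rec.to_hdf5(path)
        back = sim.Recording.from_hdf5(path)
        assert np.array_equal(back.traces["v"], rec.traces["v"])
        assert back.provenance == rec.provenance

    def test_dataframe_export(self, passive_cell):
        rec = sim.run_protocol(passive_cell, rc_step_protocol(dt=0.1))
        df = rec.to_dataframe()
        assert len(df) == rec.n_sweeps * len(rec.time_ms)
        assert {"sweep", "time_ms", "amplitude", "v"} <= set(df.columns)

    def test_decimation(self, passive_cell):
        proto = sim.Protocol(
            mode="current_clamp",
            sweeps=(sim.Stimulus(amplitude=-50.0, duration_ms=100.0),),
            dt_ms=0.025, post_ms=50.0, decimate_khz=20.0)
        rec = sim.run_protocol(passive_cell, proto)
        assert rec.dt_ms == pytest.approx(0.05)
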