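"""Model construction, presets, manipulations and SWC import."""

import numpy as np
import pytest

from slacksim import channels as ch
from slacksim import features as feat
from slacksim import neurons as nr
from slacksim import simulate as sim


class TestPresets:
    def test_referential_transparency(self):
        a = nr.build_preset_neuron("SST", 3)
        b = nr.build_preset_neuron("SST", 3)
        assert a == b
        c = nr.build_preset_neuron("SST", 4)
        assert a != c

    def test_unknown_subtype(self):
        with pytest.raises(ValueError):
            nr.build_preset_neuron("XX", 0)

    def test_structure(self):
        m = nr.build_preset_neuron("PV", 0)
        assert 3 <= len(m.compartments) <= 9
        regions = {c.region for c in m.compartments.values()}
        assert regions == {"soma", "dend", "axon"}
        # KCNT1 in all compartments at the standard insertion density
        for c in m.compartments.values():
            assert c.channels[ch.KCNT1] == pytest.approx(0.03)
        # control I_NaP at 0.001 x g_NaT wherever NaT lives
        for c in m.compartments.values():
            if ch.NA_T in c.channels:
                assert c.channels[ch.NA_P] == pytest.approx(
                    0.001 * c.channels[ch.NA_T])

    def test_pv_is_fs_and_vip_is_nfs(self):
        """PV presets classify fast-spiking, VIP non-fast-spiking."""
        proto = sim.make_current_step_protocol("culture", max_pA=500)
        for subtype, expected in (("PV", "FS"), ("VIP", "NFS")):
            rec = sim.run_protocol(nr.build_preset_neuron(subtype, 0), proto)
            _, klass = feat.fi_curve_and_class(rec)
            assert klass == expected


class TestInsertChannel:
    def test_insert_in_regions(self, sst_wt):
        spec = ch.leak_spec(2e-4, -60.0)
        spec = ch.ChannelSpec(name="extra", gbar_S_per_cm2=2e-4,
                              e_rev_mV=-60.0)
        m = nr.insert_channel(sst_wt, spec, {"soma", "dend", "axon"}, 0.03)
        assert all(c.channels["extra"] == 0.03
                   for c in m.compartments.values())

    def test_zero_density_allowed(self, sst_wt):
        spec = ch.ChannelSpec(name="extra", gbar_S_per_cm2=0.0, e_rev_mV=0.0)
        m = nr.insert_channel(sst_wt, spec, {"soma"}, 0.0)
        assert m.compartments[m.soma_id].channels["extra"] == 0.0

    def test_reinsert_replaces(self, sst_wt):
        spec = ch.kcnt1_spec(-35.0, 12.0)
        m = nr.insert_channel(sst_wt, spec, {"soma"}, 0.05)
        m = nr.insert_channel(m, spec, {"soma"}, 0.05)
        assert m.compartments[m.soma_id].channels[ch.KCNT1] == 0.05

    def test_empty_regions_rejected(self, sst_wt):
        with pytest.raises(ValueError):
            nr.insert_channel(sst_wt, ch.kcnt1_spec(-35.0, 12.0), set(), 0.03)


class TestKineticsSwap:
    def test_swap_assigns_donor_parameters(self):
        vip = nr.build_preset_neuron("VIP", 0)
        donor = nr.load_preset_params()["subtypes"]["SST"]["kcnt1"]
        m = nr.swap_kcnt1_kinetics(vip, donor["v50_mV"], donor["slope_mV"])
        g = m.channel_library[ch.KCNT1].gate_of_kind("boltzmann_v")
        assert (g.v50_mV, g.slope_mV) == (donor["v50_mV"], donor["slope_mV"])
        # Na gate untouched
        h = m.channel_library[ch.KCNT1].gate_of_kind("hill_na")
        assert h.ec50_mM == 40.0

    def test_swap_requires_kcnt1(self, passive_cell):
        with pytest.raises(ValueError):
            nr.swap_kcnt1_kinetics(passive_cell, -35.0, 12.0)

    def test_swap_composes_with_gof(self):
        vip = nr.build_preset_neuron("VIP", 0)
        m = nr.swap_kcnt1_kinetics(vip, -35.0, 12.0)
        m = m.with_channel_spec(ch.apply_gof(m.channel_library[ch.KCNT1],
                                             "gof30"))
        spec = m.channel_library[ch.KCNT1]
        assert spec.gate_of_kind("hill_na").ec50_mM == 30.0
        assert spec.gate_of_kind("boltzmann_v").v50_mV == -35.0
        # equals manual construction in the other order
        m2 = vip.with_channel_spec(ch.apply_gof(vip.channel_library[ch.KCNT1],
                                                "gof30"))
        m2 = nr.swap_kcnt1_kinetics(m2, -35.0, 12.0)
        assert m2.channel_library[ch.KCNT1] == spec


class TestModelInvariants:
    def test_missing_channel_rejected(self):
        comp = nr.Compartment(id="soma", region="soma", length_um=10,
                              diameter_um=10, channels={"ghost": 1e-4})
        with pytest.raises(ValueError):
            nr.NeuronModel(subtype="PC", compartments={"soma": comp},
                           channel_library={})

    def test_cycle_rejected(self):
        a = nr.Compartment(id="a", region="soma", length_um=10,
                           diameter_um=10, parent=None)
        b = nr.Compartment(id="b", region="dend", length_um=10,
                           diameter_um=10, parent="c")
        c = nr.Compartment(id="c", region="dend", length_um=10,
                           diameter_um=10, parent="b")
        with pytest.raises(ValueError):
            nr.NeuronModel(subtype="PC", compartments={"a": a, "b": b, "c": c},
                           channel_library={})

    def test_manipulations_preserve_invariants(self, sst_wt):
        m = ch.set_inap_density(sst_wt, 2.0)
        m = nr.swap_kcnt1_kinetics(m, -20.0, 9.0)
        # reconstruct from its own pieces: still valid
        rebuilt = nr.NeuronModel(subtype=m.subtype,
                                 compartments=m.compartments,
                                 channel_library=m.channel_library,
                                 na_pool=m.na_pool)
        assert rebuilt == m

    def test_inap_scale_zero_removes(self, sst_wt):
        m = ch.set_inap_density(sst_wt, 0.0)
        assert all(ch.NA_P not in c.channels for c in m.compartments.values())


MINI_SWC = """\
# soma + two dendrite points
1 1 0 0 0 5 -1
2 3 0 0 10 1 1
3 3 0 0 25 1 2
"""


class TestSWCImport:
    def test_minimal_file(self):
        m = nr.import_morphology(MINI_SWC)
        assert len(m.compartments) == 3
        root = m.compartments[m.soma_id]
        assert root.region == "soma"
        dend = [c for c in m.compartments.values() if c.region == "dend"]
        assert len(dend) == 2
        assert sum(c.length_um for c in dend) == pytest.approx(25.0)

    def test_collapse(self):
        m = nr.import_morphology(MINI_SWC, collapse=2)
        dend = [c for c in m.compartments.values() if c.region == "dend"]
        assert len(dend) == 1
        assert dend[0].length_um == pytest.approx(25.0)

    def test_self_parent_rejected(self):
        with pytest.raises(ValueError, match="own parent"):
            nr.import_morphology("1 1 0 0 0 5 1\n")

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            nr.import_morphology("# nothing\n")

    def test_malformed_line_names_line(self):
        bad = MINI_SWC + "4 3 0 0\n"
        with pytest.raises(ValueError, match="line 5"):
            nr.import_morphology(bad)

    def test_passive_simulation_runs(self):
        m = nr.import_morphology(MINI_SWC, passive={"g_leak": 1e-4})
        proto = sim.Protocol(
            mode="current_clamp", sweeps=(sim.Stimulus(amplitude=-20.0,
                                                       duration_ms=200.0),),
            dt_ms=0.05, settle_ms=50.0, post_ms=100.0)
        rec = sim.run_protocol(m, proto)
        assert np.all(np.isfinite(rec.traces["v"]))
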