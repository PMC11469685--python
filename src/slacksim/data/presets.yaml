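# Versioned subtype presets for the reduced compartmental models.
#
# KCNT1 voltage-gate parameters (v50_mV, slope_mV) per subtype are
# calibration placeholders constrained qualitatively: glutamatergic (PC)
# and VIP activation curves are right-shifted with a steeper slope, SST
# and PV curves sit further left with a shallower slope.  The onset time
# constant tau_v_ms stands in for the patch-measured single-exponential
# onset of the VU170-sensitive current.  The liquid-junction-potential
# shift applied when mapping experimental activation curves onto the
# model is exposed here and defaults to 0 (uncorrected).
#
# Per-subtype passive and active densities were calibrated once against
# the qualitative class orderings (input resistance VIP > SST > PV,
# rheobase / maximal rate PV > SST > VIP, AP half-width VIP > SST > PV,
# SST threshold most hyperpolarized) and are frozen here.
version: 1
kcnt1:
  gbar_S_per_cm2: 0.03
  e_rev_mV: -90.0
  tau_v_ms: 5.0
  ljp_shift_mV: 0.0
subtypes:
  PC:
    kcnt1: {v50_mV: -10.0, slope_mV: 6.0}
    soma: {length_um: 25.0, diameter_um: 25.0}
    dend: {n: 3, length_um: 400.0, diameter_um: 2.5}
    axon: {length_um: 60.0, diameter_um: 1.0}
    cm_uF_per_cm2: 1.0
    ra_ohm_cm: 150.0
    e_leak_mV: -75.0
    g_leak: 1.0e-4
    g_nat: 0.055
    g_kdr: 0.030
    dend_active_fraction: 0.1
    nat: {m_v50_mV: -31.0, m_slope_mV: 6.0, h_v50_mV: -52.0, h_slope_mV: -7.0,
          h_tau_min_ms: 0.6, h_tau_amp_ms: 8.0}
    kdr: {n_v50_mV: -28.0, n_slope_mV: 9.0, n_tau_min_ms: 1.0, n_tau_amp_ms: 4.0}
  VIP:
    kcnt1: {v50_mV: -10.0, slope_mV: 6.0}
    soma: {length_um: 14.0, diameter_um: 14.0}
    dend: {n: 2, length_um: 180.0, diameter_um: 1.5}
    axon: {length_um: 40.0, diameter_um: 0.8}
    cm_uF_per_cm2: 1.0
    ra_ohm_cm: 150.0
    e_leak_mV: -72.0
    g_leak: 0.9e-4
    g_nat: 0.028
    g_kdr: 0.018
    dend_active_fraction: 0.1
    nat: {m_v50_mV: -30.0, m_slope_mV: 6.0, h_v50_mV: -60.0, h_slope_mV: -7.0,
          h_tau_min_ms: 1.2, h_tau_amp_ms: 28.0, h_tau_vpeak_mV: -50.0,
          h_tau_sigma_mV: 25.0}
    kdr: {n_v50_mV: -24.0, n_slope_mV: 9.0, n_tau_min_ms: 1.6, n_tau_amp_ms: 30.0,
          n_tau_vpeak_mV: -75.0, n_tau_sigma_mV: 30.0}
  SST:
    kcnt1: {v50_mV: -35.0, slope_mV: 12.0}
    soma: {length_um: 16.0, diameter_um: 16.0}
    dend: {n: 2, length_um: 220.0, diameter_um: 1.8}
    axon: {length_um: 50.0, diameter_um: 1.0}
    cm_uF_per_cm2: 1.0
    ra_ohm_cm: 150.0
    e_leak_mV: -70.0
    g_leak: 1.5e-4
    g_nat: 0.055
    g_kdr: 0.028
    dend_active_fraction: 0.1
    nat: {m_v50_mV: -37.0, m_slope_mV: 6.0, h_v50_mV: -57.0, h_slope_mV: -7.0,
          h_tau_min_ms: 0.6, h_tau_amp_ms: 12.0}
    kdr: {n_v50_mV: -26.0, n_slope_mV: 9.0, n_tau_min_ms: 0.8, n_tau_amp_ms: 10.0,
          n_tau_vpeak_mV: -72.0, n_tau_sigma_mV: 28.0}
  PV:
    kcnt1: {v50_mV: -22.0, slope_mV: 10.0}
    soma: {length_um: 18.0, diameter_um: 18.0}
    dend: {n: 2, length_um: 250.0, diameter_um: 2.0}
    axon: {length_um: 50.0, diameter_um: 1.0}
    cm_uF_per_cm2: 1.0
    ra_ohm_cm: 150.0
    e_leak_mV: -76.0
    g_leak: 2.8e-4
    g_nat: 0.080
    g_kdr: 0.060
    dend_active_fraction: 0.1
    nat: {m_v50_mV: -30.0, m_slope_mV: 6.0, h_v50_mV: -52.0, h_slope_mV: -7.0,
          h_tau_min_ms: 0.3, h_tau_amp_ms: 2.5}
    kdr: {n_v50_mV: -12.0, n_slope_mV: 8.0, n_tau_min_ms: 0.4, n_tau_amp_ms: 1.2}
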