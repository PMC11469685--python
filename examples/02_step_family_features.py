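"""Current-clamp step family on a preset neuron, with feature extraction.

Builds one SST-class model, runs the standard step protocol (500 ms
pulses from -100 pA in 20 pA increments) and extracts the passive and
firing features an electrophysiologist would report.
"""

import numpy as np

from slacksim import features as feat
from slacksim import neurons as nr
from slacksim import simulate as sim

model = nr.build_preset_neuron("SST", variant_seed=0)
proto = sim.make_current_step_protocol("culture", max_pA=400.0)
rec = sim.run_protocol(model, proto)

p = feat.passive_properties(rec)
rheo = feat.rheobase(rec)
fi, klass = feat.fi_curve_and_class(rec)

print(f"resting potential : {p.v_rest_mV:7.1f} mV")
print(f"input resistance  : {p.r_in_MOhm:7.1f} MOhm")
print(f"membrane tau      : {p.tau_ms:7.1f} ms")
print(f"capacitance       : {p.cm_pF:7.1f} pF  (tau / R_in)")
print(f"rheobase          : {rheo:7.0f} pA")
print(f"max firing rate   : {fi.max_rate_Hz:7.0f} Hz -> class {klass}")

i = int(np.argmin(np.abs(rec.amplitudes - 2 * rheo)))
spikes = feat.detect_aps(rec.traces["v"][i], rec.time_ms)
spikes = spikes[(spikes >= 100.0) & (spikes < 600.0)]
f = feat.ap_features(rec.traces["v"][i], rec.time_ms, spikes[0])
print(f"first AP at 2x rheobase: threshold {f.threshold_mV:.1f} mV, "
      f"amplitude {f.amplitude_mV:.1f} mV,")
print(f"  half-width {f.half_width_ms:.2f} ms, AHP {f.ahp_mV:.1f} mV")
print("\nThe SST preset is a moderately excitable interneuron: "
      "intermediate R_in,\nhyperpolarized AP threshold, and a maximal "
      "rate between the VIP and PV classes.")
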