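"""Persistent Na⁺ current isolation by slow ramp and TTX subtraction.

Generates synthetic ramp recordings (hold -80 mV, 20 mV/s for 5 s) with a
known inward I_NaP, applies TTX virtually (fast I_NaP block, slow K_Na
decline), subtracts the first post-TTX sweep from the control average and
bins the difference at 5 mV intervals.
"""

import numpy as np

from slacksim import features as feat
from slacksim import synthetic as syn

cfg = syn.RampInapConfig(seed=0, inap_peak_pA=100.0, inap_peak_mV=-40.0)
ctrl, post_ttx, gt = syn.gen_ramp_inap(cfg)

iv = feat.inap_iv(ctrl, post_ttx, cm_pF=100.0)
print("ramp difference current (control mean - first post-TTX sweep):")
for v, i in zip(iv.voltages_mV, iv.current):
    bar = "#" * int(round(-i * 20)) if i < 0 else ""
    print(f"  {v:6.1f} mV : {i:7.3f} pA/pF {bar}")

print(f"\npeak negative I_NaP: {iv.peak_negative:.2f} pA/pF "
      f"(ground truth {gt['true_peak_pA'] / 100.0:.2f} pA/pF at "
      f"{cfg.inap_peak_mV:.0f} mV)")
print("The inward dip near -40 mV is the TTX-sensitive persistent Na+ "
      "current;\nbin-averaging over 5 mV intervals slightly attenuates the "
      "Gaussian peak.")
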