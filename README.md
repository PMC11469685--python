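# slacksim

Compartmental-neuron simulation and patch-clamp trace analysis for
studying **KCNT1 (Slack) channelopathies** — how gain-of-function (GOF) of
a sodium-activated potassium conductance can push closely related cortical
interneuron classes in opposite directions.

## The problem

KCNT1 carries the K_Na current: a K⁺ conductance activated jointly by
membrane voltage and intracellular Na⁺. Epilepsy-linked GOF variants
increase its Na⁺ sensitivity. Counterintuitively, the same variant makes
somatostatin (SST) interneurons hypoexcitable but parvalbumin (PV)
interneurons hyperexcitable, while VIP and pyramidal (PC) neurons are
untouched. `slacksim` packages the computational side of that question:

* a KCNT1 conductance model with a Hill Na⁺ gate
  (`a_Na = [Na]ᵢʰ/([Na]ᵢʰ + EC50ʰ)`, EC50 = 40 mM, h = 3.5; GOF lowers
  EC50 to 35 or 30 mM) times a Boltzmann voltage gate
  (`a_V = 1/(1+exp(−(V−V50)/k))`, per-subtype V50/k, 5 ms relaxation),
  inserted at 0.03 S/cm² in all compartments, plus the transient and
  persistent Na⁺ currents, delayed rectifier, leak, and a submembrane
  Na⁺ pool;
* reduced compartmental presets for the PC, VIP, SST and PV classes with
  seeded cell-to-cell variability;
* the standard virtual protocols — current-clamp step families,
  K_Na voltage steps with drug subtraction (TTX / VU170), and the slow
  ramp that isolates the persistent Na⁺ current — with a deterministic
  Crank–Nicolson cable integrator (compiled inner loop);
* every trace measurement: passive properties, AP detection and shape,
  rheobase, F–I and the FS/NFS rule (> 60 Hz and < 25% broadening),
  subtraction I–V and Boltzmann activation fits, exponential onset τ,
  5-mV-binned ramp I–V; sPSC template detection (0.5 ms rise / 3 ms
  decay, 3 × SD), the E/I ratio, and paired-recording motif
  classification (not coupled / chemical one-way / chemical two-way /
  electrical);
* seeded synthetic-data generators with ground truth for closed-loop
  testing of all of the above;
* the three in-silico experiments: GOF titration, SST-kinetics swap into
  VIP/PC, and the PV rescue by a twofold persistent-Na⁺ increase, with
  exact paired permutation statistics.

There is no command-line interface: the importable API is the surface,
and `examples/` contains one short narrative script per capability.

## Worked example

```python
from slacksim import experiments as ex

sst = ex.run_gof_sweep("SST", n_models=4, max_pA=500.0)
print(sst.summary()[[("r_in_MOhm", "mean"), ("rheobase_pA", "mean"),
                     ("total_aps", "mean")]].round(1))
d, p = ex.paired_compare(sst, "total_aps", "wt", "gof30")
print(f"paired APs (gof30 - wt): {d:+.1f}, p = {p:.4f}")
```

prints

```
          r_in_MOhm rheobase_pA total_aps
               mean        mean      mean
condition
wt            319.7        75.0     556.0
gof35         315.4        85.0     531.8
gof30         308.0       105.0     481.2
paired APs (gof30 - wt): -74.8, p = 0.1250
```

Reading it: raising the channel's Na⁺ sensitivity (EC50 40 → 35 → 30 mM)
progressively lowers the SST models' input resistance, raises the current
needed to evoke a spike, and cuts the number of APs fired across the step
family — the hypoexcitable phenotype. (p here is the exact sign-flip
permutation floor for 4 paired models; the full experiment uses 10.)
`examples/05_gof_experiments.py` adds the PV side: GOF alone also
suppresses the PV models, and only doubling the persistent Na⁺
conductance — as observed experimentally — flips them to firing more than
wild type with a lower rheobase.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the core pipeline from scratch: the SST GOF sweep and the PV
I_NaP rescue on freshly built preset models, activation-curve recovery
from a synthetic voltage-clamp family, and motif classification plus
connection probability on a 40-pair synthetic batch, printing each
result and writing the JSON report to `--out`.

## Layout

```
src/slacksim/
  channels.py     conductance & gate math, GOF, Na+ pool
  neurons.py      compartments, subtype presets, SWC import
  simulate.py     protocols, cable integrator, virtual pharmacology
  _kernel.py      compiled inner loop (numba)
  features.py     passive/AP/F-I/IV/activation/ramp measurements
  synaptic.py     PSC detection, E/I ratio, motif classification
  synthetic.py    seeded generators with ground truth
  experiments.py  GOF titration, kinetics swap, I_NaP rescue, statistics
  data/presets.yaml  frozen subtype calibration
docs/methods.md   model, assumptions, parameter rationale, limitations
examples/         one runnable narrative script per capability
```
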