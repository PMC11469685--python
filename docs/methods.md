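# Methods

`slacksim` models how gain-of-function (GOF) of the sodium-activated
potassium channel KCNT1 (Slack) reshapes the excitability of four cortical
neuron classes — pyramidal cells (PC) and the VIP-, SST- and PV-expressing
GABAergic subtypes — and implements the patch-clamp measurement definitions
needed to quantify it. This note records the model, its assumptions, the
tunable parameters, and the design choices made where the design was open.

## The KCNT1 conductance

KCNT1 is modelled as a Hodgkin–Huxley-style conductance with two
independent multiplicative gates:

* a **Na⁺ gate** with Hill steady state
  `a_Na = [Na]ᵢʰ / ([Na]ᵢʰ + EC50ʰ)`, EC50 = 40 mM and Hill coefficient
  h = 3.5 in the wild type. The gate is instantaneous: K_Na channel
  activation tracks the local Na⁺ concentration, whose own relaxation is
  much slower than any gating time scale we resolve.
* a **voltage gate** with Boltzmann steady state
  `a_V = 1 / (1 + exp(−(V − V50)/k))` relaxing mono-exponentially with a
  fixed time constant τ_V (default 5 ms). A single-exponential onset is
  what outside-out patch measurements of the blocker-sensitive current
  show; the printed record contains the fit overlay but not the value, so
  τ_V is a config parameter.

Current density is `ḡ · a_Na · a_V · (V − E_K)`, outward positive, with
ḡ = 0.03 S/cm² inserted in somatic, dendritic and axonal compartments and
E_K = −90 mV. GOF is a pure increase in Na⁺ sensitivity: EC50 lowered to
35 mM (moderate) or 30 mM (strong), nothing else changed.

Per-subtype activation parameters (V50, k) exist in the source experiments
only as figure curves, so the shipped values are **calibration
placeholders** constrained qualitatively: PC/VIP curves right-shifted and
steep (V50 = −10 mV, k = 6), SST shallow and left (−35 mV, 12). PV was
calibrated to −22 mV, k = 10 — between SST and VIP — because with
identical SST/PV curves the PV model's subthreshold GOF effect exceeded
SST's, inverting the effect-size ordering the modelling experiments must
reproduce (SST largest). A liquid-junction-potential shift for mapping
experimental curves onto the model is exposed in `presets.yaml`
(`ljp_shift_mV`) and defaults to 0: the value used in the source analysis
is not stated, and guessing one would shift every calibrated curve.

## The Na⁺ pool

Each compartment carries a submembrane Na⁺ shell:

    d[Na]/dt = −i_Na/(F·depth) − ([Na] − Na_rest)/τ_Na

fed by the Na⁺-carrying currents (transient and persistent). Defaults:
Na_rest = 10 mM, τ_Na = 300 ms, depth = 0.3 µm. The dynamic pool is
plumbing this package adds — the source experiments fixed internal Na⁺
(10 or 0 mM) for verification, a mode reproduced by `clamp_to_mM`. The
pool constants were calibrated once, jointly with the presets: with
slower clearance (500 ms / 0.2 µm) Na⁺ accumulation during fast-spiking
trains made KCNT1 GOF suppress PV firing so strongly that the observed
twofold-I_NaP rescue could not overcome it. With [Na]ᵢ clamped to 0 mM
the KCNT1 current is identically zero (a test asserts this).

## Neuron presets

Reduced models — soma, a two- or three-segment dendritic cable, an axon
stub (4–6 compartments) — replace full reconstructions. Each carries
leak, transient Na⁺ (m³h), delayed-rectifier K⁺ (n²), KCNT1, and a
persistent Na⁺ current fixed at 0.001 × g_NaT per compartment (control;
the rescue experiment doubles it). Gating steady states are Boltzmann
functions; time constants are a floor plus a Gaussian bump in voltage,
which is enough freedom to shape spike width, refractoriness and
recovery without rate equations.

Densities and kinetics per subtype were calibrated **once** against the
qualitative class orderings (input resistance VIP > SST > PV; rheobase
and maximal rate PV > SST > VIP; AP half-width VIP > SST > PV; SST
threshold most hyperpolarized) and frozen in `data/presets.yaml`. The
mechanisms behind the orderings: PV has a fast, right-shifted (Kv3-like)
rectifier and fast Na⁺ recovery, giving narrow spikes and rates above
200 Hz; VIP and SST have rectifiers that deactivate slowly at
hyperpolarized potentials, which lengthens the inter-spike interval like
an adaptation current and caps VIP below the 60 Hz fast-spiking
criterion; SST's Na⁺ activation is left-shifted, giving it the most
hyperpolarized threshold. Resting potentials: E_leak = −76 mV (PV),
−70 mV (SST), −72 mV (VIP), −75 mV (PC). "Ten neurons per class" is
emulated by seeded ±15% multiplicative jitter of passive and maximal
conductances; (subtype, seed) fully determines a model.

## Integration

Voltages advance with a Crank–Nicolson-style implicit solve of the
branched cable equation (dense Gaussian elimination on the ≤9-compartment
tree, per sweep); gates and the Na⁺ pool use exact exponential updates,
staggered before the voltage solve. Default dt = 0.025 ms. All sweeps of
a protocol integrate in parallel from one settled state (300 ms at the
holding level). The compiled (numba) kernel and the reference numpy
stepper produce bit-identical traces; a test enforces this. Integration
aborts with a named sweep and time if |V| exceeds 200 mV.

Voltage clamp is ideal (no series resistance) and comes in two flavours:
somatic (dendrites free — the whole-cell situation, with its usual
space-clamp error) and space clamp (every compartment follows the
command). The K_Na and ramp measurement protocols default to space
clamp: with the voltage identical under control and blocker, the
subtraction current equals the simulator's internally logged channel
current exactly, which is what the subtraction-oracle acceptance test
exploits. Virtual pharmacology is parameter substitution — a blocker
scales its targets' conductances by (1 − fraction): TTX blocks both Na⁺
currents, VU170 only KCNT1. No binding kinetics.

## Measurement definitions

* **V_rest**: mean over the 50 ms before stimulus onset. **R_in**: slope
  of steady-state deflection vs injected current over all hyperpolarizing
  sweeps (steady state = last 100 ms of the step; the 100 ms window is
  stated only for subtraction currents, we unify). **τ**: single
  exponential over 200 ms after stimulus offset; because a single sweep's
  decay can sit near the noise floor on low-R cells, the decay is pooled
  across hyperpolarizing sweeps by amplitude-weighted regression before
  fitting. **C_m** = τ/R_in.
* **AP detection**: upward crossing of dV/dt ≥ 20 mV/ms followed by a
  local maximum above −10 mV within 10 ms; crossings sharing a peak
  collapse to the latest (the true upstroke); 2 ms merge window. The
  criterion value operationalizes "inflection point of the rising phase"
  and is configurable.
* **AP features**: threshold = voltage at the detection crossing;
  amplitude = peak − threshold; half-width at threshold + amplitude/2
  with interpolated flank crossings; AHP = threshold − minimum V within
  50 ms after the peak (the anchor is the peak; the source text gives the
  window but not the anchor). Clipped waveforms are flagged, not scored.
* **Rheobase**: smallest step current with ≥ 1 AP; resolution equals the
  protocol increment; "not evocable" is `None`, distinct from 0.
* **FS/NFS**: fast-spiking iff maximum mean rate > 60 Hz AND half-width
  broadening (last vs first AP of the maximal-rate sweep) < 25%.
* **Subtraction I–V**: control − drug, averaged over the final 100 ms of
  each voltage pulse. **Activation fit**: G = I/(V − E_K) for steps
  > 5 mV above reversal, Boltzmann least squares.
* **I_NaP ramp**: mean control − first post-TTX sweep, binned by command
  voltage in half-open 5 mV bins (centers reported), optionally per pF;
  the peak negative bin value is reported.
* **sPSC detection**: difference-of-exponentials template (0.5 ms rise,
  3 ms decay) least-squares scaled (with offset) at each lag; events where
  the fitted amplitude exceeds 3 × baseline SD; merges within the template
  span; charge integrates to return-to-baseline or five decay constants.
* **Motif call**: per direction, electrical evidence = step-evoked mean
  deflection > 5 × baseline SD; chemical evidence = PSCs time-locked 1–10
  ms after presynaptic APs (≥ 30% of APs and ≥ 2 events); spikelets
  (biphasic fast transients after APs) are recorded as evidence but never
  required. Electrical takes precedence; then two-way/one-way/none. The
  5×SD deflection threshold and the lock window are not stated in the
  source and are config-exposed.

## Synthetic data

Generators produce every input class with serialized ground truth:
RC-plus-stylized-spike step families (linear-flank APs whose half-width
equals the flank duration; the subthreshold trajectory is capped at
threshold), voltage-step families embedding a Boltzmann × ohmic K_Na
current with exponential onset plus an optional inward Na⁺ component
(VU170 removes K_Na only; TTX removes both, making the TTX difference
net inward at subthreshold potentials), ramp families with an inward
Gaussian I_NaP and progressive post-TTX K_Na decline, Poisson PSC trains,
and four-block paired recordings per motif. Noise is additive Gaussian
(defaults 0.2 mV / a few pA, chosen to resemble room-temperature
whole-cell noise floors; an optional 1/f term exists). Identical configs
give bit-identical data.

What a green closed-loop test establishes: the analysis recovers the
generating parameters of a stylized world whose event shapes match the
detection templates exactly. It does not establish robustness to real
amplifier artifacts, drift, seal degradation, or kinetics that deviate
from the assumed templates.

## Experiments and statistics

The three in-silico experiments pair conditions within model seed:
GOF titration (wt/gof35/gof30), SST-kinetics swap into VIP or PC at
EC50 = 30 mM, and the PV rescue (gof35 + 2 × I_NaP). The step family runs
to a fixed +500 pA ceiling (the source stops at an F–I plateau; a fixed
ceiling keeps runs paired and deterministic). Failed integrations are
recorded per cell and excluded pairwise. Comparisons use an exact
two-sided sign-flip permutation test on paired differences for n ≤ 12
models (all 2ⁿ assignments) and a paired t-test above; the mixed-model
machinery used for the biological data is out of scope by design.

## Known limitations

* The presets are reduced qualitative models: they reproduce orderings
  and directions of effect, not the biological means of any dataset.
* Somatic voltage clamp shares the space-clamp error of real whole-cell
  recordings; quantitative subtraction oracles therefore use space clamp.
* Sample-wise dt-convergence below 0.1 mV holds for passive and
  subthreshold responses; on spiking sweeps, dt changes spike phase, so
  pointwise trace comparison is not a meaningful convergence metric.
* The spikelet detector assumes biphasic junction currents; electrical
  pairs whose AP waveform lacks an afterhyperpolarization would show
  deflection evidence only.
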