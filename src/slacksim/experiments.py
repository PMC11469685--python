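"""End-to-end in-silico experiments on the preset model neurons.

Three experiments probe how KCNT1 gain-of-function reshapes excitability:

* ``run_gof_sweep`` — insert KCNT1 at wild-type Na⁺ sensitivity (EC50 =
  40 mM) and two GOF levels (35, 30 mM) into seeded model variants of one
  subtype, run the current-clamp step family and extract input
  resistance, rheobase and the F–I curve, paired across levels by model
  seed.
* ``run_kinetics_swap`` — write the SST-class activation-curve parameters
  (V50, slope) into VIP or PC models at EC50 = 30 mM, asking whether the
  voltage dependence of the K_Na current alone explains which classes are
  vulnerable.
* ``run_inap_rescue`` — combine PV-model GOF with a twofold increase of
  the persistent Na⁺ conductance, testing whether the I_NaP increase is
  sufficient to flip the GOF effect from hypo- to hyperexcitability.

Comparisons between conditions are within-model (repeated measures): an
exact sign-flip permutation test on the paired differences for n ≤ 12
models, a paired t-test above that.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import channels as chn
from . import features as feat
from .neurons import NeuronModel, build_preset_neuron, load_preset_params, \
    swap_kcnt1_kinetics
from .simulate import IntegrationError, make_current_step_protocol, run_protocol

__all__ = [
    "ExperimentResult",
    "condition_model",
    "run_gof_sweep",
    "run_kinetics_swap",
    "run_inap_rescue",
    "rm_anova",
    "paired_compare",
]

GOF_LEVELS = ("wt", "gof35", "gof30")


@dataclass
class ExperimentResult:
    """Per-model × per-condition feature table plus F–I curves.

    ``table`` has one row per (model_seed, condition) with the scalar
    features; ``fi`` maps (model_seed, condition) to the FICurve; failed
    cells are listed in ``failed`` and appear as NaN rows.
    """

    subtype: str
    conditions: tuple[str, ...]
    table: pd.DataFrame
    fi: dict = field(default_factory=dict)
    failed: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Mean ± SEM of every feature per condition."""
        num = self.table.drop(columns=["model_seed"]) \
            .select_dtypes(include="number").columns
        g = self.table.groupby("condition", sort=False)[list(num)]
        out = g.agg(["mean", "sem"])
        return out.loc[list(self.conditions)]

    def feature(self, name: str) -> pd.DataFrame:
        """Wide per-model table of one feature (models × conditions)."""
        return self.table.pivot(index="model_seed", columns="condition",
                                values=name)[list(self.conditions)]


def condition_model(subtype: str, seed: int, level: str = "wt",
                    inap_scale: float = 1.0,
                    kcnt1_kinetics_from: Optional[str] = None) -> NeuronModel:
    """Build one preset variant under a genotype/manipulation condition."""
    model = build_preset_neuron(subtype, seed)
    if kcnt1_kinetics_from is not None:
        donor = load_preset_params()["subtypes"][kcnt1_kinetics_from]["kcnt1"]
        model = swap_kcnt1_kinetics(model, donor["v50_mV"], donor["slope_mV"])
    spec = chn.apply_gof(model.channel_library[chn.KCNT1], level)
    model = model.with_channel_spec(spec)
    if inap_scale != 1.0:
        model = chn.set_inap_density(model, inap_scale)
    return model


def _measure(model: NeuronModel, max_pA: float, dt_ms: float):
    proto = make_current_step_protocol("culture", max_pA=max_pA, dt_ms=dt_ms,
                                       record=("v", "i"))
    rec = run_protocol(model, proto)
    passive = feat.passive_properties(rec)
    rheo = feat.rheobase(rec)
    fi, klass = feat.fi_curve_and_class(rec)
    # AP height from the first AP of the first suprathreshold sweep
    ap_amp = np.nan
    if rheo is not None:
        i = int(np.argmin(np.abs(rec.amplitudes - rheo)))
        t = rec.time_ms
        spikes = feat.detect_aps(rec.traces["v"][i], t)
        spikes = spikes[(spikes >= rec.stim_onset_ms)
                        & (spikes < rec.stim_onset_ms + rec.stim_dur_ms)]
        if len(spikes):
            f = feat.ap_features(rec.traces["v"][i], t, spikes[0])
            if f.valid:
                ap_amp = f.amplitude_mV
    return {
        "r_in_MOhm": passive.r_in_MOhm,
        "tau_ms": passive.tau_ms,
        "v_rest_mV": passive.v_rest_mV,
        "rheobase_pA": np.nan if rheo is None else rheo,
        "max_rate_Hz": fi.max_rate_Hz,
        "total_aps": int(fi.counts.sum()),
        "ap_amplitude_mV": ap_amp,
        "fs_class": klass,
    }, fi


def _run_conditions(subtype: str, condition_specs: dict, n_models: int,
                    max_pA: float, dt_ms: float,
                    seed0: int = 0) -> ExperimentResult:
    if n_models < 2:
        raise ValueError("need at least 2 model variants for paired analysis")
    rows, fi_map, failed = [], {}, []
    for seed, (label, kwargs) in itertools.product(
            range(seed0, seed0 + n_models), condition_specs.items()):
        try:
            model = condition_model(subtype, seed, **kwargs)
            row, fi = _measure(model, max_pA, dt_ms)
            fi_map[(seed, label)] = fi
        except IntegrationError as e:
            failed.append((seed, label, str(e)))
            row = {k: np.nan for k in ("r_in_MOhm", "tau_ms", "v_rest_mV",
                                       "rheobase_pA", "max_rate_Hz",
                                       "total_aps", "ap_amplitude_mV")}
            row["fs_class"] = "failed"
        row.update(model_seed=seed, condition=label)
        rows.append(row)
    table = pd.DataFrame(rows)
    return ExperimentResult(subtype=subtype,
                            conditions=tuple(condition_specs),
                            table=table, fi=fi_map, failed=failed)


def run_gof_sweep(subtype: str, levels: Sequence[str] = GOF_LEVELS,
                  n_models: int = 10, max_pA: float = 500.0,
                  dt_ms: float = 0.025, seed0: int = 0) -> ExperimentResult:
    """GOF titration: the step family at each Na⁺-sensitivity level."""
    for lv in levels:
        if lv not in GOF_LEVELS:
            raise ValueError(f"unknown GOF level {lv!r}")
    specs = {lv: {"level": lv} for lv in levels}
    return _run_conditions(subtype, specs, n_models, max_pA, dt_ms, seed0)


def run_kinetics_swap(target: str, n_models: int = 10, max_pA: float = 500.0,
                      dt_ms: float = 0.025, donor: str = "SST",
                      seed0: int = 0) -> ExperimentResult:
    """Donor-kinetics swap into VIP or PC models at EC50 = 30 mM."""
    if target not in ("VIP", "PC"):
        raise ValueError("kinetics swap targets VIP or PC models")
    specs = {
        "wt": {"level": "wt"},
        "gof30": {"level": "gof30"},
        "gof30+donor_kinetics": {"level": "gof30", "kcnt1_kinetics_from": donor},
    }
    return _run_conditions(target, specs, n_models, max_pA, dt_ms, seed0)


def run_inap_rescue(subtype: str = "PV", gof_level: str = "gof35",
                    inap_scale: float = 2.0, n_models: int = 10,
                    max_pA: float = 500.0, dt_ms: float = 0.025,
                    seed0: int = 0) -> ExperimentResult:
    """GOF plus an I_NaP increase in PV models (the rescue experiment)."""
    if inap_scale < 0:
        raise ValueError("inap_scale must be non-negative")
    specs = {
        "wt": {"level": "wt"},
        gof_level: {"level": gof_level},
        f"{gof_level}+inap{inap_scale:g}x": {"level": gof_level,
                                             "inap_scale": inap_scale},
    }
    return _run_conditions(subtype, specs, n_models, max_pA, dt_ms, seed0)


def rm_anova(result: ExperimentResult, feature: str) -> tuple[float, float]:
    """One-way repeated-measures ANOVA of a feature across all conditions.

    Returns (F, p) with model seed as the within-subject unit; use
    :func:`paired_compare` for the post-hoc paired contrasts.  Rows with
    any missing condition are dropped listwise.
    """
    from statsmodels.stats.anova import AnovaRM

    wide = result.table.pivot(index="model_seed", columns="condition",
                              values=feature).dropna()
    if len(wide) < 2:
        raise ValueError("need at least 2 complete models")
    long = wide.reset_index().melt(id_vars="model_seed",
                                   var_name="condition", value_name="y")
    fit = AnovaRM(long, depvar="y", subject="model_seed",
                  within=["condition"]).fit()
    row = fit.anova_table.iloc[0]
    return float(row["F Value"]), float(row["Pr > F"])


def paired_compare(result: ExperimentResult, feature: str,
                   condition_a: str, condition_b: str,
                   exact_max_n: int = 12) -> tuple[float, float]:
    """Within-model comparison of one feature between two conditions.

    Returns (mean paired difference b − a, p-value).  For n ≤ 12 pairs
    the p-value is an exact two-sided sign-flip permutation test on the
    paired differences (all 2ⁿ sign assignments); for larger n a paired
    t-test is used.  Models missing either condition are excluded.
    """
    wide = result.feature(feature)
    for c in (condition_a, condition_b):
        if c not in wide.columns:
            raise ValueError(f"condition {c!r} not in result")
    sub = wide[[condition_a, condition_b]].dropna()
    if len(sub) < 2:
        raise ValueError("need at least 2 complete pairs")
    d = (sub[condition_b] - sub[condition_a]).to_numpy()
    obs = float(d.mean())
    n = len(d)
    if n <= exact_max_n:
        signs = np.array(list(itertools.product([1.0, -1.0], repeat=n)))
        perm_means = signs @ d / n
        p = float(np.mean(np.abs(perm_means) >= abs(obs) - 1e-12))
    else:
        from scipy import stats

        p = float(stats.ttest_rel(sub[condition_b], sub[condition_a]).pvalue)
    return obs, p
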