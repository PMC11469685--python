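"""Compartmental neuron models and the four cortical subtype presets.

Reduced models (soma, a short dendritic cable and an axonal stub — 3 to 9
compartments) stand in for full reconstructed morphologies of the four
electrical classes studied here: pyramidal cells (PC), and the VIP-, SST-
and PV-expressing GABAergic subtypes.  Per-subtype passive and active
densities are calibrated once, against the qualitative class orderings
(input resistance VIP > SST > PV, rheobase and maximal firing rate
PV > SST > VIP, AP width VIP > SST > PV, SST with the most hyperpolarized
threshold), and frozen in a versioned parameter file shipped with the
package.  The "ten neurons per class" variety of real datasets is emulated
by seeded ±15% jitter of passive and maximal-conductance parameters.

An SWC import hook builds a model from a standard 7-column morphology file
for users who want to run the same channel manipulations on reconstructed
cells.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import yaml

from . import channels as ch
from .channels import ChannelSpec, GateSpec, NaPoolParams

__all__ = [
    "Compartment",
    "NeuronModel",
    "SUBTYPES",
    "load_preset_params",
    "build_preset_neuron",
    "insert_channel",
    "swap_kcnt1_kinetics",
    "import_morphology",
]

SUBTYPES = ("PC", "VIP", "SST", "PV")
REGIONS = ("soma", "dend", "axon")


@dataclass(frozen=True)
class Compartment:
    """A cylindrical cable segment with passive properties and channels.

    ``channels`` maps channel-library names to conductance densities in
    S/cm²; ``parent`` is the id of the upstream compartment (None at the
    soma root).
    """

    id: str
    region: str
    length_um: float
    diameter_um: float
    cm_uF_per_cm2: float = 1.0
    ra_ohm_cm: float = 150.0
    parent: Optional[str] = None
    channels: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.length_um <= 0 or self.diameter_um <= 0:
            raise ValueError("compartment geometry must be strictly positive")
        if self.cm_uF_per_cm2 <= 0 or self.ra_ohm_cm <= 0:
            raise ValueError("cm and axial resistivity must be strictly positive")
        object.__setattr__(self, "channels", dict(self.channels))

    @property
    def area_cm2(self) -> float:
        """Lateral (membrane) area of the cylinder in cm²."""
        return np.pi * self.diameter_um * self.length_um * 1e-8


@dataclass(frozen=True)
class NeuronModel:
    """A tree of compartments plus the channel library they reference."""

    subtype: str
    compartments: Mapping[str, Compartment]
    channel_library: Mapping[str, ChannelSpec]
    na_pool: NaPoolParams = field(default_factory=NaPoolParams)

    def __post_init__(self) -> None:
        comps = dict(self.compartments)
        object.__setattr__(self, "compartments", comps)
        object.__setattr__(self, "channel_library", dict(self.channel_library))
        roots = [c for c in comps.values() if c.parent is None]
        if len(roots) != 1 or roots[0].region != "soma":
            raise ValueError("model must have exactly one root compartment, at the soma")
        # Reject cycles / dangling parents by walking every lineage to the root.
        for comp in comps.values():
            seen = set()
            cur: Optional[str] = comp.id
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle in compartment tree at {cur!r}")
                seen.add(cur)
                if cur not in comps:
                    raise ValueError(f"compartment {comp.id!r} references missing parent {cur!r}")
                cur = comps[cur].parent
        for comp in comps.values():
            for name in comp.channels:
                if name not in self.channel_library:
                    raise ValueError(
                        f"compartment {comp.id!r} uses channel {name!r} absent from library")

    @property
    def soma_id(self) -> str:
        return next(c.id for c in self.compartments.values() if c.parent is None)

    def total_area_cm2(self) -> float:
        return sum(c.area_cm2 for c in self.compartments.values())

    def with_channel_spec(self, spec: ChannelSpec) -> "NeuronModel":
        lib = dict(self.channel_library)
        lib[spec.name] = spec
        return replace(self, channel_library=lib)


# ---------------------------------------------------------------------------
# Preset parameter file

_REQUIRED_SUBTYPE_KEYS = {
    "kcnt1", "soma", "dend", "axon", "cm_uF_per_cm2", "ra_ohm_cm",
    "e_leak_mV", "g_leak", "g_nat", "g_kdr", "nat", "kdr",
    "dend_active_fraction",
}


def load_preset_params() -> dict:
    """Load and schema-check the versioned subtype parameter file."""
    text = (importlib.resources.files("slacksim") / "data" / "presets.yaml").read_text()
    params = yaml.safe_load(text)
    if not isinstance(params, dict) or "subtypes" not in params or "kcnt1" not in params:
        raise ValueError("preset file must define 'kcnt1' and 'subtypes' sections")
    for st in SUBTYPES:
        if st not in params["subtypes"]:
            raise ValueError(f"preset file missing subtype {st!r}")
        missing = _REQUIRED_SUBTYPE_KEYS - set(params["subtypes"][st])
        if missing:
            raise ValueError(f"subtype {st!r} missing keys {sorted(missing)}")
    return params


_SUBTYPE_CODE = {st: i for i, st in enumerate(SUBTYPES)}


def build_preset_neuron(subtype: str, variant_seed: int = 0,
                        jitter_frac: float = 0.15) -> NeuronModel:
    """Build one seeded variant of a subtype preset.

    ``variant_seed`` selects a deterministic ±15% multiplicative jitter of
    the passive parameters and maximal conductances around the calibrated
    preset, emulating cell-to-cell variability within a class; the same
    (subtype, seed) pair always yields the identical model.  The model
    carries leak, transient Na⁺, delayed-rectifier K⁺, wild-type KCNT1 at
    0.03 S/cm² in soma, dendrite and axon, and the control persistent Na⁺
    current at 0.001 × g_NaT.
    """
    if subtype not in SUBTYPES:
        raise ValueError(f"unknown subtype {subtype!r}; expected one of {SUBTYPES}")
    params = load_preset_params()
    p = params["subtypes"][subtype]
    k = params["kcnt1"]

    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=20240501, spawn_key=(
            _SUBTYPE_CODE[subtype], int(variant_seed))))

    def jit() -> float:
        return float(1.0 + jitter_frac * rng.uniform(-1.0, 1.0))

    g_leak = p["g_leak"] * jit()
    g_nat = p["g_nat"] * jit()
    g_kdr = p["g_kdr"] * jit()
    soma_d = p["soma"]["diameter_um"] * jit()
    dend_l = p["dend"]["length_um"] * jit()

    daf = p["dend_active_fraction"]
    g_kcnt1 = k["gbar_S_per_cm2"]

    # Per-compartment densities (the values in Compartment.channels) are
    # authoritative for the simulator; the library specs carry the somatic
    # density for reference.
    nat = ch.nat_spec(gbar_S_per_cm2=g_nat, **p["nat"])
    kdr = ch.kdr_spec(gbar_S_per_cm2=g_kdr, **p["kdr"])
    leak = ch.leak_spec(gbar_S_per_cm2=g_leak, e_rev_mV=p["e_leak_mV"])
    kcnt1 = ch.kcnt1_spec(
        v50_mV=p["kcnt1"]["v50_mV"] + k.get("ljp_shift_mV", 0.0),
        slope_mV=p["kcnt1"]["slope_mV"],
        tau_v_ms=k["tau_v_ms"],
        gbar_S_per_cm2=g_kcnt1,
        e_rev_mV=k["e_rev_mV"],
    )

    def chanmap(region: str) -> dict:
        f = daf if region == "dend" else 1.0
        m = {ch.LEAK: g_leak, ch.NA_T: g_nat * f, ch.K_DR: g_kdr * f,
             ch.KCNT1: g_kcnt1}
        return m

    cm = p["cm_uF_per_cm2"]
    ra = p["ra_ohm_cm"]
    comps = {}
    comps["soma"] = Compartment(
        id="soma", region="soma", length_um=p["soma"]["length_um"],
        diameter_um=soma_d, cm_uF_per_cm2=cm, ra_ohm_cm=ra,
        parent=None, channels=chanmap("soma"))
    n_dend = p["dend"]["n"]
    prev = "soma"
    for i in range(n_dend):
        cid = f"dend{i}"
        comps[cid] = Compartment(
            id=cid, region="dend", length_um=dend_l / n_dend,
            diameter_um=p["dend"]["diameter_um"], cm_uF_per_cm2=cm,
            ra_ohm_cm=ra, parent=prev, channels=chanmap("dend"))
        prev = cid
    comps["axon"] = Compartment(
        id="axon", region="axon", length_um=p["axon"]["length_um"],
        diameter_um=p["axon"]["diameter_um"], cm_uF_per_cm2=cm,
        ra_ohm_cm=ra, parent="soma", channels=chanmap("axon"))

    model = NeuronModel(
        subtype=subtype,
        compartments=comps,
        channel_library={ch.LEAK: leak, ch.NA_T: nat, ch.K_DR: kdr,
                         ch.KCNT1: kcnt1},
        na_pool=NaPoolParams(),
    )
    # Control persistent Na+ current at 0.001 x g_NaT per compartment.
    return ch.set_inap_density(model, 1.0)


def insert_channel(neuron: NeuronModel, spec: ChannelSpec, regions,
                   density_S_per_cm2: float) -> NeuronModel:
    """Insert (or replace) a channel at a density in the given regions.

    Re-inserting an existing channel replaces its density rather than
    adding to it, so the operation is idempotent.
    """
    regions = set(regions)
    if not regions:
        raise ValueError("regions must be non-empty")
    if not regions <= set(REGIONS):
        raise ValueError(f"regions must be a subset of {REGIONS}")
    if density_S_per_cm2 < 0:
        raise ValueError("density must be non-negative")
    comps = {}
    for cid, comp in neuron.compartments.items():
        if comp.region in regions:
            m = dict(comp.channels)
            m[spec.name] = density_S_per_cm2
            comps[cid] = replace(comp, channels=m)
        else:
            comps[cid] = comp
    lib = dict(neuron.channel_library)
    lib[spec.name] = spec
    return replace(neuron, compartments=comps, channel_library=lib)


def swap_kcnt1_kinetics(neuron: NeuronModel, donor_v50_mV: float,
                        donor_slope_mV: float) -> NeuronModel:
    """Replace the KCNT1 voltage-gate parameters with donor-class values.

    Implements the kinetics-swap manipulation: the Boltzmann V50 and slope
    measured in one neuron class are written into another class's KCNT1
    channel while the Na⁺ gate (and everything else) is left untouched.
    """
    if ch.KCNT1 not in neuron.channel_library:
        raise ValueError("neuron carries no KCNT1 channel to modify")
    spec = neuron.channel_library[ch.KCNT1]
    new_gates = tuple(
        replace(g, v50_mV=donor_v50_mV, slope_mV=donor_slope_mV)
        if g.kind == "boltzmann_v" else g
        for g in spec.gates
    )
    return neuron.with_channel_spec(replace(spec, gates=new_gates))


# ---------------------------------------------------------------------------
# SWC import

_SWC_REGION = {1: "soma", 2: "axon", 3: "dend", 4: "dend"}


def import_morphology(swc_text: str, passive: Optional[dict] = None,
                      collapse: int = 1, subtype: str = "PC") -> NeuronModel:
    """Build a passive model from standard 7-column SWC morphology text.

    Each SWC point (after the root) becomes a cylindrical compartment from
    its parent point to itself; ``collapse`` > 1 merges runs of that many
    consecutive points into one compartment (preserving path length and
    mean diameter).  ``passive`` may override cm_uF_per_cm2, ra_ohm_cm,
    g_leak and e_leak_mV.  Channels beyond leak are inserted afterwards
    with :func:`insert_channel`.
    """
    passive = dict(passive or {})
    cm = passive.get("cm_uF_per_cm2", 1.0)
    ra = passive.get("ra_ohm_cm", 150.0)
    g_leak = passive.get("g_leak", 1.0e-4)
    e_leak = passive.get("e_leak_mV", -70.0)

    pts: dict[int, tuple] = {}
    order: list[int] = []
    for lineno, raw in enumerate(swc_text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) != 7:
            raise ValueError(f"SWC line {lineno}: expected 7 columns, got {len(cols)}")
        try:
            idx = int(cols[0]); typ = int(cols[1])
            x, y, z, r = (float(c) for c in cols[2:6])
            parent = int(cols[6])
        except ValueError as e:
            raise ValueError(f"SWC line {lineno}: {e}") from None
        if idx == parent:
            raise ValueError(f"SWC line {lineno}: point {idx} is its own parent")
        if idx in pts:
            raise ValueError(f"SWC line {lineno}: duplicate index {idx}")
        pts[idx] = (typ, np.array([x, y, z]), r, parent, lineno)
        order.append(idx)
    if not pts:
        raise ValueError("empty SWC file")
    roots = [i for i in order if pts[i][3] == -1]
    if len(roots) != 1:
        raise ValueError(f"SWC must have exactly one root point, found {len(roots)}")
    root = roots[0]
    if pts[root][0] != 1:
        raise ValueError("SWC root point must be of soma type (1)")
    for idx in order:
        parent = pts[idx][3]
        if parent != -1 and parent not in pts:
            raise ValueError(f"SWC line {pts[idx][4]}: unresolvable parent {parent}")

    leak = ch.leak_spec(gbar_S_per_cm2=g_leak, e_rev_mV=e_leak)
    typ, _, r, _, _ = pts[root]
    comps: dict[str, Compartment] = {
        f"swc{root}": Compartment(
            id=f"swc{root}", region="soma", length_um=max(2 * r, 1.0),
            diameter_um=2 * r, cm_uF_per_cm2=cm, ra_ohm_cm=ra, parent=None,
            channels={ch.LEAK: g_leak})
    }
    # Children in file order; collapse runs of unbranched same-type points.
    children: dict[int, list[int]] = {}
    for idx in order:
        parent = pts[idx][3]
        if parent != -1:
            children.setdefault(parent, []).append(idx)

    def walk(start: int, parent_cid: str) -> None:
        stack = [(c, parent_cid) for c in reversed(children.get(start, []))]
        while stack:
            idx, pcid = stack.pop()
            run = [idx]
            # Extend the run through unbranched chains of the same type.
            while (len(run) < collapse and len(children.get(run[-1], [])) == 1
                   and pts[children[run[-1]][0]][0] == pts[idx][0]):
                run.append(children[run[-1]][0])
            length = 0.0
            dias = []
            prev_xyz = pts[pts[run[0]][3]][1]
            for j in run:
                xyz = pts[j][1]
                length += float(np.linalg.norm(xyz - prev_xyz))
                prev_xyz = xyz
                dias.append(2 * pts[j][2])
            cid = f"swc{run[-1]}"
            comps[cid] = Compartment(
                id=cid, region=_SWC_REGION.get(pts[idx][0], "dend"),
                length_um=max(length, 0.1), diameter_um=float(np.mean(dias)),
                cm_uF_per_cm2=cm, ra_ohm_cm=ra, parent=pcid,
                channels={ch.LEAK: g_leak})
            for c in reversed(children.get(run[-1], [])):
                stack.append((c, cid))

    walk(root, f"swc{root}")
    return NeuronModel(subtype=subtype, compartments=comps,
                       channel_library={ch.LEAK: leak})
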