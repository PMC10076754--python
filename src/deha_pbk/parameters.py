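"""Parameter assembly for the DEHA/MEHA PBK model.

This module owns the numeric parameterisation of one simulated individual:
physiology (organ volumes and blood flows), tissue:blood partition
coefficients and plasma binding, oral-uptake and metabolic kinetics, and
molar masses. It also provides the two in-silico/in-vitro parameterisation
primitives used to build that table:

* :func:`fraction_unbound` — QSPR prediction of the plasma fraction unbound
  from the octanol-water log partition coefficient, valid for chemicals that
  are predominantly uncharged at pH 7.4.
* :func:`intrinsic_clearance` — in vitro to in vivo extrapolation of
  whole-organ intrinsic clearance from a microsomal depletion half-life via
  the microsomal protein yield (MPY) scaling factor.

Units: time h, amounts mg, volumes L, concentrations mg/L, half-lives are
*entered* in minutes and converted once at assembly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "Physiology",
    "PartitionSet",
    "KineticParams",
    "MolarMasses",
    "ParameterSet",
    "ClearanceInputs",
    "fraction_unbound",
    "intrinsic_clearance",
    "default_parameters",
    "load_defaults_config",
]

LN2 = math.log(2.0)


def _load_yaml(name: str) -> dict:
    with resources.files("deha_pbk.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


def fraction_unbound(logP: float) -> float:
    """Plasma fraction unbound predicted from log P(octanol:water).

    fu = 1 / (10**x + 1) with x = 0.4485 * logP - 0.4782, the regression for
    chemicals in a predominantly uncharged state at pH 7.4. Strictly
    decreasing in logP and maps the real line onto (0, 1).
    """
    if not np.all(np.isfinite(logP)):
        raise ValueError("logP must be finite")
    x = 0.4485 * np.asarray(logP, dtype=float) - 0.4782
    out = 1.0 / (10.0 ** x + 1.0)
    return float(out) if np.isscalar(logP) or out.ndim == 0 else out


@dataclass(frozen=True)
class ClearanceInputs:
    """Inputs for scaling a microsomal depletion half-life to whole-organ
    intrinsic clearance."""

    t_half_min: float          # substrate depletion half-life, minutes
    protein_conc_mg_per_ml: float  # incubation protein concentration
    MPY_mg_per_g: float        # microsomal protein yield of the organ
    organ_mass_g: float

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            # a zero yield is a valid degenerate input (no metabolic
            # capacity -> zero clearance); everything else must be positive
            lo_ok = v >= 0 if f.name == "MPY_mg_per_g" else v > 0
            if not lo_ok or not math.isfinite(v):
                raise ValueError(f"{f.name} must be positive and finite, got {v!r}")


def intrinsic_clearance(ci: ClearanceInputs) -> float:
    """Whole-organ in vivo intrinsic clearance, L/h.

    CL = (ln2 / t_half) * (1 / C_protein) * MPY * organ mass

    (ln2/t_half)/C_protein is the in vitro intrinsic clearance in
    mL/min/mg protein; MPY (mg protein per g organ) and the organ mass scale
    it to mL/min for the whole organ; the result is converted to L/h.
    """
    cl_ml_per_min = (LN2 / ci.t_half_min) / ci.protein_conc_mg_per_ml \
        * ci.MPY_mg_per_g * ci.organ_mass_g
    return cl_ml_per_min * 60.0 / 1000.0


@dataclass(frozen=True)
class Physiology:
    """Body size, organ volumes (fraction of BW) and blood flows (fraction
    of cardiac output)."""

    BW: float = 89.0
    VT: float = 0.95
    VLiC: float = 0.0309
    VFaC: float = 0.195
    VGuC: float = 0.015
    VStC: float = 0.0022
    VSpdC: float = 0.607
    VRpdC: float = 0.0371
    VBldC: float = 0.05
    QCC: float = 14.0          # L/h per kg BW
    QHepartC: float = 0.060
    QFaC: float = 0.050
    QGuC: float = 0.149
    QStC: float = 0.011
    QSpdC: float = 0.270
    QRpdC: float = 0.420

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"physiology field {f.name} must be > 0")


@dataclass(frozen=True)
class PartitionSet:
    """Tissue:blood partition coefficients and arterial binding for parent
    (suffix b) and monoester (suffix M)."""

    Pbab: float = 3.0
    Pfab: float = 47.2
    Plib: float = 5.9
    Pgub: float = 7.4
    Pstb: float = 7.4
    Prpdb: float = 3.7
    Pspdb: float = 3.3
    PbaM: float = 1.23
    PfaM: float = 2.00
    PliM: float = 10.7
    PguM: float = 3.08
    PstM: float = 3.08
    PrpdM: float = 2.26
    PspdM: float = 1.83
    fu_DEHA: float = 0.000158
    fu_MEHA: float = 0.007175
    FB_DEHA: float = 0.90
    FB_MEHA: float = 0.90

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name.startswith(("P",)) and v < 0:
                raise ValueError(f"partition coefficient {f.name} must be >= 0")
        for name in ("fu_DEHA", "fu_MEHA"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        for name in ("FB_DEHA", "FB_MEHA"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must lie in [0, 1)")


@dataclass(frozen=True)
class KineticParams:
    """Uptake, metabolism and elimination constants.

    Half-lives in minutes; rates in 1/h; MPY in mg microsomal protein per g
    organ. FracMetab_OH/FracMetab_cx are the fractions of metabolised MEHA
    routed to the 5OH-MEHA and 5cx-MEPA urinary pools.
    """

    T_half_DEHA: float = 3.0
    T_half_DEHA_gut: float = 30.0
    T_half_MEHA: float = 22.8
    MPY: float = 34.0
    MPY_gut: float = 3.9
    protein_conc: float = 0.5
    tissue_density: float = 1.05
    FracAbsorbed: float = 0.627
    FracDOSEHep: float = 0.503
    BELLYPERM: float = 3.72
    GIPERM: float = 14.79
    k_gastric_emptying: float = 1.0
    Lymphlag: float = 2.99
    K1_Lymph: float = 2.54
    FracMetab_OH: float = 0.00089
    FracMetab_cx: float = 0.00375
    K1_OH: float = 2.72
    K1_cx: float = 2.72

    def __post_init__(self):
        if not (0 <= self.FracAbsorbed <= 1):
            raise ValueError("FracAbsorbed must lie in [0, 1]")
        if not (0 <= self.FracDOSEHep <= 1):
            raise ValueError("FracDOSEHep must lie in [0, 1]")
        if self.FracMetab_OH + self.FracMetab_cx > 1:
            raise ValueError("FracMetab_OH + FracMetab_cx must be <= 1")
        for name in ("T_half_DEHA", "T_half_DEHA_gut", "T_half_MEHA", "MPY",
                     "MPY_gut", "protein_conc", "tissue_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("BELLYPERM", "GIPERM", "k_gastric_emptying", "Lymphlag",
                     "K1_Lymph", "FracMetab_OH", "FracMetab_cx", "K1_OH",
                     "K1_cx"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class MolarMasses:
    """Molar masses, g/mol (config-supplied; computed from formulae)."""

    M_DEHA: float = 370.57
    M_MEHA: float = 258.36
    M_5OH: float = 274.35
    M_5cx: float = 288.34
    M_5oxo: float = 272.34
    M_AA: float = 146.14

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"molar mass {f.name} must be > 0")


# map between external parameter names (as used in the prior table, design
# matrices and calibration) and (section, field) of the ParameterSet
_NAME_MAP: dict[str, tuple[str, str]] = {
    "BW": ("physiology", "BW"),
    "VT": ("physiology", "VT"),
    "QCC": ("physiology", "QCC"),
    **{n: ("physiology", n) for n in
       ("VLiC", "VFaC", "VGuC", "VStC", "VSpdC", "VRpdC", "VBldC",
        "QHepartC", "QFaC", "QGuC", "QStC", "QSpdC", "QRpdC")},
    **{n: ("partitions", n) for n in
       ("Pbab", "Pfab", "Plib", "Pgub", "Pstb", "Prpdb", "Pspdb",
        "PbaM", "PfaM", "PliM", "PguM", "PstM", "PrpdM", "PspdM",
        "fu_DEHA", "fu_MEHA", "FB_DEHA", "FB_MEHA")},
    "DEHA_half_life": ("kinetics", "T_half_DEHA"),
    "DEHA_GUT_half_life": ("kinetics", "T_half_DEHA_gut"),
    "MEHA_half_life": ("kinetics", "T_half_MEHA"),
    "protein_conc": ("kinetics", "protein_conc"),
    "tissue_density": ("kinetics", "tissue_density"),
    **{n: ("kinetics", n) for n in
       ("MPY", "MPY_gut", "FracAbsorbed", "FracDOSEHep", "BELLYPERM",
        "GIPERM", "k_gastric_emptying", "Lymphlag", "K1_Lymph",
        "FracMetab_OH", "FracMetab_cx", "K1_OH", "K1_cx")},
}


@dataclass(frozen=True)
class ParameterSet:
    """Complete parameterisation of one simulated individual."""

    physiology: Physiology = field(default_factory=Physiology)
    partitions: PartitionSet = field(default_factory=PartitionSet)
    kinetics: KineticParams = field(default_factory=KineticParams)
    molar: MolarMasses = field(default_factory=MolarMasses)
    label: str = "default"

    # -- derived absolute quantities ------------------------------------
    def volumes_L(self) -> dict[str, float]:
        """Absolute compartment volumes in litres.

        If the drawn volume fractions sum to more than the vascularised
        fraction VT, all fractions are rescaled proportionally onto VT so
        that any draw from the marginal priors yields a physical body
        composition.
        """
        ph = self.physiology
        fr = {"Li": ph.VLiC, "Fa": ph.VFaC, "Gu": ph.VGuC, "St": ph.VStC,
              "Spd": ph.VSpdC, "Rpd": ph.VRpdC, "Bld": ph.VBldC}
        s = sum(fr.values())
        if s > ph.VT:
            fr = {k: v * ph.VT / s for k, v in fr.items()}
        return {k: v * ph.BW for k, v in fr.items()}

    def flows_L_per_h(self) -> dict[str, float]:
        """Absolute organ blood flows in L/h.

        Flow fractions are renormalised to sum to one: any residual cardiac
        output is assigned to the slowly perfused compartment (preserving
        the stated organ flows while conserving total blood flow); if the
        drawn fractions exceed one, all are rescaled proportionally.
        """
        ph = self.physiology
        QC = ph.QCC * ph.BW
        fr = {"Hepart": ph.QHepartC, "Fa": ph.QFaC, "Gu": ph.QGuC,
              "St": ph.QStC, "Spd": ph.QSpdC, "Rpd": ph.QRpdC}
        s = sum(fr.values())
        resid = 1.0 - s
        if resid >= 0.0:
            fr["Spd"] += resid
        else:
            fr = {k: v / s for k, v in fr.items()}
        out = {k: v * QC for k, v in fr.items()}
        out["C"] = QC
        return out

    def organ_mass_g(self, organ: str) -> float:
        return self.volumes_L()[organ] * 1000.0 * self.kinetics.tissue_density

    def clearances_L_per_h(self) -> dict[str, float]:
        """Whole-organ intrinsic clearances: DEHA liver/gut, MEHA liver."""
        k = self.kinetics
        cl = {}
        for key, t_half, mpy, organ in (
                ("DEHA_liver", k.T_half_DEHA, k.MPY, "Li"),
                ("DEHA_gut", k.T_half_DEHA_gut, k.MPY_gut, "Gu"),
                ("MEHA_liver", k.T_half_MEHA, k.MPY, "Li")):
            cl[key] = intrinsic_clearance(ClearanceInputs(
                t_half_min=t_half, protein_conc_mg_per_ml=k.protein_conc,
                MPY_mg_per_g=mpy, organ_mass_g=self.organ_mass_g(organ)))
        return cl

    # -- updates and serialisation --------------------------------------
    def with_updates(self, updates: Mapping[str, float]) -> "ParameterSet":
        """Return a copy with named parameters replaced.

        Names follow the prior-table convention (e.g. ``DEHA_half_life``,
        ``Pbab``, ``FracAbsorbed``); unknown names raise ``KeyError``.
        """
        per_section: dict[str, dict[str, float]] = {}
        for name, value in updates.items():
            try:
                section, fieldname = _NAME_MAP[name]
            except KeyError:
                raise KeyError(f"unknown parameter name: {name!r}") from None
            per_section.setdefault(section, {})[fieldname] = float(value)
        kwargs = {}
        for section, upd in per_section.items():
            kwargs[section] = replace(getattr(self, section), **upd)
        return replace(self, **kwargs)

    def get(self, name: str) -> float:
        section, fieldname = _NAME_MAP[name]
        return getattr(getattr(self, section), fieldname)

    def to_dict(self) -> dict:
        out = {}
        for section in ("physiology", "partitions", "kinetics", "molar"):
            obj = getattr(self, section)
            out[section] = {f.name: getattr(obj, f.name) for f in fields(obj)}
        out["label"] = self.label
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSet":
        return cls(physiology=Physiology(**d["physiology"]),
                   partitions=PartitionSet(**d["partitions"]),
                   kinetics=KineticParams(**d["kinetics"]),
                   molar=MolarMasses(**d["molar"]),
                   label=d.get("label", "unnamed"))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_defaults_config() -> dict:
    """Raw packaged default configuration (unit-suffixed keys)."""
    return _load_yaml("defaults.yaml")


def _strip_units(section: Mapping[str, float]) -> dict[str, float]:
    # YAML keys carry unit suffixes (e.g. BW_kg, K1_OH_per_h); dataclass
    # fields do not. Strip the known suffixes.
    suffixes = ("_L_per_h_per_kg", "_mg_per_ml", "_g_per_ml", "_mg_per_g",
                "_g_per_mol", "_per_h", "_frac", "_min", "_kg", "_h")
    out = {}
    for key, value in section.items():
        name = key
        for suf in suffixes:
            if name.endswith(suf):
                name = name[: -len(suf)]
                break
        out[name] = value
    return out


def default_parameters() -> ParameterSet:
    """The packaged default parameterisation.

    Raises ``ValueError`` listing offending keys if the packaged config does
    not match the parameter schema.
    """
    cfg = load_defaults_config()
    sections = {}
    for section, cls in (("physiology", Physiology),
                         ("partitions", PartitionSet),
                         ("kinetics", KineticParams),
                         ("molar_masses", MolarMasses)):
        raw = _strip_units(cfg[section])
        raw.pop("logP_DEHA", None)
        raw.pop("logP_MEHA", None)
        known = {f.name for f in fields(cls)}
        bad = sorted(set(raw) - known)
        if bad:
            raise ValueError(
                f"unknown keys in packaged config section {section}: {bad}")
        sections[section] = cls(**raw)
    return ParameterSet(physiology=sections["physiology"],
                        partitions=sections["partitions"],
                        kinetics=sections["kinetics"],
                        molar=sections["molar_masses"])
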