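"""Processing of urine-void biomonitoring records.

A volunteer's record is a time-ordered series of urine voids (clock time
since dose, void volume, analyte concentrations). The observable used for
calibration is the *deposition rate*: the analyte mass in a void divided by
the time since the previous void, assigned to the interval midpoint —
a representation that exposes trends far more clearly than raw or
creatinine-corrected concentrations.

The module also computes the fraction of ingested parent excreted as each
metabolite (FUE, molar-mass corrected), the dietary background deposition
of adipic acid (estimated from voids where the specific metabolite
5cx-MEPA has essentially washed out), and the absorption bounds implied by
summing the FUE over the four measured metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import MolarMasses

__all__ = ["UrineVoid", "VolunteerDataset", "DepositionSeries",
           "deposition_rates", "fue", "aa_background", "absorption_bounds",
           "ANALYTES"]

ANALYTES = ("5OH-MEHA", "5cx-MEPA", "5oxo-MEHA", "AA")

_MOLAR_KEY = {"5OH-MEHA": "M_5OH", "5cx-MEPA": "M_5cx",
              "5oxo-MEHA": "M_5oxo", "AA": "M_AA"}


@dataclass(frozen=True)
class UrineVoid:
    """One timed urine collection."""

    t: float                      # h since dose
    volume: float                 # L
    conc: dict                    # analyte -> mg/L

    def __post_init__(self):
        if self.t < 0:
            raise ValueError("void time must be >= 0")
        if self.volume <= 0:
            raise ValueError("void volume must be > 0")
        if any(v < 0 for v in self.conc.values()):
            raise ValueError("concentrations must be >= 0")

    def mass(self, analyte: str) -> float:
        """Analyte mass in the void, mg."""
        return self.conc[analyte] * self.volume


@dataclass
class VolunteerDataset:
    """All voids of one volunteer plus dosing metadata."""

    id: str
    BW: float                     # kg
    dose: float                   # mg per kg BW
    voids: list = field(default_factory=list)

    def __post_init__(self):
        if self.dose <= 0 or self.BW <= 0:
            raise ValueError("dose and BW must be > 0")
        ts = [v.t for v in self.voids]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("voids must be strictly time-ordered")

    @property
    def dose_mg(self) -> float:
        return self.dose * self.BW

    def void_times(self) -> np.ndarray:
        return np.array([v.t for v in self.voids])

    def masses(self, analyte: str) -> np.ndarray:
        """Per-void analyte masses (mg); NaN where not measured."""
        return np.array([v.mass(analyte) if analyte in v.conc else np.nan
                         for v in self.voids])

    # -- long-format CSV schema: volunteer_id,t_h,volume_L,analyte,conc_mg_per_L
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.voids:
            for analyte, conc in v.conc.items():
                rows.append((self.id, v.t, v.volume, analyte, conc))
        return pd.DataFrame(rows, columns=["volunteer_id", "t_h", "volume_L",
                                           "analyte", "conc_mg_per_L"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, volunteer_id: str, BW: float,
                   dose: float) -> "VolunteerDataset":
        sub = df[df["volunteer_id"] == volunteer_id]
        voids = []
        for (t, vol), grp in sub.groupby(["t_h", "volume_L"], sort=True):
            conc = dict(zip(grp["analyte"], grp["conc_mg_per_L"]))
            voids.append(UrineVoid(t=float(t), volume=float(vol), conc=conc))
        voids.sort(key=lambda v: v.t)
        return cls(id=volunteer_id, BW=BW, dose=dose, voids=voids)


@dataclass
class DepositionSeries:
    """Midpoint-assigned average deposition rates derived from voids."""

    analyte: str
    midpoints: np.ndarray         # h
    rates: np.ndarray             # mg/h
    t_start: np.ndarray           # interval starts, h
    t_end: np.ndarray             # interval ends (void times), h

    def __post_init__(self):
        if np.any(np.diff(self.midpoints) <= 0):
            raise ValueError("midpoints must be strictly increasing")

    def total_mass(self) -> float:
        """Sum of rate x interval width = total excreted mass, mg."""
        return float(np.sum(self.rates * (self.t_end - self.t_start)))


def deposition_rates(ds: VolunteerDataset, analyte: str,
                     t_first_start: float = 0.0) -> DepositionSeries:
    """Deposition-rate series for one analyte.

    rate_i = conc_i * volume_i / (t_i - t_{i-1}), assigned to the interval
    midpoint. The first void's interval starts at the dose time (default 0).
    Voids without a measurement of the analyte are skipped, with the next
    measured void's interval extending back across them.
    """
    voids = [v for v in ds.voids if analyte in v.conc]
    if len(voids) < 2:
        raise ValueError(f"need >= 2 voids with {analyte} measurements")
    t_prev = t_first_start
    mids, rates, starts, ends = [], [], [], []
    for v in voids:
        if v.t <= t_prev:
            raise ValueError("void times must increase strictly")
        rates.append(v.mass(analyte) / (v.t - t_prev))
        mids.append(0.5 * (t_prev + v.t))
        starts.append(t_prev)
        ends.append(v.t)
        t_prev = v.t
    return DepositionSeries(analyte=analyte, midpoints=np.array(mids),
                            rates=np.array(rates), t_start=np.array(starts),
                            t_end=np.array(ends))


def fue(ds: VolunteerDataset, analyte: str, molar: MolarMasses,
        background_total_mg: float = 0.0) -> float:
    """Fraction of the ingested parent excreted in urine as ``analyte``.

    FUE = (1/D) * sum_i m_i * (M_DEHA / M_analyte), with an optional total
    background mass subtracted before conversion (used for adipic acid).
    """
    masses = ds.masses(analyte)
    total = float(np.nansum(masses))
    # tolerate rounding when the signal is pure background
    if background_total_mg > total * (1.0 + 1e-9) + 1e-12:
        raise ValueError(
            f"background ({background_total_mg:.4g} mg) exceeds the total "
            f"excreted {analyte} mass ({total:.4g} mg)")
    background_total_mg = min(background_total_mg, total)
    m_ratio = molar.M_DEHA / getattr(molar, _MOLAR_KEY[analyte])
    return (total - background_total_mg) * m_ratio / ds.dose_mg


def aa_background(ds: VolunteerDataset, window_h: float = 24.0,
                  threshold: float = 0.01,
                  select_times=None) -> tuple[float, float]:
    """Background adipic-acid deposition: (total over the window in mg,
    rate in mg/h).

    Voids within the measurement window whose 5cx-MEPA deposition rate has
    fallen below ``threshold`` of its maximum are taken as representing
    dietary background alone; the AA rate averaged over those voids times
    the window length gives the total background deposition. If the
    specific metabolite never washes out far enough for any void to
    qualify, pass the void times to use explicitly via ``select_times``.
    """
    aa = deposition_rates(ds, "AA")
    if select_times is not None:
        wanted = set(np.round(np.asarray(select_times, float), 9))
        sel = [(t, r) for t, r in zip(aa.t_end, aa.rates)
               if round(float(t), 9) in wanted]
        if len(sel) != len(wanted):
            raise ValueError("select_times must match AA void times")
    else:
        cx = deposition_rates(ds, "5cx-MEPA")
        cx_at = dict(zip(cx.t_end, cx.rates))
        cutoff = threshold * cx.rates.max()
        sel = [(t, r) for t, r in zip(aa.t_end, aa.rates)
               if t <= window_h and t in cx_at and cx_at[t] < cutoff]
    if not sel:
        raise ValueError(
            "no voids qualify for background estimation (5cx-MEPA never "
            f"falls below {threshold:.0%} of its maximum within "
            f"{window_h} h); select background time points manually via "
            "select_times")
    rate = float(np.mean([r for _, r in sel]))
    return rate * window_h, rate


def absorption_bounds(fues: dict) -> tuple[float, dict]:
    """Absorption lower bound and per-analyte excretion-fraction bounds.

    The lower bound on the fraction of ingested DEHA absorbed is the sum of
    the FUE over the four measured metabolites. For each analyte, the
    fraction of *absorbed* DEHA it represents is bounded by (FUE,
    FUE / sum(FUE)) — the complete-absorption and lower-bound-absorption
    cases respectively.
    """
    total = sum(fues.values())
    if total == 0:
        raise ValueError("all FUE are zero; absorption bounds undefined")
    bounds = {}
    for analyte, f in fues.items():
        pair = (f, f / total)
        bounds[analyte] = (min(pair), max(pair))
    return total, bounds
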