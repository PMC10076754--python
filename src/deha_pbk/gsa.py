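"""Global sensitivity analysis: Latin hypercube uncertainty screening and
Morris elementary-effects screening.

The LHS stage draws a space-filling sample from the parameter
distributions and runs the PBK model over it to assess the bounding
behaviour of the four observable outputs (parent and monoester blood
concentrations, and the urinary deposition rates of the two specific
metabolites). The Morris stage varies each parameter one at a time along
r randomised trajectories over a grid on [0,1]^k (mapped linearly onto
each parameter's 2.5th-97.5th percentile range), at a cost of r*(k+1)
model runs; per output measure it reports mu* (mean absolute elementary
effect), sigma (SD of effects, flagging interaction/nonlinearity), their
Euclidean distance from the origin, and that distance normalised so the
most influential parameter per measure scores one. Parameters whose
normalised distance exceeds a threshold for at least one measure are
retained for calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .model import SimulationError, simulate
from .parameters import ParameterSet, default_parameters

__all__ = ["Design", "MorrisResult", "lhs_design", "morris_design",
           "elementary_effects", "morris_screen", "screen_filter",
           "run_ensemble", "pbk_measures", "MEASURE_NAMES"]

# the twelve screening measures: blood concentrations at 0.5 and 5 h,
# urinary deposition rates at 1, 3, 5 and 10 h
MEASURE_TIMES_BLOOD = (0.5, 5.0)
MEASURE_TIMES_URINE = (1.0, 3.0, 5.0, 10.0)
MEASURE_NAMES = tuple(
    [f"CV_DEHA@{t}h" for t in MEASURE_TIMES_BLOOD]
    + [f"CV_MEHA@{t}h" for t in MEASURE_TIMES_BLOOD]
    + [f"RUrine_OH@{t}h" for t in MEASURE_TIMES_URINE]
    + [f"RUrine_cx@{t}h" for t in MEASURE_TIMES_URINE])


@dataclass
class Design:
    """A matrix of parameter draws (rows = model runs)."""

    frame: pd.DataFrame
    provenance: str               # 'lhs' | 'morris'
    seed: int
    unit: np.ndarray | None = field(default=None, repr=False)
    trajectories: np.ndarray | None = None    # Morris: row -> trajectory id
    delta: float | None = None                # Morris: grid jump in [0,1]

    @property
    def n_runs(self) -> int:
        return len(self.frame)

    @property
    def names(self) -> list:
        return list(self.frame.columns)


def lhs_design(priors, n: int, seed: int,
               truncation: tuple = (0.05, 0.95)) -> Design:
    """Latin hypercube sample of the priors: exactly one point per
    equiprobable stratum per parameter, mapped through each (truncated)
    quantile function."""
    if n < 2:
        raise ValueError("n must be >= 2")
    sampler = qmc.LatinHypercube(d=len(priors), seed=seed)
    u = sampler.random(n)
    cols = {}
    for i, spec in enumerate(priors):
        lo, hi = truncation
        q = lo + u[:, i] * (hi - lo) if spec.truncation is None \
            and spec.family in ("normal", "lognormal") else u[:, i]
        lo_s, hi_s = spec.support()
        if np.isclose(lo_s, hi_s):
            cols[spec.name] = np.full(n, lo_s)
            import warnings
            warnings.warn(f"degenerate prior for {spec.name}; held constant")
        else:
            cols[spec.name] = spec.ppf(q)
    return Design(frame=pd.DataFrame(cols), provenance="lhs", seed=seed,
                  unit=u)


def morris_design(ranges: dict, r: int = 7, levels: int = 4,
                  seed: int = 0) -> Design:
    """Morris one-at-a-time trajectory design.

    ``ranges`` maps parameter name -> (lower, upper); the design has
    exactly r*(k+1) rows for k parameters. Each trajectory starts from a
    random grid point and changes one randomly-ordered parameter per step
    by the grid jump delta = levels / (2*(levels-1)).
    """
    names = list(ranges)
    k = len(names)
    if k < 1 or r < 1:
        raise ValueError("need k >= 1 parameters and r >= 1 trajectories")
    for nm, (lo, hi) in ranges.items():
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"invalid range for parameter {nm!r}: "
                             f"({lo}, {hi})")
    rng = np.random.default_rng(seed)
    delta = levels / (2.0 * (levels - 1))
    grid = np.arange(0, levels) / (levels - 1)
    unit_rows = []
    traj_ids = []
    for t in range(r):
        x = rng.choice(grid, size=k)
        direction = np.ones(k)
        # step down where a positive jump would leave the unit cube
        direction[x + delta > 1.0 + 1e-12] = -1.0
        order = rng.permutation(k)
        unit_rows.append(x.copy())
        traj_ids.append(t)
        for i in order:
            x = x.copy()
            x[i] += direction[i] * delta
            unit_rows.append(x.copy())
            traj_ids.append(t)
    unit = np.clip(np.array(unit_rows), 0.0, 1.0)
    lo = np.array([ranges[nm][0] for nm in names])
    hi = np.array([ranges[nm][1] for nm in names])
    frame = pd.DataFrame(lo + unit * (hi - lo), columns=names)
    return Design(frame=frame, provenance="morris", seed=seed, unit=unit,
                  trajectories=np.array(traj_ids), delta=delta)


def elementary_effects(design: Design, y: np.ndarray) -> pd.DataFrame:
    """Elementary effects from trajectory-ordered model output.

    ``y`` has shape (n_runs,) or (n_runs, n_measures). Effects are scaled
    to the unit parameter range (divide by the signed jump in [0,1]
    coordinates). Trajectories containing non-finite output are discarded
    with a warning. Returns a long frame: parameter, measure, trajectory,
    effect."""
    if design.provenance != "morris":
        raise ValueError("elementary effects require a Morris design")
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] == 1:
        y = y.T
    n_meas = y.shape[1]
    names = design.names
    rows = []
    for t in np.unique(design.trajectories):
        sel = np.flatnonzero(design.trajectories == t)
        if not np.all(np.isfinite(y[sel])):
            import warnings
            warnings.warn(f"trajectory {t} contains failed runs; discarded")
            continue
        for a, b in zip(sel, sel[1:]):
            du = design.unit[b] - design.unit[a]
            i = int(np.argmax(np.abs(du)))
            step = du[i]
            for m in range(n_meas):
                rows.append((names[i], m, int(t),
                             (y[b, m] - y[a, m]) / step))
    return pd.DataFrame(rows, columns=["parameter", "measure", "trajectory",
                                       "effect"])


@dataclass
class MorrisResult:
    """Per-parameter, per-measure screening statistics."""

    table: pd.DataFrame       # parameter, measure, mu_star, sigma,
    #                           distance, norm_distance
    measure_names: list

    def max_norm_distance(self) -> pd.Series:
        return self.table.groupby("parameter")["norm_distance"].max()


def morris_screen(design: Design, y: np.ndarray,
                  measure_names=None) -> MorrisResult:
    """Summarise elementary effects into mu*, sigma, Euclidean distance
    from the origin and the per-measure normalised distance (max = 1)."""
    eff = elementary_effects(design, y)
    g = eff.groupby(["parameter", "measure"])["effect"]
    table = pd.DataFrame({
        "mu_star": g.apply(lambda s: np.mean(np.abs(s))),
        "sigma": g.std(ddof=1).fillna(0.0)}).reset_index()
    table["distance"] = np.hypot(table["mu_star"], table["sigma"])
    table["norm_distance"] = table.groupby("measure")["distance"] \
        .transform(lambda s: s / s.max() if s.max() > 0 else 0.0)
    if measure_names is None:
        measure_names = sorted(table["measure"].unique())
    return MorrisResult(table=table, measure_names=list(measure_names))


def screen_filter(result: MorrisResult, threshold: float = 0.1) -> list:
    """Parameters whose normalised Euclidean distance exceeds the
    threshold for at least one measure."""
    mx = result.max_norm_distance()
    return sorted(mx.index[mx > threshold])


def pbk_measures(updates: dict, base: ParameterSet | None = None,
                 dose_mg_per_kg: float = 0.112) -> np.ndarray:
    """The twelve screening measures for one parameter draw.

    Default dose corresponds to a 10 mg oral dose at the default 89 kg
    body weight. Returns NaN on solver failure so that the containing
    trajectory can be discarded."""
    base = base if base is not None else default_parameters()
    times = np.array(sorted(set(MEASURE_TIMES_BLOOD + MEASURE_TIMES_URINE)))
    t_eval = np.concatenate(([0.0], times))
    try:
        params = base.with_updates(updates)
        out = simulate(params, dose_mg_per_kg, t_eval=t_eval,
                       rtol=1e-7, atol=1e-11)
    except (SimulationError, ValueError):
        return np.full(len(MEASURE_NAMES), np.nan)
    at = {t: i for i, t in enumerate(out.time)}
    vals = ([out.CV_DEHA[at[t]] for t in MEASURE_TIMES_BLOOD]
            + [out.CV_MEHA[at[t]] for t in MEASURE_TIMES_BLOOD]
            + [out.RUrine_OH[at[t]] for t in MEASURE_TIMES_URINE]
            + [out.RUrine_cx[at[t]] for t in MEASURE_TIMES_URINE])
    return np.array(vals)


def run_ensemble(design: Design, dose_mg_per_kg: float = 0.112,
                 base: ParameterSet | None = None, duration: float = 48.0,
                 grid_step: float = 0.1,
                 outputs=("CV_DEHA", "CV_MEHA", "RUrine_OH", "RUrine_cx"),
                 max_failure_frac: float = 0.05) -> dict:
    """Run the model over every design row; per output, per-run curves and
    the pointwise min/max envelope. Failed rows are recorded, and more
    than ``max_failure_frac`` failures aborts with a diagnostic."""
    base = base if base is not None else default_parameters()
    curves = {name: [] for name in outputs}
    failed = []
    time = None
    for i, row in design.frame.iterrows():
        try:
            params = dc_replace(base.with_updates(row.to_dict()),
                                label=f"design_row_{i}")
            out = simulate(params, dose_mg_per_kg, duration=duration,
                           grid_step=grid_step, rtol=1e-7, atol=1e-11)
        except (SimulationError, ValueError) as exc:
            failed.append((i, str(exc)))
            for name in outputs:
                curves[name].append(None)
            continue
        time = out.time
        for name in outputs:
            curves[name].append(getattr(out, name))
    if len(failed) > max_failure_frac * design.n_runs:
        raise SimulationError(
            f"{len(failed)}/{design.n_runs} design rows failed "
            f"(first: {failed[0]})", "ensemble")
    result = {"time": time, "failed": failed}
    for name in outputs:
        ok = [c for c in curves[name] if c is not None]
        arr = np.vstack(ok)
        result[name] = {"curves": arr, "lo": arr.min(axis=0),
                        "hi": arr.max(axis=0)}
    return result
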