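"""Prior/uncertainty distributions for model parameters.

Each parameter carries one :class:`PriorSpec` describing its distribution
family (normal, lognormal, uniform or half-normal), an optional percentile
truncation (physiological distributions are truncated at their 5th/95th
percentiles), and whether the parameter is shared across volunteers
(``global``) or volunteer-specific (``local``).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = ["PriorSpec", "prior_table", "sample_prior", "morris_parameter_names"]

_FAMILIES = ("normal", "lognormal", "uniform", "halfnormal")


@dataclass(frozen=True)
class PriorSpec:
    """One named parameter's distribution, truncation and scope."""

    name: str
    family: str
    params: dict
    scope: str = "global"              # global | local
    calibrated: bool = False
    truncation: tuple[float, float] | None = None  # percentile pair
    # optional distinct distribution for uncertainty/sensitivity screening
    # (family/params dict), where it differs from the calibration prior
    screening: dict | None = None

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r} for {self.name}")
        if self.scope not in ("global", "local"):
            raise ValueError(f"scope must be global|local for {self.name}")
        if self.family == "uniform":
            lo, up = self.params["lower"], self.params["upper"]
            if not (np.isfinite(lo) and np.isfinite(up) and lo < up):
                raise ValueError(f"uniform bounds must be finite and ordered "
                                 f"for {self.name}")
        elif self.family == "normal" and self.params["sd"] <= 0:
            raise ValueError(f"sd must be > 0 for {self.name}")
        elif self.family == "lognormal" and self.params["sdlog"] <= 0:
            raise ValueError(f"sdlog must be > 0 for {self.name}")
        elif self.family == "halfnormal" and self.params["sd"] <= 0:
            raise ValueError(f"sd must be > 0 for {self.name}")
        if self.truncation is not None:
            lo, hi = self.truncation
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"truncation percentiles out of order for "
                                 f"{self.name}")
        # cache the frozen base distribution, the truncated support and the
        # truncation log-normaliser (logpdf is on the sampler's hot path)
        object.__setattr__(self, "_frozen", self._make_base())
        if self.truncation is None:
            sup = self._frozen.support()
            lognorm = 0.0
        else:
            sup = tuple(self._frozen.ppf(self.truncation))
            lognorm = float(np.log(self.truncation[1] - self.truncation[0]))
        object.__setattr__(self, "_support", (float(sup[0]), float(sup[1])))
        object.__setattr__(self, "_lognorm", lognorm)

    def _make_base(self):
        p = self.params
        if self.family == "normal":
            return stats.norm(p["mean"], p["sd"])
        if self.family == "lognormal":
            return stats.lognorm(s=p["sdlog"], scale=np.exp(p["meanlog"]))
        if self.family == "uniform":
            return stats.uniform(p["lower"], p["upper"] - p["lower"])
        return stats.halfnorm(scale=p["sd"])

    def support(self) -> tuple[float, float]:
        """Lower/upper bounds after truncation (may be infinite)."""
        return self._support

    def ppf(self, q):
        """Quantile function of the (truncated) distribution."""
        if self.truncation is None:
            return self._frozen.ppf(q)
        lo, hi = self.truncation
        return self._frozen.ppf(lo + np.asarray(q) * (hi - lo))

    def logpdf(self, x):
        """Log density of the (truncated) distribution; analytic closed
        forms, vectorised, -inf outside the support."""
        x = np.asarray(x, dtype=float)
        p = self.params
        c = -0.9189385332046727  # -log(sqrt(2*pi))
        with np.errstate(divide="ignore", invalid="ignore"):
            if self.family == "normal":
                z = (x - p["mean"]) / p["sd"]
                out = c - np.log(p["sd"]) - 0.5 * z * z
            elif self.family == "lognormal":
                z = (np.log(x) - p["meanlog"]) / p["sdlog"]
                out = np.where(x > 0,
                               c - np.log(x * p["sdlog"]) - 0.5 * z * z,
                               -np.inf)
            elif self.family == "uniform":
                out = np.full_like(x, -np.log(p["upper"] - p["lower"]))
            else:  # halfnormal
                z = x / p["sd"]
                out = np.log(2.0) + c - np.log(p["sd"]) - 0.5 * z * z
        lo, hi = self._support
        out = np.where((x >= lo) & (x <= hi), out - self._lognorm, -np.inf)
        return out if out.ndim else float(out)

    def sample(self, n: int, rng: np.random.Generator):
        return self.ppf(rng.uniform(size=n))

    def median(self) -> float:
        return float(self.ppf(0.5))

    def range_95(self) -> tuple[float, float]:
        """2.5th-97.5th percentile range (screening ranges)."""
        return float(self.ppf(0.025)), float(self.ppf(0.975))

    def screening_spec(self) -> "PriorSpec":
        """The distribution used for LHS/Morris screening (the calibration
        prior itself unless a distinct screening distribution is given)."""
        if self.screening is None:
            return self
        return PriorSpec(name=self.name, scope=self.scope,
                         calibrated=self.calibrated, **self.screening)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["truncation"] is not None:
            d["truncation"] = list(d["truncation"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        d = dict(d)
        if d.get("truncation") is not None:
            d["truncation"] = tuple(d["truncation"])
        return cls(**d)


def _load_prior_config() -> dict:
    with resources.files("deha_pbk.data").joinpath("priors.yaml").open() as fh:
        return yaml.safe_load(fh)


def prior_table() -> list[PriorSpec]:
    """The packaged distribution table (calibration priors and screening
    distributions). Raises on duplicate names."""
    cfg = _load_prior_config()
    specs = [PriorSpec.from_dict(row) for row in cfg["priors"]]
    names = [s.name for s in specs]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate prior names: {sorted(dupes)}")
    return specs


def morris_parameter_names() -> list[str]:
    """Names of the parameters varied in elementary-effects screening."""
    return list(_load_prior_config()["morris_parameters"])


def screening_table() -> list[PriorSpec]:
    """Screening distributions for the 52 screened parameters, in the
    declared order (the calibration prior unless a distinct screening
    distribution is configured)."""
    by_name = {s.name: s for s in prior_table()}
    return [by_name[n].screening_spec() for n in morris_parameter_names()]


def sample_prior(priors: Sequence[PriorSpec], n: int,
                 seed: int | np.random.Generator) -> pd.DataFrame:
    """Independent draws from each prior; reproducible given the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    return pd.DataFrame({s.name: s.sample(n, rng) for s in priors})
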