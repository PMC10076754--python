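"""Blocked random-walk Metropolis sampling.

A small, dependency-free MCMC core used for posterior inference. The
target is supplied as a set of additive log-density *parts* (e.g. the
joint prior plus one likelihood part per volunteer) together with a map
from each update block to the parts it affects, so that proposals only
recompute the simulations they invalidate. Proposal scales adapt per block
during a discarded burn-in (Robbins-Monro on the log-scale, targeting the
standard random-walk acceptance rate); blocks may optionally propose
multiplicatively (log-scale random walk, with the Hastings correction) —
used for strictly positive scale parameters such as error SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Chain", "BlockSpec", "block_rwm"]


@dataclass(frozen=True)
class BlockSpec:
    """One update block: parameter indices, affected part indices, and
    whether proposals are on the log scale."""

    indices: np.ndarray
    affected_parts: tuple
    log_scale: bool = False
    name: str = ""


@dataclass
class Chain:
    """Thinned MCMC output with provenance metadata."""

    draws: pd.DataFrame
    logpost: np.ndarray
    n_iter: int
    thin: int
    seed: int
    burn_frac: float
    acceptance: dict
    param_names: list

    @property
    def n_burn_retained(self) -> int:
        return int(np.floor(len(self.draws) * self.burn_frac))

    def retained(self, discard_burn: bool = True) -> pd.DataFrame:
        """Retained draws; by default the burn-in fraction is discarded."""
        return self.draws.iloc[self.n_burn_retained:] if discard_burn \
            else self.draws

    def mode_index(self, discard_burn: bool = True) -> int:
        lp = self.logpost[self.n_burn_retained:] if discard_burn \
            else self.logpost
        off = self.n_burn_retained if discard_burn else 0
        return int(np.argmax(lp)) + off

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_iter={self.n_iter} thin={self.thin} "
                     f"seed={self.seed} burn_frac={self.burn_frac}\n")
            df = self.draws.copy()
            df["log_posterior"] = self.logpost
            df.to_csv(fh, index=False)


def block_rwm(parts_fn, x0: np.ndarray, blocks: list, n_parts: int,
              param_names: list, n_iter: int, thin: int = 10,
              seed: int = 0, scales: np.ndarray | None = None,
              burn_frac: float = 0.2, adapt: bool = True,
              target_accept: float = 0.25, adapt_batch: int = 50) -> Chain:
    """Run a component-blocked random-walk Metropolis chain.

    ``parts_fn(x, dirty, parts_old)`` must return the full parts vector
    with the entries listed in ``dirty`` recomputed (others may be copied
    from ``parts_old``). The posterior is ``sum(parts)``; any ``-inf`` part
    rejects the move. Identical seeds yield identical retained samples.
    """
    if n_iter < thin:
        raise ValueError("n_iter must be >= thin")
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    n = x.size
    if scales is None:
        scales = np.full(n, 0.1)
    scales = np.asarray(scales, dtype=float).copy()
    log_factor = np.zeros(len(blocks))

    all_parts = list(range(n_parts))
    parts = parts_fn(x, all_parts, np.full(n_parts, -np.inf))
    if not np.isfinite(parts.sum()):
        raise ValueError("initial point has non-finite log posterior")

    n_keep = n_iter // thin
    draws = np.empty((n_keep, n))
    lp_trace = np.empty(n_keep)
    n_prop = np.zeros(len(blocks), dtype=int)
    n_acc = np.zeros(len(blocks), dtype=int)
    batch_prop = np.zeros(len(blocks), dtype=int)
    batch_acc = np.zeros(len(blocks), dtype=int)
    n_burn_iter = int(np.floor(n_iter * burn_frac))
    kept = 0

    for it in range(n_iter):
        for b, blk in enumerate(blocks):
            idx = blk.indices
            eps = rng.normal(size=idx.size) * scales[idx] \
                * np.exp(log_factor[b])
            x_new = x.copy()
            hastings = 0.0
            if blk.log_scale:
                if np.any(x[idx] <= 0):
                    continue
                x_new[idx] = x[idx] * np.exp(eps)
                hastings = float(np.sum(np.log(x_new[idx]) - np.log(x[idx])))
            else:
                x_new[idx] = x[idx] + eps
            dirty = list(blk.affected_parts)
            parts_new = parts_fn(x_new, dirty, parts)
            delta = parts_new[dirty].sum() - parts[dirty].sum()
            n_prop[b] += 1
            batch_prop[b] += 1
            if np.isfinite(delta) and \
                    np.log(rng.uniform()) < delta + hastings:
                x = x_new
                parts = parts_new
                n_acc[b] += 1
                batch_acc[b] += 1
            if adapt and it < n_burn_iter and batch_prop[b] >= adapt_batch:
                rate = batch_acc[b] / batch_prop[b]
                log_factor[b] += np.clip(rate - target_accept, -0.5, 0.5)
                batch_prop[b] = batch_acc[b] = 0
        if (it + 1) % thin == 0:
            draws[kept] = x
            lp_trace[kept] = parts.sum()
            kept += 1

    return Chain(draws=pd.DataFrame(draws[:kept], columns=param_names),
                 logpost=lp_trace[:kept], n_iter=n_iter, thin=thin,
                 seed=seed, burn_frac=burn_frac,
                 acceptance={blk.name or f"block{i}": (n_acc[i] / n_prop[i]
                                                       if n_prop[i] else 0.0)
                             for i, blk in enumerate(blocks)},
                 param_names=list(param_names))
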