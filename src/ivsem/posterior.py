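"""Posterior draw containers, summaries and simple-slopes evaluation.

Point estimates are posterior medians; interval estimates are 95% highest
posterior density (HPD) intervals; evidence against a sign is reported as a
one-tailed probability — for a positive median the share of draws below
zero, for a negative median the share above zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .utils import hpd_interval

__all__ = ["PosteriorDraws", "posterior_summary", "simple_slopes"]


@dataclass
class PosteriorDraws:
    """Retained MCMC draws: ``values`` has shape (chains, draws, params)."""

    names: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (chains, draws, params)")
        if self.values.shape[2] != len(self.names):
            raise ValueError("parameter axis does not match names")

    @property
    def n_chains(self) -> int:
        return self.values.shape[0]

    @property
    def n_draws(self) -> int:
        """Total retained draws across chains."""
        return self.values.shape[0] * self.values.shape[1]

    def combined(self) -> np.ndarray:
        """Draws pooled across chains, shape (chains*draws, params)."""
        return self.values.reshape(-1, len(self.names))

    def select(self, names: list[str]) -> np.ndarray:
        idx = [self.names.index(n) for n in names]
        return self.combined()[:, idx]

    def per_chain(self, name: str) -> np.ndarray:
        """Shape (chains, draws) trace of one parameter."""
        return self.values[:, :, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """One row per retained draw with chain and iteration labels."""
        c, d, p = self.values.shape
        df = pd.DataFrame(self.combined(), columns=self.names)
        df.insert(0, "chain", np.repeat(np.arange(c), d))
        df.insert(1, "iteration", np.tile(np.arange(d), c))
        return df

    @classmethod
    def concat(cls, sets: list["PosteriorDraws"]) -> "PosteriorDraws":
        """Equal-weight mixture of several draw sets (stacked on the chain axis)."""
        if not sets:
            raise ValueError("no draw sets to concatenate")
        names = sets[0].names
        for s in sets[1:]:
            if s.names != names:
                raise ValueError("parameter sets differ across draw sets")
        d_min = min(s.values.shape[1] for s in sets)
        values = np.concatenate([s.values[:, :d_min, :] for s in sets], axis=0)
        return cls(names=names, values=values,
                   meta={**sets[0].meta, "pooled_from": len(sets)})


def _one_tailed(x: np.ndarray, median: float) -> float:
    """Share of draws on the side of zero opposite to the median's sign.

    Draws exactly at zero count as half, so a symmetric posterior at zero
    reports 0.5 rather than an arbitrary 0 or 1.
    """
    n = x.size
    ties = np.count_nonzero(x == 0.0)
    if median >= 0:
        opp = np.count_nonzero(x < 0.0)
    else:
        opp = np.count_nonzero(x > 0.0)
    return (opp + 0.5 * ties) / n


def posterior_summary(draws: PosteriorDraws, prob: float = 0.95,
                      min_draws: int = 1000) -> pd.DataFrame:
    """Per-parameter median, HPD bounds, one-tailed probability and SD."""
    flat = draws.combined()
    if flat.shape[0] == 0:
        raise ValueError("no retained draws to summarize")
    if flat.shape[0] < min_draws:
        raise ValueError(
            f"only {flat.shape[0]} retained draws; at least {min_draws} required "
            "for stable interval estimates (pass min_draws to override)")
    rows = []
    for j, name in enumerate(draws.names):
        x = flat[:, j]
        med = float(np.median(x))
        lo, hi = hpd_interval(x, prob)
        rows.append({
            "parameter": name,
            "median": med,
            "hpd_lower": lo,
            "hpd_upper": hi,
            "one_tailed_p": _one_tailed(x, med),
            "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
            "n_draws": x.size,
        })
    return pd.DataFrame(rows).set_index("parameter")


def simple_slopes(beta_aele, beta_interaction, gi_values,
                  prob: float = 0.95) -> pd.DataFrame:
    """Conditional effect of one adverse event on the outcome at fixed
    (centered) investment levels: slope(g) = beta_aele + beta_interaction * g.

    ``beta_aele`` / ``beta_interaction`` may be scalars (point slopes only)
    or 1-d arrays of posterior draws, in which case each slope carries the
    median and 95% HPD band of its per-draw distribution.
    """
    gi = np.atleast_1d(np.asarray(gi_values, dtype=float))
    if gi.size == 0:
        raise ValueError("empty grid of investment values")
    ba = np.asarray(beta_aele, dtype=float)
    bi = np.asarray(beta_interaction, dtype=float)
    rows = []
    for g in gi:
        s = ba + bi * g
        if s.ndim == 0:
            rows.append({"gi_c": g, "slope": float(s),
                         "hpd_lower": float(s), "hpd_upper": float(s)})
        else:
            lo, hi = hpd_interval(s, prob)
            rows.append({"gi_c": g, "slope": float(np.median(s)),
                         "hpd_lower": lo, "hpd_upper": hi})
    return pd.DataFrame(rows)
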