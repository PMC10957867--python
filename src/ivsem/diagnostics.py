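"""Identification and convergence checks for the structural IV model.

Three identification screens, each reported in the familiar
chi-square/F style:

* relevance — joint Wald test of the instrument block in each first-stage
  equation, converted to an F statistic (F = W/q); F > 10 flags a strong
  instrument set, below that the instruments are weak and estimates
  imprecise;
* exclusion — joint Wald test that the direct instrument→outcome effects
  are zero, available from a ``mode="direct"`` fit;
* endogeneity — joint Wald test that the two error covariances between
  the endogenous predictors' errors and the outcome error are zero,
  available from a ``mode="covariance"`` fit.  Rejection indicates the
  naive regression would be confounded.

Wald tests on a Bayesian fit use the posterior mean and posterior
covariance of the restricted subvector — a normal approximation to the
joint posterior, and approximate by construction.

Convergence uses the original Gelman–Rubin potential scale reduction
factor (between- vs within-chain variance; no rank normalization, no
chain splitting unless requested); values below 1.1 indicate good
convergence, below 1.2 acceptable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .posterior import PosteriorDraws

__all__ = [
    "WaldResult", "FResult", "PsrfResult", "DiagnosticsReport",
    "wald_test", "wald_to_f", "relevance_f", "endogeneity_test",
    "exclusion_test", "psrf",
]

F_STRENGTH_THRESHOLD = 10.0


@dataclass
class WaldResult:
    statistic: float
    df: int
    pvalue: float

    def __iter__(self):
        return iter((self.statistic, self.df, self.pvalue))


@dataclass
class FResult:
    f: float
    df: int
    strong: bool

    def __iter__(self):
        return iter((self.f, self.df, self.strong))


def wald_test(estimates, covariance, restriction_idx=None) -> WaldResult:
    """Joint Wald test that a subvector of estimates is zero.

    chi2 = theta' V^{-1} theta over the restricted entries; df equals the
    number of restrictions; p from the chi-square upper tail.
    """
    theta = np.asarray(estimates, dtype=float).ravel()
    V = np.asarray(covariance, dtype=float)
    if V.ndim == 0:
        V = V.reshape(1, 1)
    if restriction_idx is not None:
        idx = list(restriction_idx)
        theta = theta[idx]
        V = V[np.ix_(idx, idx)]
    q = theta.size
    if q == 0:
        raise ValueError("no restrictions to test")
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError("restricted covariance block is singular or not "
                         "positive definite") from exc
    z = np.linalg.solve(L, theta)
    w = float(z @ z)
    return WaldResult(statistic=w, df=q, pvalue=float(stats.chi2.sf(w, q)))


def wald_to_f(w: float, q: int) -> FResult:
    """Asymptotic Wald→F conversion, F = W/q, with the F>10 strength flag."""
    if q < 1:
        raise ValueError("number of restrictions q must be >= 1")
    if w < 0:
        raise ValueError("Wald statistic must be non-negative")
    f = w / q
    return FResult(f=float(f), df=q, strong=bool(f > F_STRENGTH_THRESHOLD))


def _posterior_block(fit, names):
    """Posterior mean and covariance of a named subvector of draws."""
    sub = fit.draws_.select(list(names))
    return sub.mean(axis=0), np.cov(sub, rowvar=False)


def relevance_f(fit) -> dict[str, FResult]:
    """First-stage instrument strength per endogenous predictor.

    For a Bayesian fit: Wald test of the instrument coefficients in that
    first-stage equation (posterior normal approximation) converted to F.
    For a 2SLS fit the directly computed partial first-stage F is used.
    """
    if hasattr(fit, "first_stage_f_"):        # 2SLS path
        return {name: FResult(f=f, df=q, strong=f > F_STRENGTH_THRESHOLD)
                for name, (f, q, _) in fit.first_stage_f_.items()}
    out = {}
    for endog_name in fit.draws_.meta["endog"]:
        names = [f"{endog_name}~{z}" for z in fit.draws_.meta["instruments"]]
        mean, cov = _posterior_block(fit, names)
        w = wald_test(mean, cov)
        out[endog_name] = wald_to_f(w.statistic, w.df)
    return out


def endogeneity_test(fit) -> WaldResult:
    """Joint Wald test (df=2) that the error covariances between each
    endogenous predictor and the outcome are zero."""
    if fit.draws_.meta.get("mode") != "covariance":
        raise ValueError("endogeneity test requires a covariance-"
                         "identification fit (mode='covariance'); in "
                         "direct-effect mode these covariances are fixed at 0")
    mean, cov = _posterior_block(fit, ["psi_31", "psi_32"])
    return wald_test(mean, cov)


def exclusion_test(fit) -> WaldResult:
    """Joint Wald test that all direct instrument→outcome effects are zero."""
    if fit.draws_.meta.get("mode") != "direct":
        raise ValueError("exclusion test requires a direct-effect fit "
                         "(mode='direct')")
    outcome = fit.draws_.meta["outcome"]
    gammas = [f"{outcome}~{c}" for c in fit.direct_effect_cols]
    mean, cov = _posterior_block(fit, gammas)
    return wald_test(mean, cov)


@dataclass
class PsrfResult:
    values: pd.Series
    degenerate: list = field(default_factory=list)

    @property
    def max(self) -> float:
        finite = self.values.dropna()
        return float(finite.max()) if len(finite) else float("nan")

    def passes(self, threshold: float = 1.1) -> bool:
        return bool(self.max < threshold) if np.isfinite(self.max) else False


def _gelman_rubin(chains: np.ndarray) -> float:
    """Original Gelman–Rubin PSRF for one parameter, chains shape (m, n)."""
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def psrf(draws, split: bool = False) -> PsrfResult:
    """Potential scale reduction factor per parameter.

    ``draws`` is a :class:`PosteriorDraws` or an (chains, draws) array for
    a single parameter.  Constant identical chains (zero within-chain
    variance) are reported on the ``degenerate`` list rather than as NaN.
    ``split=True`` halves each chain first (the split-chain variant).
    """
    if isinstance(draws, PosteriorDraws):
        arrays = {name: draws.per_chain(name) for name in draws.names}
    else:
        arrays = {"parameter": np.asarray(draws, dtype=float)}
    values, degenerate = {}, []
    for name, ch in arrays.items():
        if ch.ndim != 2 or ch.shape[0] < 2:
            raise ValueError("PSRF needs at least 2 chains")
        if ch.shape[1] < 10:
            raise ValueError("PSRF needs at least 10 draws per chain")
        if split:
            half = ch.shape[1] // 2
            ch = np.concatenate([ch[:, :half], ch[:, half:2 * half]], axis=0)
        if np.allclose(ch.var(axis=1, ddof=1), 0.0):
            degenerate.append(name)
            values[name] = np.nan
            continue
        values[name] = _gelman_rubin(ch)
    return PsrfResult(values=pd.Series(values), degenerate=degenerate)


@dataclass
class DiagnosticsReport:
    """All identification and convergence checks for one fitted model."""

    relevance: dict[str, FResult]
    endogeneity: WaldResult | None = None
    exclusion: WaldResult | None = None
    max_psrf: float = float("nan")
    psrf_degenerate: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {"relevance": {k: {"F": v.f, "df": v.df, "strong": v.strong}
                           for k, v in self.relevance.items()},
             "max_psrf": self.max_psrf,
             "psrf_degenerate": list(self.psrf_degenerate)}
        for key in ("endogeneity", "exclusion"):
            w = getattr(self, key)
            d[key] = None if w is None else {
                "chi2": w.statistic, "df": w.df, "p": w.pvalue}
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        lines = []
        for name, r in self.relevance.items():
            verdict = "strong" if r.strong else "weak"
            lines.append(f"relevance [{name}]: F({r.df}) = {r.f:.2f} ({verdict})")
        if self.endogeneity is not None:
            w = self.endogeneity
            lines.append(f"endogeneity: Wald chi2({w.df}) = {w.statistic:.2f}, "
                         f"P = {w.pvalue:.3f}")
        if self.exclusion is not None:
            w = self.exclusion
            lines.append(f"exclusion: Wald chi2({w.df}) = {w.statistic:.2f}, "
                         f"P = {w.pvalue:.3f}")
        lines.append(f"max PSRF = {self.max_psrf:.3f} "
                     f"(<1.1 good, <1.2 acceptable)")
        return "\n".join(lines) + "\n"
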