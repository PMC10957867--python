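"""Structural instrumental-variable estimators.

The structural system has three equations per child:

    gi_c      = a10 + a1' z + a1e * aele_c                 + e1   (first stage)
    gi_x_aele = a20 + a2' z + a2e * aele_c                 + e2   (first stage)
    sdq_total = b0 + b_gi*gi_c + b_int*gi_x_aele
                + b_ae*aele_c [+ g' d]                     + e3   (structural)

with z the six instruments (three living-distance dummies and their
products with centered adversity — the products are the natural
instruments for the endogenous interaction) and (e1, e2, e3) ~ MVN(0, Psi)
per row.  The system is triangular, so its Jacobian is one and the
row-wise residual vector carries the full likelihood.

Two identification modes, which cannot be combined (a model with both
free instrument→outcome effects and free instrument-side error
covariances is never identified):

* ``mode="covariance"`` — no direct instrument→outcome paths (g ≡ 0); the
  off-diagonals of Psi involving e3 are free, and their joint test is the
  endogeneity check.
* ``mode="direct"`` — the distance dummies get direct effects g on the
  outcome; cov(e1, e3) = cov(e2, e3) = 0.  The joint test of g = 0 is the
  exclusion check.

Estimation is by closed-form two-stage least squares
(:class:`TwoStageLeastSquares`) or by a Gibbs sampler
(:class:`BayesianIVRegressor`) alternating (a) the joint Gaussian full
conditional of all regression coefficients given Psi, under independent
N(0, prior_sd^2) priors, and (b) the conjugate inverse-Wishart full
conditional of Psi given the coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular
from sklearn.base import BaseEstimator

from .posterior import PosteriorDraws, posterior_summary
from .preprocess import AnalysisFrame
from .utils import spawn_seeds

__all__ = ["ModelSpec", "TwoStageLeastSquares", "BayesianIVRegressor",
           "fit_2sls", "gibbs_fit"]

PSI_LABELS = {"covariance": ("psi_11", "psi_21", "psi_22",
                             "psi_31", "psi_32", "psi_33"),
              "direct": ("psi_11", "psi_21", "psi_22", "psi_33")}


@dataclass
class ModelSpec:
    """Declarative model description: variable roles, priors, sampler."""

    outcome: str = "sdq_total"
    endog: tuple[str, ...] = ("gi_c", "gi_x_aele")
    exog: tuple[str, ...] = ("aele_c",)
    instruments: tuple[str, ...] = ("d1", "d2", "d3",
                                    "d1_x_aele", "d2_x_aele", "d3_x_aele")
    prior_sd: float = 100.0
    psi_prior_scale: np.ndarray | None = None    # default: identity
    psi_prior_df: int | None = None              # default: block dim + 1
    chains: int = 2
    iterations: int = 20_000
    burn_in: int = 10_000
    seed: int = 0
    mode: str = "covariance"
    direct_effect_cols: tuple[str, ...] = ("d1", "d2", "d3")

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required (for convergence "
                             "checks)")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")
        if len(self.instruments) < len(self.endog):
            raise ValueError("order condition violated: need at least as many "
                             "instruments as endogenous predictors")
        if self.mode not in ("covariance", "direct"):
            raise ValueError(f"mode must be 'covariance' or 'direct', got {self.mode!r}")


def _matrix(df: pd.DataFrame, cols, intercept: bool = True) -> np.ndarray:
    parts = [np.ones((len(df), 1))] if intercept else []
    if cols:
        parts.append(df[list(cols)].to_numpy(dtype=float))
    return np.hstack(parts)


def _rank_check(mat: np.ndarray, names: list[str], label: str) -> None:
    q, r = np.linalg.qr(mat)
    diag = np.abs(np.diag(r))
    tol = mat.shape[0] * np.finfo(float).eps * max(diag.max(), 1.0)
    bad = [names[i] for i in np.nonzero(diag <= tol)[0]]
    if bad:
        raise ValueError(f"{label} matrix is rank deficient; collinear or "
                         f"constant columns: {bad}")


class TwoStageLeastSquares(BaseEstimator):
    """Closed-form 2SLS for the structural equation, the frequentist
    oracle for the Bayesian fit.

    The same instrument set identifies both endogenous predictors (one may
    not mix instrument sets across endogenous regressors), and first-stage
    strength is reported per endogenous predictor as the partial F of the
    excluded instruments.

    Fitted attributes: ``params_`` (Series), ``cov_`` (DataFrame),
    ``first_stage_f_`` (dict: name -> (F, df1, df2)), ``resid_``, ``n_``.
    """

    def __init__(self, outcome="sdq_total", endog=("gi_c", "gi_x_aele"),
                 exog=("aele_c",),
                 instruments=("d1", "d2", "d3",
                              "d1_x_aele", "d2_x_aele", "d3_x_aele")):
        self.outcome = outcome
        self.endog = endog
        self.exog = exog
        self.instruments = instruments

    @classmethod
    def from_spec(cls, spec: ModelSpec) -> "TwoStageLeastSquares":
        return cls(outcome=spec.outcome, endog=spec.endog, exog=spec.exog,
                   instruments=spec.instruments)

    def fit(self, X, y=None):
        df = X.data if isinstance(X, AnalysisFrame) else X
        yv = df[self.outcome].to_numpy(dtype=float)
        Xm = _matrix(df, list(self.endog) + list(self.exog))
        Zm = _matrix(df, list(self.instruments) + list(self.exog))
        x_names = ["const"] + list(self.endog) + list(self.exog)
        z_names = ["const"] + list(self.instruments) + list(self.exog)
        _rank_check(Zm, z_names, "instrument")

        ZtZ = Zm.T @ Zm
        ZtX = Zm.T @ Xm
        Zty = Zm.T @ yv
        W = np.linalg.solve(ZtZ, ZtX)            # first-stage coefficients
        A = ZtX.T @ W                            # X' P_Z X
        c = W.T @ Zty                            # X' P_Z y
        try:
            beta = np.linalg.solve(A, c)
        except np.linalg.LinAlgError as exc:
            raise ValueError("projected design is singular — instruments do "
                             "not separately identify the endogenous "
                             "predictors") from exc
        n, k = Xm.shape
        resid = yv - Xm @ beta
        sigma2 = float(resid @ resid) / (n - k)
        cov = sigma2 * np.linalg.inv(A)

        self.params_ = pd.Series(beta, index=x_names)
        self.cov_ = pd.DataFrame(cov, index=x_names, columns=x_names)
        self.resid_ = resid
        self.n_ = n
        self.first_stage_f_ = {
            name: self._partial_f(df, name, Zm) for name in self.endog}
        return self

    def _partial_f(self, df, name, Zm):
        """Partial F of the excluded instruments in one first-stage
        regression (reduced model keeps intercept + exogenous covariates)."""
        x = df[name].to_numpy(dtype=float)
        Z0 = _matrix(df, list(self.exog))
        rss1 = self._rss(Zm, x)
        rss0 = self._rss(Z0, x)
        q = len(self.instruments)
        dof = len(x) - Zm.shape[1]
        f = ((rss0 - rss1) / q) / (rss1 / dof)
        return float(f), q, dof

    @staticmethod
    def _rss(Z, x):
        coef, *_ = np.linalg.lstsq(Z, x, rcond=None)
        r = x - Z @ coef
        return float(r @ r)

    def predict(self, X):
        df = X.data if isinstance(X, AnalysisFrame) else X
        Xm = _matrix(df, list(self.endog) + list(self.exog))
        return Xm @ self.params_.to_numpy()


def _sample_inv_wishart(rng: np.random.Generator, df: float,
                        scale: np.ndarray) -> np.ndarray:
    """Draw from IW(df, scale) via a Bartlett decomposition.

    If W ~ Wishart(df, I) = A A' with A lower triangular, then
    L A'^{-1} (L A'^{-1})' ~ IW(df, L L') for L = chol(scale); the result
    is symmetric positive definite by construction.
    """
    p = scale.shape[0]
    if p == 1:
        # IW_1(df, s) is inverse-gamma(df/2, s/2)
        return np.array([[scale[0, 0] / (2.0 * rng.gamma(df / 2.0))]])
    L = np.linalg.cholesky(scale)
    A = np.zeros((p, p))
    A[np.diag_indices(p)] = np.sqrt(rng.chisquare(df - np.arange(p)))
    A[np.tril_indices(p, -1)] = rng.standard_normal(p * (p - 1) // 2)
    B = solve_triangular(A, L.T, lower=True)     # A^{-1} L'
    M = B.T                                      # L A'^{-T} ... = L A^{-T}
    return M @ M.T


class BayesianIVRegressor(BaseEstimator):
    """Gibbs-sampled Bayesian structural IV regression with free error
    covariances.

    Priors: independent N(0, prior_sd^2) on every regression coefficient
    (default SD 100, effectively flat on the SDQ scale) and a proper
    least-informative inverse-Wishart on the error covariance blocks
    (identity scale, block dimension + 1 degrees of freedom) — the proper
    counterpart of the improper reference prior, guaranteeing a valid
    conjugate Gibbs step.  Defaults: 2 chains of 20,000 iterations with
    10,000 burn-in each.

    Fitted attributes: ``draws_`` (:class:`PosteriorDraws`), ``summary_``,
    ``coef_names_``, ``psi_names_``, ``n_``, ``n_psi_redraws_``.
    """

    def __init__(self, outcome="sdq_total", endog=("gi_c", "gi_x_aele"),
                 exog=("aele_c",),
                 instruments=("d1", "d2", "d3",
                              "d1_x_aele", "d2_x_aele", "d3_x_aele"),
                 prior_sd=100.0, psi_prior_scale=None, psi_prior_df=None,
                 chains=2, iterations=20_000, burn_in=10_000,
                 mode="covariance", direct_effect_cols=("d1", "d2", "d3"),
                 random_state=0):
        self.outcome = outcome
        self.endog = endog
        self.exog = exog
        self.instruments = instruments
        self.prior_sd = prior_sd
        self.psi_prior_scale = psi_prior_scale
        self.psi_prior_df = psi_prior_df
        self.chains = chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.mode = mode
        self.direct_effect_cols = direct_effect_cols
        self.random_state = random_state

    @classmethod
    def from_spec(cls, spec: ModelSpec) -> "BayesianIVRegressor":
        return cls(outcome=spec.outcome, endog=spec.endog, exog=spec.exog,
                   instruments=spec.instruments, prior_sd=spec.prior_sd,
                   psi_prior_scale=spec.psi_prior_scale,
                   psi_prior_df=spec.psi_prior_df, chains=spec.chains,
                   iterations=spec.iterations, burn_in=spec.burn_in,
                   mode=spec.mode, direct_effect_cols=spec.direct_effect_cols,
                   random_state=spec.seed)

    # ------------------------------------------------------------------ #

    def _validate(self):
        ModelSpec(outcome=self.outcome, endog=tuple(self.endog),
                  exog=tuple(self.exog), instruments=tuple(self.instruments),
                  prior_sd=self.prior_sd, chains=self.chains,
                  iterations=self.iterations, burn_in=self.burn_in,
                  seed=self.random_state if self.random_state is not None else 0,
                  mode=self.mode,
                  direct_effect_cols=tuple(self.direct_effect_cols))
        if len(self.endog) != 2:
            raise ValueError("this system is defined for exactly 2 endogenous "
                             "predictors (composite and its interaction)")

    def fit(self, X, y=None):
        self._validate()
        df = X.data if isinstance(X, AnalysisFrame) else X
        fs_cols = list(self.instruments) + list(self.exog)
        out_cols = list(self.endog) + list(self.exog)
        if self.mode == "direct":
            out_cols += list(self.direct_effect_cols)

        X1 = _matrix(df, fs_cols)
        X3 = _matrix(df, out_cols)
        _rank_check(X1, ["const"] + fs_cols, "instrument")
        _rank_check(X3, ["const"] + out_cols, "outcome design")
        Y = df[[self.endog[0], self.endog[1], self.outcome]].to_numpy(float)
        designs = [X1, X1, X3]
        names = ([f"{self.endog[0]}~{c}" for c in ["const"] + fs_cols]
                 + [f"{self.endog[1]}~{c}" for c in ["const"] + fs_cols]
                 + [f"{self.outcome}~{c}" for c in ["const"] + out_cols])
        psi_names = list(PSI_LABELS[self.mode])

        n = len(df)
        sizes = [d.shape[1] for d in designs]
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        p = int(offsets[-1])

        # cached cross-products; all designs are fixed across iterations
        XtX = [[designs[j].T @ designs[k] for k in range(3)] for j in range(3)]
        XtY = [[designs[j].T @ Y[:, k] for k in range(3)] for j in range(3)]

        kept = self.iterations - self.burn_in
        seeds = spawn_seeds(self.random_state, self.chains)
        coef_draws = np.empty((self.chains, kept, p))
        psi_draws = np.empty((self.chains, kept, len(psi_names)))
        self.n_psi_redraws_ = 0

        for c, s in enumerate(seeds):
            rng = np.random.default_rng(s)
            self._run_chain(rng, designs, Y, XtX, XtY, offsets, p, n,
                            coef_draws[c], psi_draws[c])

        self.coef_names_ = names
        self.psi_names_ = psi_names
        self.n_ = n
        self.draws_ = PosteriorDraws(
            names=names + psi_names,
            values=np.concatenate([coef_draws, psi_draws], axis=2),
            meta={"mode": self.mode, "n": n, "chains": self.chains,
                  "iterations": self.iterations, "burn_in": self.burn_in,
                  "outcome": self.outcome, "endog": tuple(self.endog),
                  "exog": tuple(self.exog),
                  "instruments": tuple(self.instruments),
                  "seed": self.random_state})
        self.summary_ = posterior_summary(self.draws_,
                                          min_draws=min(1000, kept * self.chains))
        return self

    # ------------------------------------------------------------------ #

    def _psi_priors(self):
        scale = self.psi_prior_scale
        scale = np.eye(3) if scale is None else np.asarray(scale, float)
        if self.mode == "covariance":
            df = 4 if self.psi_prior_df is None else self.psi_prior_df
            return [(scale, df, slice(0, 3))]
        df2 = 3 if self.psi_prior_df is None else self.psi_prior_df
        df1 = 2 if self.psi_prior_df is None else self.psi_prior_df
        return [(scale[:2, :2], df2, slice(0, 2)),
                (scale[2:, 2:], df1, slice(2, 3))]

    def _run_chain(self, rng, designs, Y, XtX, XtY, offsets, p, n,
                   coef_out, psi_out):
        prior_prec = 1.0 / self.prior_sd ** 2
        blocks = self._psi_priors()

        # start from equation-wise least squares, jittered per chain so the
        # convergence diagnostic sees genuinely distinct starting points
        theta = np.empty(p)
        for j in range(3):
            sl = slice(offsets[j], offsets[j + 1])
            coef, *_ = np.linalg.lstsq(designs[j], Y[:, j], rcond=None)
            theta[sl] = coef
        theta += rng.normal(0, 0.1 * (np.abs(theta) + 0.1))
        R = np.column_stack([Y[:, j] - designs[j] @ theta[offsets[j]:offsets[j + 1]]
                             for j in range(3)])
        Psi = (R.T @ R) / max(n - 1, 1) + 1e-6 * np.eye(3)

        K = np.empty((p, p))
        b = np.empty(p)
        keep_from = self.burn_in
        for it in range(self.iterations):
            Om = np.linalg.inv(Psi)
            for j in range(3):
                sj = slice(offsets[j], offsets[j + 1])
                acc = Om[j, 0] * XtY[j][0] + Om[j, 1] * XtY[j][1] + Om[j, 2] * XtY[j][2]
                b[sj] = acc
                for k in range(3):
                    K[sj, offsets[k]:offsets[k + 1]] = Om[j, k] * XtX[j][k]
            K[np.diag_indices(p)] += prior_prec
            L = np.linalg.cholesky(K)
            mean = cho_solve((L, True), b)
            theta = mean + solve_triangular(L.T, rng.standard_normal(p),
                                            lower=False)

            for j in range(3):
                R[:, j] = Y[:, j] - designs[j] @ theta[offsets[j]:offsets[j + 1]]
            S = R.T @ R

            Psi = np.zeros((3, 3))
            for scale0, df0, sl in blocks:
                Sblk = S[sl, sl]
                for attempt in range(100):
                    draw = _sample_inv_wishart(rng, df0 + n, scale0 + Sblk)
                    if np.all(np.isfinite(draw)):
                        break
                    self.n_psi_redraws_ += 1
                else:
                    raise RuntimeError("error-covariance draw diverged "
                                       "(non-finite after 100 redraws)")
                Psi[sl, sl] = draw

            if not np.all(np.isfinite(theta)):
                raise RuntimeError(f"divergent coefficient draw at iteration {it}")
            if it >= keep_from:
                coef_out[it - keep_from] = theta
                if self.mode == "covariance":
                    psi_out[it - keep_from] = (Psi[0, 0], Psi[1, 0], Psi[1, 1],
                                               Psi[2, 0], Psi[2, 1], Psi[2, 2])
                else:
                    psi_out[it - keep_from] = (Psi[0, 0], Psi[1, 0], Psi[1, 1],
                                               Psi[2, 2])


def fit_2sls(frame, spec: ModelSpec | None = None) -> TwoStageLeastSquares:
    """Two-stage least squares point estimates, asymptotic covariance and
    first-stage F statistics for the structural model."""
    spec = spec or ModelSpec()
    return TwoStageLeastSquares.from_spec(spec).fit(frame)


def gibbs_fit(frame, spec: ModelSpec | None = None) -> BayesianIVRegressor:
    """Bayesian fit of the structural model by Gibbs sampling; returns the
    fitted estimator whose ``draws_`` attribute holds the posterior."""
    spec = spec or ModelSpec()
    return BayesianIVRegressor.from_spec(spec).fit(frame)
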