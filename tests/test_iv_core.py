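"""2SLS and Gibbs estimators, posterior summaries, simple slopes."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ivsem import (ModelSpec, TwoStageLeastSquares, fit_2sls, gibbs_fit,
                   posterior_summary, simple_slopes)
from ivsem.posterior import PosteriorDraws

from conftest import TRUTH, make_frame


class TestTwoStageLeastSquares:
    def test_perfect_instruments_reduce_to_ols(self):
        """Instrumenting each endogenous variable with itself projects onto
        the original design, so 2SLS equals OLS exactly."""
        import statsmodels.api as sm

        frame = make_frame(n=400, seed=1)
        ts = TwoStageLeastSquares(
            instruments=("gi_c", "gi_x_aele")).fit(frame)
        X = sm.add_constant(frame.data[["gi_c", "gi_x_aele", "aele_c"]])
        ols = sm.OLS(frame.data.sdq_total, X).fit()
        np.testing.assert_allclose(
            ts.params_[["gi_c", "gi_x_aele", "aele_c"]],
            ols.params[["gi_c", "gi_x_aele", "aele_c"]], rtol=1e-10)

    def test_just_identified_three_rows_by_hand(self):
        """A square single-endogenous system equals indirect least squares:
        beta = cov(z, y) / cov(z, x)."""
        df = pd.DataFrame({"x": [1.0, 2.0, 4.0], "z": [0.0, 1.0, 2.0],
                           "y": [2.0, 3.5, 7.0]})
        ts = TwoStageLeastSquares(outcome="y", endog=("x",), exog=(),
                                  instruments=("z",)).fit(df)
        z, x, y = df.z, df.x, df.y
        beta_hand = np.cov(z, y)[0, 1] / np.cov(z, x)[0, 1]
        assert ts.params_["x"] == pytest.approx(beta_hand, rel=1e-12)
        assert ts.params_["const"] == pytest.approx(y.mean() - beta_hand * x.mean(),
                                                    rel=1e-10)

    def test_recovers_planted_interaction(self):
        frame = make_frame(n=10000, seed=2, confounding=0.0,
                           item_noise_sd=0.0)
        ts = fit_2sls(frame)
        se = np.sqrt(ts.cov_.loc["gi_x_aele", "gi_x_aele"])
        assert abs(ts.params_["gi_x_aele"] - (-0.839)) < 3 * se

    def test_matches_statsmodels_iv2sls(self):
        from statsmodels.sandbox.regression.gmm import IV2SLS

        frame = make_frame(n=1500, seed=3)
        ts = fit_2sls(frame)
        df = frame.data
        X = np.column_stack([np.ones(len(df)), df.gi_c, df.gi_x_aele, df.aele_c])
        Z = np.column_stack([np.ones(len(df)), df.d1, df.d2, df.d3,
                             df.d1_x_aele, df.d2_x_aele, df.d3_x_aele,
                             df.aele_c])
        ref = IV2SLS(df.sdq_total.to_numpy(), X, instrument=Z).fit()
        np.testing.assert_allclose(ts.params_.to_numpy(), ref.params, rtol=1e-8)

    def test_first_stage_f_reported(self):
        frame = make_frame(n=1000, seed=4)
        ts = fit_2sls(frame)
        for name in ("gi_c", "gi_x_aele"):
            f, q, dof = ts.first_stage_f_[name]
            assert f > 10 and q == 6 and dof == 1000 - 8

    def test_collinear_instruments_named(self):
        frame = make_frame(n=200, seed=5)
        frame.data["d1_dup"] = frame.data["d1"]
        with pytest.raises(ValueError, match="d1_dup"):
            TwoStageLeastSquares(
                instruments=("d1", "d2", "d3", "d1_dup")).fit(frame)


class TestGibbsSampler:
    def test_same_seed_identical_draws(self, fast_spec):
        frame = make_frame(n=400, seed=6)
        f1 = gibbs_fit(frame, fast_spec)
        f2 = gibbs_fit(frame, fast_spec)
        np.testing.assert_array_equal(f1.draws_.values, f2.draws_.values)
        f3 = gibbs_fit(frame, dataclasses.replace(fast_spec, seed=99))
        assert not np.array_equal(f1.draws_.values, f3.draws_.values)

    def test_posterior_medians_match_2sls_oracle(self, frame_2000, gibbs_2000):
        """On complete data with flat priors the Bayesian medians agree
        with 2SLS within 5% + 2 posterior SDs."""
        ts = fit_2sls(frame_2000)
        for param, col in [("sdq_total~gi_c", "gi_c"),
                           ("sdq_total~aele_c", "aele_c"),
                           ("sdq_total~gi_x_aele", "gi_x_aele")]:
            row = gibbs_2000.summary_.loc[param]
            ref = ts.params_[col]
            assert abs(row["median"] - ref) < 0.05 * abs(ref) + 2 * row["sd"]

    def test_tight_prior_shrinks_toward_zero(self, fast_spec):
        frame = make_frame(n=400, seed=7)
        spec = dataclasses.replace(fast_spec, prior_sd=0.001)
        fit = gibbs_fit(frame, spec)
        med = fit.summary_.loc["sdq_total~gi_c", "median"]
        assert abs(med) < 0.05

    def test_translation_equivariance(self, fast_spec):
        """Shifting the outcome by a constant moves only the outcome
        intercept's posterior (under an effectively flat prior)."""
        frame = make_frame(n=400, seed=8)
        spec = dataclasses.replace(fast_spec, prior_sd=1e6)
        f0 = gibbs_fit(frame, spec)
        shifted = dataclasses.replace(frame, data=frame.data.assign(
            sdq_total=frame.data.sdq_total + 10))
        f1 = gibbs_fit(shifted, spec)
        i0 = f0.summary_.loc["sdq_total~const", "median"]
        i1 = f1.summary_.loc["sdq_total~const", "median"]
        assert i1 - i0 == pytest.approx(10.0, abs=1e-3)
        others = [n for n in f0.coef_names_
                  if n.startswith("sdq_total~") and not n.endswith("const")]
        for name in others:
            np.testing.assert_allclose(f1.draws_.per_chain(name),
                                       f0.draws_.per_chain(name), atol=1e-4)

    def test_psi_draws_positive_definite(self, gibbs_2000):
        flat = gibbs_2000.draws_
        sub = flat.select(["psi_11", "psi_21", "psi_22",
                           "psi_31", "psi_32", "psi_33"])
        for row in sub[::97]:
            p11, p21, p22, p31, p32, p33 = row
            psi = np.array([[p11, p21, p31], [p21, p22, p32], [p31, p32, p33]])
            assert np.linalg.eigvalsh(psi).min() > 0

    def test_draw_count_contract(self, gibbs_2000):
        assert gibbs_2000.draws_.n_draws == 2 * (3000 - 1000)

    def test_spec_invariants(self):
        with pytest.raises(ValueError, match="burn_in"):
            ModelSpec(iterations=100, burn_in=100)
        with pytest.raises(ValueError, match="chains"):
            ModelSpec(chains=1)
        with pytest.raises(ValueError, match="prior_sd"):
            ModelSpec(prior_sd=0)
        with pytest.raises(ValueError, match="order condition"):
            ModelSpec(instruments=("d1",))
        with pytest.raises(ValueError, match="mode"):
            ModelSpec(mode="bogus")


class TestPosteriorSummary:
    def test_point_mass(self):
        draws = PosteriorDraws(["theta"], np.full((2, 50, 1), 3.0))
        s = posterior_summary(draws, min_draws=1).loc["theta"]
        assert s["median"] == 3.0
        assert s["hpd_lower"] == s["hpd_upper"] == 3.0
        assert s["one_tailed_p"] == 0.0

    def test_normal_hpd_width(self, rng):
        x = rng.standard_normal((2, 5000, 1))
        s = posterior_summary(PosteriorDraws(["z"], x)).loc["z"]
        width = s["hpd_upper"] - s["hpd_lower"]
        assert width == pytest.approx(3.92, rel=0.05)

    def test_symmetric_draws_one_tailed_half(self, rng):
        x = rng.standard_normal(4000)
        sym = np.concatenate([x, -x]).reshape(1, -1, 1)
        s = posterior_summary(PosteriorDraws(["z"], sym)).loc["z"]
        assert s["one_tailed_p"] == pytest.approx(0.5, abs=0.01)

    def test_hpd_matches_arviz_on_skewed_draws(self, rng):
        import arviz

        x = rng.gamma(2.0, 1.0, size=20000)
        draws = PosteriorDraws(["g"], x.reshape(1, -1, 1))
        s = posterior_summary(draws).loc["g"]
        ref = arviz.hdi(x, hdi_prob=0.95)
        assert s["hpd_lower"] == pytest.approx(ref[0], abs=0.05)
        assert s["hpd_upper"] == pytest.approx(ref[1], abs=0.05)

    def test_too_few_draws_rejected(self):
        draws = PosteriorDraws(["t"], np.zeros((2, 10, 1)))
        with pytest.raises(ValueError, match="retained draws"):
            posterior_summary(draws)


class TestSimpleSlopes:
    def test_point_arithmetic(self):
        out = simple_slopes(3.196, -0.839, [0.0, 1.0, -1.602])
        assert out.slope.tolist() == pytest.approx([3.196, 2.357, 4.540],
                                                   abs=1e-3)

    def test_band_at_zero_equals_aele_hpd(self, gibbs_2000):
        ba = gibbs_2000.draws_.select(["sdq_total~aele_c"])[:, 0]
        bi = gibbs_2000.draws_.select(["sdq_total~gi_x_aele"])[:, 0]
        out = simple_slopes(ba, bi, [0.0]).iloc[0]
        s = gibbs_2000.summary_.loc["sdq_total~aele_c"]
        assert out["hpd_lower"] == pytest.approx(s["hpd_lower"], abs=1e-12)
        assert out["hpd_upper"] == pytest.approx(s["hpd_upper"], abs=1e-12)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simple_slopes(3.196, -0.839, [])
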