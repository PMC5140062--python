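"""The hyper-model of model error: f, its uncertainty, and the spectrum bound.

The closed forms here are mutually constrained (the augmented-FIM f-block
must invert to sigma_f^2; the acceptable f is the fixed point sigma_f(f)=f;
the missing-spectrum f is the plain estimator applied to the missing-spectrum
chi^2), and all of them must reproduce the (f, sigma_f) pairs a fit of each
study stage yields.  These identities are asserted exactly here.
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq, minimize_scalar

from sloppysys.discrepancy import (
    SloppySpectrumModel,
    acceptable_f,
    augmented_fim,
    discrepancy_report,
    estimate_f,
    inflate_covariance,
    neg_log_likelihood,
    sigma_f,
    spectrum_chi2,
)
from sloppysys.fim import fim_from_spectrum
from sloppysys.fitting import Dataset

from conftest import LinearPredictor


class TestEstimateF:
    def test_egfr_scale_fit(self):
        f, clamped = estimate_f(100000.0, 7000, 48)
        assert not clamped
        assert round(f, 1) == 3.7

    def test_exactly_expected_error_gives_zero(self):
        f, clamped = estimate_f(13.0, 19, 6)
        assert f == 0.0 and clamped

    def test_doubled_chi2_gives_one(self):
        f, _ = estimate_f(2 * 94, 100, 6)
        assert f == pytest.approx(1.0)

    def test_requires_more_data_than_parameters(self):
        with pytest.raises(ValueError):
            estimate_f(10.0, 5, 5)


class TestSigmaF:
    @pytest.mark.parametrize("f,M,N,expected", [
        (0.76, 19, 6, 0.41),
        (2.0, 35, 6, 0.33),
    ])
    def test_split_dose_fit_pairs(self, f, M, N, expected):
        assert round(sigma_f(f, M, N), 2) == expected

    def test_egfr_pair_via_estimator(self):
        f, _ = estimate_f(100000.0, 7000, 48)
        assert round(sigma_f(f, 7000, 48), 2) == 0.03

    def test_zero_f_is_flagged_infinite(self):
        assert sigma_f(0.0, 19, 6) == math.inf


class TestNegLogLikelihood:
    def _data_and_pred(self, seed=0, M=20):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.5, 2.0, M)
        m = LinearPredictor(x)
        pred = m.predict()
        d = pred.values + rng.normal(0, 0.3, M)
        sig = rng.uniform(0.1, 0.5, M)
        data = Dataset.from_rows([(e, o, t, dv, sv) for (e, o, t), dv, sv in
                                  zip(m.index, d, sig)])
        return data, pred

    def test_f_zero_reduces_to_gaussian(self):
        data, pred = self._data_and_pred()
        resid = (data.values - pred.values) / data.sigmas
        gauss = float(np.sum(resid**2 / 2 + np.log(data.sigmas)
                             + 0.5 * np.log(2 * np.pi)))
        assert neg_log_likelihood(data, pred, 0.0) == pytest.approx(gauss, rel=1e-12)

    def test_single_perfect_record(self):
        m = LinearPredictor([1.0])
        pred = m.predict()
        data = Dataset.from_rows([("lin", "y", 1.0, 1.0, 1.0)])
        assert neg_log_likelihood(data, pred, 0.0) == pytest.approx(
            0.5 * math.log(2 * math.pi))

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_profile_minimum_reproduces_estimator(self, seed):
        # minimizing the NLL over f at fixed theta = closed-form estimator
        rng = np.random.default_rng(seed)
        M = 120
        x = rng.uniform(0.5, 2.0, M)
        m = LinearPredictor(x)
        pred = m.predict()
        sig = rng.uniform(0.1, 0.5, M)
        d = pred.values + 2.0 * sig * rng.standard_normal(M)  # overdispersed
        data = Dataset.from_rows([(e, o, t, dv, sv) for (e, o, t), dv, sv in
                                  zip(m.index, d, sig)])
        res = minimize_scalar(lambda f: neg_log_likelihood(data, pred, f),
                              bounds=(0.0, 10.0), method="bounded",
                              options={"xatol": 1e-8})
        chi2 = float(np.sum((data.values - pred.values) ** 2 / sig**2))
        # NLL profile in f has dof M (theta fixed), so compare at N=0
        f_closed, _ = estimate_f(chi2, M, 0)
        assert res.x == pytest.approx(f_closed, abs=1e-5)


class TestAugmentedFim:
    def test_f_zero_limit(self):
        base = fim_from_spectrum(np.diag([4.0, 1.0]))
        out = augmented_fim(base, 0.0, 30, 2)
        assert np.allclose(out[:2, :2], base.matrix)
        assert out[2, 2] == 0.0

    def test_f_block_cross_check(self):
        base = fim_from_spectrum(np.eye(2))
        out = augmented_fim(base, 1.0, 10, 2)  # M - N = 8
        assert out[2, 2] == pytest.approx(2.0 * 1.0 * 8 / 4.0)
        assert 1.0 / math.sqrt(out[2, 2]) == pytest.approx(sigma_f(1.0, 10, 2))

    @given(st.integers(0, 10_000))
    def test_block_structure(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((3, 3))
        base = fim_from_spectrum(A @ A.T)
        f = float(rng.uniform(0.1, 3.0))
        out = augmented_fim(base, f, 50, 3)
        assert np.all(out[:3, 3] == 0.0) and np.all(out[3, :3] == 0.0)
        assert 1.0 / math.sqrt(out[3, 3]) == pytest.approx(sigma_f(f, 50, 3))


class TestInflateCovariance:
    def test_inflation_factor_at_egfr_f(self):
        f = 3.7
        assert round(math.sqrt(1 + f * f), 1) == 3.8
        rep = discrepancy_report((1 + f * f) * (7000 - 48), 7000, 48)
        assert round(rep.inflation, 1) == 3.8

    def test_expected_chi2_leaves_covariance_unchanged(self):
        base = fim_from_spectrum(np.diag([2.0, 5.0]))
        cov = inflate_covariance(base, float(28 - 2), 28, 2)
        assert np.allclose(cov, np.linalg.inv(base.matrix))

    def test_scalar_arithmetic(self):
        base = fim_from_spectrum(np.array([[14.0]]))
        cov = inflate_covariance(base, 2.0 * 10, 11, 1)  # chi2/(M-N) = 2
        assert cov[0, 0] == pytest.approx(1.0 / 7.0)

    def test_singular_fim_uses_pseudoinverse(self):
        base = fim_from_spectrum(np.diag([1.0, 0.0]))
        with pytest.warns(RuntimeWarning, match="pseudo-inverse"):
            cov = inflate_covariance(base, 20.0, 12, 2)
        assert cov[0, 0] == pytest.approx(2.0)


class TestAcceptableF:
    def test_small_and_large_dof(self):
        assert acceptable_f(19, 6) == pytest.approx((math.sqrt(26) - 1) ** -0.5)
        assert acceptable_f(7000, 48) == pytest.approx(0.0925, abs=5e-4)

    @given(st.integers(10, 100_000))
    def test_fixed_point_property(self, dof):
        f_star = acceptable_f(dof + 3, 3)
        assert sigma_f(f_star, dof + 3, 3) == pytest.approx(f_star, abs=1e-10)

    def test_fixed_point_agrees_with_root_finding(self):
        M, N = 40, 6
        root = brentq(lambda f: sigma_f(f, M, N) - f, 1e-3, 10.0, xtol=1e-12)
        assert acceptable_f(M, N) == pytest.approx(root, abs=1e-10)


class TestSpectrumModel:
    def test_direct_arithmetic(self):
        model = SloppySpectrumModel(lambda0=10.0, ratio=0.5, M=96, N=6)
        chi2, f, lam_thresh = spectrum_chi2(model)
        assert chi2 == pytest.approx(100.0)
        assert f == pytest.approx(1.0 / 3.0)

    def test_vanishing_ratio_limit(self):
        model = SloppySpectrumModel(lambda0=10.0, ratio=1e-12, M=96, N=6)
        chi2, f, _ = spectrum_chi2(model)
        assert chi2 == pytest.approx(90.0, rel=1e-10)
        assert f == pytest.approx(0.0, abs=1e-5)

    @given(st.floats(0.05, 0.95), st.floats(0.1, 1e4), st.integers(10, 10_000))
    def test_threshold_gives_unit_f(self, ratio, lam0, dof):
        model = SloppySpectrumModel(lambda0=lam0, ratio=ratio,
                                    M=dof + 5, N=5)
        _, _, lam_thresh = spectrum_chi2(model)
        at_thresh = SloppySpectrumModel(lambda0=lam_thresh, ratio=ratio,
                                        M=dof + 5, N=5)
        _, f, _ = spectrum_chi2(at_thresh)
        assert f == pytest.approx(1.0, rel=1e-10)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            SloppySpectrumModel(lambda0=1.0, ratio=1.5, M=20, N=2)


class TestInternalConsistency:
    """The reconstructed closed forms must interlock exactly."""

    def test_printed_pairs_from_single_formula(self):
        # one sigma_f formula reproduces all three reported (f, df) pairs
        assert round(sigma_f(0.76, 19, 6), 2) == 0.41
        assert round(sigma_f(2.0, 35, 6), 2) == 0.33
        f_egfr, _ = estimate_f(100000.0, 7000, 48)
        assert round(f_egfr, 1) == 3.7
        assert round(sigma_f(f_egfr, 7000, 48), 2) == 0.03

    @given(st.floats(0.2, 5.0), st.integers(10, 5000))
    def test_f_block_inverse_is_sigma_f_squared(self, f, dof):
        base = fim_from_spectrum(np.eye(2))
        out = augmented_fim(base, f, dof + 2, 2)
        assert 1.0 / out[2, 2] == pytest.approx(sigma_f(f, dof + 2, 2) ** 2,
                                                rel=1e-12)

    @given(st.floats(0.05, 0.95), st.floats(0.1, 100.0), st.integers(10, 1000))
    def test_spectrum_f_is_estimator_of_spectrum_chi2(self, ratio, lam0, dof):
        model = SloppySpectrumModel(lambda0=lam0, ratio=ratio, M=dof + 4, N=4)
        chi2, f, _ = spectrum_chi2(model)
        f_est, _ = estimate_f(chi2, dof + 4, 4)
        assert f == pytest.approx(f_est, rel=1e-10)


class TestReport:
    def test_verdict_threshold_rule(self):
        rep = discrepancy_report(3.0 * 13, 19, 6)
        assert rep.verdict == "inadequate"
        rep2 = discrepancy_report(13.5, 19, 6)
        assert rep2.verdict == "adequate"
        assert rep2.inflation == pytest.approx(math.sqrt(1 + rep2.f**2))

    def test_two_sigma_rule(self):
        rep = discrepancy_report(1.2 * 13, 19, 6, rule="two_sigma")
        assert rep.verdict == "adequate"

    def test_summary_serialization(self, tmp_path):
        import json
        rep = discrepancy_report(100.0, 30, 4)
        path = tmp_path / "rep.json"
        rep.to_json(path)
        loaded = json.loads(path.read_text())
        assert loaded["f"] == pytest.approx(rep.f)
        assert "f =" in rep.summary()
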