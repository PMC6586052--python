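"""Two-compartment model fitting and the likelihood-ratio comparison."""

import numpy as np
import pytest
from scipy.stats import chi2

from corddiff.protocol import PGSEProtocol, build_protocol
from corddiff.signals import add_rician_noise
from corddiff.synthdata import estimate_sigma_and_correct
from corddiff.zeppelin import (
    LRTResult,
    MLFit,
    ZepParams,
    compare_models,
    fit_model,
    likelihood_ratio_test,
    zep_signal,
)

Z = np.array([0.0, 0.0, 1.0])


@pytest.fixture(scope="module")
def block():
    return build_protocol(rng=np.random.default_rng(0)).block(29.0)


class TestForwardModel:
    def test_b0_returns_s0(self):
        proto = PGSEProtocol(np.zeros(1), np.zeros((1, 3)), np.array([29.0]), np.array([22.0]))
        p = ZepParams(s0=0.83, v_s=0.3, d_s_par=2, d_s_perp=0, d_z_par=1, d_z_perp=0.5, n=Z)
        assert zep_signal(p, proto)[0] == pytest.approx(0.83)

    def test_parallel_hand_value(self):
        proto = PGSEProtocol(
            np.array([1000.0]), np.array([[0, 0, 1.0]]), np.array([29.0]), np.array([22.0])
        )
        p = ZepParams(s0=1, v_s=0.5, d_s_par=2, d_s_perp=0, d_z_par=1, d_z_perp=0.5, n=Z)
        assert zep_signal(p, proto)[0] == pytest.approx(
            0.5 * np.exp(-2) + 0.5 * np.exp(-1), abs=1e-12
        )

    def test_stick_no_perpendicular_decay(self):
        proto = PGSEProtocol(
            np.array([2000.0]), np.array([[1.0, 0, 0]]), np.array([29.0]), np.array([22.0])
        )
        p = ZepParams(s0=1, v_s=0.4, d_s_par=2, d_s_perp=0, d_z_par=1, d_z_perp=0.5, n=Z)
        expected = 0.4 + 0.6 * np.exp(-2.0 * 0.5)
        assert zep_signal(p, proto)[0] == pytest.approx(expected, abs=1e-12)

    def test_non_unit_direction_normalized_with_warning(self):
        proto = PGSEProtocol(
            np.array([1000.0]), np.array([[0, 0, 1.0]]), np.array([29.0]), np.array([22.0])
        )
        p = ZepParams(s0=1, v_s=0.0, d_s_par=2, d_s_perp=0, d_z_par=1, d_z_perp=0.5,
                      n=np.array([0, 0, 2.0]))
        with pytest.warns(UserWarning, match="unit"):
            zep_signal(p, proto)

    def test_ordering_validation(self):
        p = ZepParams(s0=1, v_s=0.5, d_s_par=1.0, d_s_perp=0, d_z_par=2.0,
                      d_z_perp=0.5, n=Z)
        with pytest.raises(ValueError):
            p.validate()


class TestFitting:
    def test_zepstick_noiseless_recovery(self, block):
        truth = ZepParams(s0=1, v_s=0.45, d_s_par=2.2, d_s_perp=0, d_z_par=1.4,
                          d_z_perp=0.6, n=Z)
        f = fit_model(zep_signal(truth, block), block, Z, "ZepStick")
        assert f.params.v_s == pytest.approx(0.45, rel=0.01)
        assert f.params.d_s_par == pytest.approx(2.2, rel=0.01)
        assert f.params.d_z_par == pytest.approx(1.4, rel=0.01)
        assert f.params.d_z_perp == pytest.approx(0.6, rel=0.01)
        assert f.rss < 1e-10

    def test_zepzep_recovers_finite_stick_perpendicular(self, block):
        truth = ZepParams(s0=1, v_s=0.5, d_s_par=2.4, d_s_perp=0.2, d_z_par=1.5,
                          d_z_perp=0.7, n=Z)
        f = fit_model(zep_signal(truth, block), block, Z, "ZepZep")
        assert f.params.d_s_perp == pytest.approx(0.2, rel=0.10)

    def test_fitted_parameters_respect_ordering(self, block):
        rng = np.random.default_rng(0)
        truth = ZepParams(s0=1, v_s=0.5, d_s_par=2.0, d_s_perp=0, d_z_par=1.2,
                          d_z_perp=0.5, n=Z)
        y = add_rician_noise(zep_signal(truth, block), 0.1, rng)
        for variant in ("ZepStick", "ZepZep"):
            f = fit_model(y, block, Z, variant)
            f.params.validate()

    def test_rician_likelihood_requires_sigma(self, block):
        with pytest.raises(ValueError):
            fit_model(np.ones(len(block)), block, Z, "ZepStick", noise_model="rician")

    def test_nesting_monotonicity_on_noisy_voxels(self, block):
        rng = np.random.default_rng(1)
        truth = ZepParams(s0=1, v_s=0.4, d_s_par=2.1, d_s_perp=0, d_z_par=1.3,
                          d_z_perp=0.5, n=Z)
        sig = zep_signal(truth, block)
        for _ in range(10):
            y = add_rician_noise(sig, 0.1, rng)
            f0, f1, _ = compare_models(y, block, Z)
            assert f1.log_likelihood >= f0.log_likelihood - 1e-6


class TestLRT:
    def _fit(self, ll, k):
        p = ZepParams(s0=1, v_s=0.5, d_s_par=2, d_s_perp=0, d_z_par=1, d_z_perp=0.5, n=Z)
        return MLFit(params=p, log_likelihood=ll, converged=True,
                     n_free_params=k, variant="x")

    def test_identical_likelihoods(self):
        r = likelihood_ratio_test(self._fit(-10.0, 5), self._fit(-10.0, 6))
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_chi2_quantile(self):
        stat = chi2.ppf(0.95, 1)  # 3.841
        r = likelihood_ratio_test(self._fit(0.0, 5), self._fit(stat / 2, 6))
        assert r.statistic == pytest.approx(3.8415, abs=1e-3)
        assert r.p_value == pytest.approx(0.05, abs=1e-4)

    def test_negative_excursions_clamped(self):
        r = likelihood_ratio_test(self._fit(-9.0, 5), self._fit(-9.5, 6))
        assert r.statistic == 0.0

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            likelihood_ratio_test(self._fit(0, 6), self._fit(0, 6))

    def test_boundary_mixture_halves_pvalue(self):
        r_plain = likelihood_ratio_test(self._fit(0, 5), self._fit(2.0, 6))
        r_mix = likelihood_ratio_test(self._fit(0, 5), self._fit(2.0, 6),
                                      boundary_mixture=True)
        assert r_mix.p_value == pytest.approx(r_plain.p_value / 2)


@pytest.fixture(scope="module")
def null_voxels(block):
    """150 ZepStick voxels at SNR 10 with subject-pooled bias correction."""
    rng = np.random.default_rng(7)
    truth = ZepParams(s0=1, v_s=0.45, d_s_par=2.2, d_s_perp=0, d_z_par=1.4,
                      d_z_perp=0.6, n=Z)
    sig = zep_signal(truth, block)
    ys = np.array([add_rician_noise(sig, 0.1, rng) for _ in range(150)])
    _, _, yc = estimate_sigma_and_correct(ys[:, block.bvals == 0], ys)
    return yc


class TestCalibrationAndPower:
    def test_type_one_error_conservative(self, block, null_voxels):
        ps = np.array(
            [compare_models(y, block, Z)[2].p_value for y in null_voxels]
        )
        # boundary null makes χ²₁ conservative; allow binomial slack at n=150
        assert (ps < 0.05).mean() <= 0.08

    def test_power_increases_with_stick_perpendicular(self, block):
        rng = np.random.default_rng(8)
        detect = []
        for dsp in (0.05, 0.3):
            hits = 0
            for _ in range(40):
                truth = ZepParams(s0=1, v_s=0.5, d_s_par=2.4, d_s_perp=dsp,
                                  d_z_par=1.5, d_z_perp=0.7, n=Z)
                y = add_rician_noise(zep_signal(truth, block), 0.1, rng)
                yc = np.sqrt(np.maximum(y**2 - 2 * 0.1**2, 0))
                if compare_models(yc, block, Z)[2].p_value < 0.05:
                    hits += 1
            detect.append(hits / 40)
        assert detect[-1] > detect[0]
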