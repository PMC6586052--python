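"""DTI / DKI / SMT voxel estimators: forward-inverse identities and oracles."""

import numpy as np
import pytest
from scipy.special import erf

from corddiff.estimators import (
    _d_design,
    _D_IDX,
    fit_dki,
    fit_dti,
    fit_smt_micro,
    smt_kernel,
    spherical_mean,
)
from corddiff.protocol import build_protocol
from corddiff.zeppelin import ZepParams, zep_signal


@pytest.fixture(scope="module")
def block():
    return build_protocol(rng=np.random.default_rng(0)).block(29.0)


def _tensor_signal(block, eigvals, R=np.eye(3)):
    D = R @ np.diag(eigvals) @ R.T
    d6 = np.array([D[i, j] for i, j in _D_IDX])
    return np.exp(-block.b_ms_um2 * (_d_design(block.bvecs) @ d6))


class TestDTI:
    def test_isotropic(self, block):
        sig = _tensor_signal(block, [1.0, 1.0, 1.0])
        f = fit_dti(sig, block)
        assert f.ad == pytest.approx(1.0, abs=1e-9)
        assert f.rd == pytest.approx(1.0, abs=1e-9)

    def test_zeppelin_aligned_z(self, block):
        sig = _tensor_signal(block, [0.5, 0.5, 2.0])
        f = fit_dti(sig, block)
        assert f.ad == pytest.approx(2.0, abs=1e-6)
        assert f.rd == pytest.approx(0.5, abs=1e-6)

    def test_principal_direction_recovery(self, block):
        n = np.array([0.2, -0.3, 0.93])
        n /= np.linalg.norm(n)
        # rotation taking z to n
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(z, n)
        c = z @ n
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx / (1 + c)
        sig = _tensor_signal(block, [0.4, 0.4, 1.8], R)
        f = fit_dti(sig, block)
        angle = np.degrees(np.arccos(abs(f.principal_direction @ n)))
        assert angle < 1.0

    def test_uses_low_shell_only(self, block):
        # corrupt the high shell; DTI output must not change
        sig = _tensor_signal(block, [0.5, 0.5, 1.5])
        corrupted = sig.copy()
        corrupted[block.bvals > 1500] = 0.123
        f1, f2 = fit_dti(sig, block), fit_dti(corrupted, block)
        assert f1.ad == pytest.approx(f2.ad, abs=1e-12)

    def test_too_few_measurements(self, block):
        sig = _tensor_signal(block, [1, 1, 1])
        keep = np.zeros(len(block), dtype=bool)
        keep[:5] = True
        from corddiff.protocol import PGSEProtocol

        tiny = PGSEProtocol(
            block.bvals[keep], block.bvecs[keep], block.Delta[keep], block.delta[keep]
        )
        with pytest.raises(ValueError):
            fit_dti(sig[keep], tiny)


class TestDKI:
    def test_gaussian_data_zero_kurtosis(self, block):
        sig = _tensor_signal(block, [0.5, 0.5, 1.7])
        f = fit_dki(sig, block)
        assert f.ad == pytest.approx(1.7, abs=1e-6)
        assert f.rd == pytest.approx(0.5, abs=1e-6)
        assert abs(f.ak) < 1e-6
        assert abs(f.rk) < 1e-6

    def test_forward_inverse_with_axisymmetric_kurtosis(self, block):
        ad, rd, ak, rk = 1.7, 0.5, 0.8, 1.6
        b, g = block.b_ms_um2, block.bvecs
        c2 = g[:, 2] ** 2
        d_app = rd + (ad - rd) * c2
        # V(g) = K(g)·D(g)²: quartic a + b·gz² with a = RK·RD²,
        # a + b = AK·AD²  (a valid symmetric 4th-order form)
        a = rk * rd**2
        bcoef = ak * ad**2 - a
        v_app = a + bcoef * c2**2
        sig = np.exp(-b * d_app + b**2 / 6.0 * v_app)
        f = fit_dki(sig, block)
        assert f.ad == pytest.approx(ad, rel=0.01)
        assert f.rd == pytest.approx(rd, rel=0.01)
        assert f.ak == pytest.approx(ak, rel=0.01)
        assert f.rk == pytest.approx(rk, rel=0.01)

    def test_isotropic_kurtosis_ak_equals_rk(self, block):
        b = block.b_ms_um2
        sig = np.exp(-b * 1.0 + b**2 / 6.0 * 0.6)  # D iso = 1, V iso = 0.6
        f = fit_dki(sig, block)
        assert f.ak == pytest.approx(f.rk, rel=1e-6)
        assert f.ak == pytest.approx(0.6, rel=1e-6)

    def test_dti_dki_consistency_on_gaussian_data(self, block):
        sig = _tensor_signal(block, [0.6, 0.6, 1.9])
        fd, fk = fit_dti(sig, block), fit_dki(sig, block)
        assert fk.ad == pytest.approx(fd.ad, rel=0.01)
        assert fk.rd == pytest.approx(fd.rd, rel=0.01)

    def test_constraint_activates_on_negative_kurtosis_noise(self, block):
        # craft data whose unconstrained directional kurtosis goes negative
        b, g = block.b_ms_um2, block.bvecs
        c2 = g[:, 2] ** 2
        d_app = 0.5 + 1.2 * c2
        sig = np.exp(-b * d_app + b**2 / 6.0 * (-0.4) * d_app**2)
        f = fit_dki(sig, block)
        assert f.constrained
        k_dirs = f.apparent_kurtosis(g[block.bvals > 0])
        assert np.all(k_dirs >= -1e-6)


class TestSphericalMean:
    def test_direction_independent_signal(self, block):
        sig = np.where(block.bvals == 0, 1.0, 0.42)
        bs, means = spherical_mean(sig, block)
        np.testing.assert_allclose(means, 0.42)
        assert list(bs) == [711.0, 2855.0]

    def test_zeppelin_quadrature_oracle(self, block):
        lam_par, lam_perp = 2.0, 0.5
        truth = ZepParams(
            s0=1, v_s=0.0, d_s_par=1, d_s_perp=0, d_z_par=lam_par,
            d_z_perp=lam_perp, n=np.array([0, 0, 1.0]),
        )
        sig = zep_signal(truth, block)
        bs, means = spherical_mean(sig, block)
        analytic = smt_kernel(bs * 1e-3, lam_par, lam_perp)
        # low shell: 20 repulsion directions resolve the sphere to <0.5%;
        # the 40-direction shell is at least as good
        np.testing.assert_allclose(means, analytic, rtol=0.005)

    def test_stick_closed_form(self):
        lam, b = 2.0, 2.855
        val = smt_kernel(np.array([b]), lam, 0.0)[0]
        assert val == pytest.approx(
            np.sqrt(np.pi / (4 * b * lam)) * erf(np.sqrt(b * lam)), abs=1e-12
        )

    def test_isotropic_limit_continuity(self):
        assert smt_kernel(np.array([2.0]), 1.0, 1.0)[0] == pytest.approx(
            np.exp(-2.0), abs=1e-7
        )


class TestSMTFit:
    bvals = np.array([711.0, 2855.0])

    def test_isotropic_recovery(self):
        d = 0.9
        means = np.exp(-self.bvals * 1e-3 * d)
        f = fit_smt_micro(means, self.bvals)
        assert f.lam_par == pytest.approx(d, abs=1e-4)
        assert f.lam_perp == pytest.approx(d, abs=1e-4)

    def test_anisotropic_recovery(self):
        means = smt_kernel(self.bvals * 1e-3, 2.0, 0.3)
        f = fit_smt_micro(means, self.bvals)
        assert f.lam_par == pytest.approx(2.0, rel=0.02)
        assert f.lam_perp == pytest.approx(0.3, rel=0.02)

    def test_single_shell_underdetermined(self):
        with pytest.raises(ValueError):
            fit_smt_micro(np.array([0.5]), np.array([711.0]))

    def test_rotation_invariance(self, block):
        ests = []
        for tilt in (0.0, 0.4, 0.9):
            n = np.array([np.sin(tilt), 0.0, np.cos(tilt)])
            truth = ZepParams(
                s0=1, v_s=0.0, d_s_par=1, d_s_perp=0, d_z_par=1.8,
                d_z_perp=0.4, n=n,
            )
            bs, means = spherical_mean(zep_signal(truth, block), block)
            f = fit_smt_micro(means, bs)
            ests.append((f.lam_par, f.lam_perp))
        ests = np.array(ests)
        assert np.ptp(ests[:, 0]) / ests[:, 0].mean() < 0.01
        assert np.ptp(ests[:, 1]) / ests[:, 1].mean() < 0.01
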