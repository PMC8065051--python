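"""Unit tests for the kurtosis signal model, estimator and scalar metrics."""

import numpy as np
import pytest

from dktihist.dki import (
    ANTEROPOSTERIOR_AXIS,
    DegenerateTensorError,
    DiffusionTensor,
    GradientScheme,
    KurtosisTensor,
    SchemeError,
    apparent_diffusion,
    apparent_kurtosis,
    diffusion_metrics,
    eigendecompose,
    fit_dki,
    fit_dki_array,
    forward_signal,
    kfa,
    kurtosis_metrics,
    reference_scheme,
)
from dktihist.quadrature import sphere_directions

from conftest import random_rotation, random_tensor_pair


def isotropic_kt(w: float) -> KurtosisTensor:
    """w * I4, which has W_app(n) = w for every unit n."""
    d = np.eye(3)
    t = (np.einsum("ij,kl->ijkl", d, d) + np.einsum("ik,jl->ijkl", d, d)
         + np.einsum("il,jk->ijkl", d, d)) / 3.0
    return KurtosisTensor(w * t)


class TestGradientScheme:
    def test_reference_protocol_shape(self, scheme):
        assert len(scheme) == 91
        assert np.array_equal(scheme.shells, [100.0, 1000.0, 2000.0])
        assert scheme.b0_mask.sum() == 1

    def test_rejects_non_unit_direction(self):
        bad = reference_scheme()
        dirs = bad.directions.copy()
        dirs[5] *= 1.5
        with pytest.raises(SchemeError, match="column 5"):
            GradientScheme(bad.bvalues, dirs)

    def test_rejects_single_shell(self):
        dirs = sphere_directions(30)
        with pytest.raises(SchemeError, match="distinct nonzero b-values"):
            GradientScheme(np.full(30, 1000.0), dirs)

    def test_rejects_too_few_directions(self):
        d = sphere_directions(10)
        bvals = np.r_[np.full(10, 1000.0), np.full(10, 2000.0)]
        with pytest.raises(SchemeError, match="15 distinct"):
            GradientScheme(bvals, np.vstack([d, d]))


class TestApparentDiffusion:
    def test_isotropic_tensor_gives_scalar(self, rng):
        dt = DiffusionTensor(0.7e-3 * np.eye(3))
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        assert apparent_diffusion(dt, n) == pytest.approx(0.7e-3, rel=1e-12)

    def test_eigenvector_direction(self):
        dt = DiffusionTensor(np.diag([1.5e-3, 0.0, 0.0]))
        assert apparent_diffusion(dt, np.array([1.0, 0, 0])) == pytest.approx(1.5e-3)

    def test_matches_bruteforce_double_sum(self, rng):
        dt, _ = random_tensor_pair(rng)
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        brute = sum(n[i] * n[j] * dt.matrix[i, j] for i in range(3) for j in range(3))
        assert apparent_diffusion(dt, n) == pytest.approx(brute, rel=1e-12)

    def test_rejects_non_unit_direction(self):
        dt = DiffusionTensor(np.eye(3) * 1e-3)
        with pytest.raises(ValueError, match="unit norm"):
            apparent_diffusion(dt, np.array([1.0, 1.0, 0.0]))


class TestApparentKurtosis:
    def test_isotropic_kurtosis_constant_over_directions(self, rng):
        dt = DiffusionTensor(1e-3 * np.eye(3))
        kt = isotropic_kt(0.9)
        for _ in range(5):
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            assert apparent_kurtosis(dt, kt, n) == pytest.approx(0.9, rel=1e-10)

    def test_zero_kurtosis_tensor(self, rng):
        dt, _ = random_tensor_pair(rng)
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        assert apparent_kurtosis(dt, KurtosisTensor.zero(), n) == 0.0

    def test_matches_bruteforce_81_term_sum(self, rng):
        dt, kt = random_tensor_pair(rng)
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        w_app = sum(
            n[i] * n[j] * n[k] * n[l] * kt.tensor[i, j, k, l]
            for i in range(3) for j in range(3) for k in range(3) for l in range(3)
        )
        d_app = float(n @ dt.matrix @ n)
        expected = dt.md**2 / d_app**2 * w_app
        assert apparent_kurtosis(dt, kt, n) == pytest.approx(expected, rel=1e-10)

    def test_degenerate_diffusivity_raises(self):
        dt = DiffusionTensor(np.diag([1e-3, 1e-3, 0.0]))
        with pytest.raises(DegenerateTensorError):
            apparent_kurtosis(dt, isotropic_kt(1.0), np.array([0.0, 0.0, 1.0]))


class TestForwardSignal:
    def test_b0_returns_s0_exactly(self, scheme, rng):
        dt, kt = random_tensor_pair(rng)
        sig = forward_signal(123.0, dt, kt, scheme)
        assert float(sig[scheme.b0_mask][0]) == 123.0

    def test_gaussian_limit_monoexponential(self, scheme):
        d = 0.9e-3
        dt = DiffusionTensor(d * np.eye(3))
        sig = forward_signal(1.0, dt, KurtosisTensor.zero(), scheme)
        np.testing.assert_allclose(sig, np.exp(-scheme.bvalues * d), rtol=1e-12)

    def test_closed_form_with_kurtosis(self):
        # ln S = -b d + (b^2/6) d^2 K at b = 2000, d = 0.8e-3, K = 0.8
        b, d, k = 2000.0, 0.8e-3, 0.8
        scheme = GradientScheme(
            np.r_[0.0, np.full(90, 100.0), [b]][: 92],
            np.vstack([np.zeros(3), sphere_directions(90), [[1.0, 0, 0]]]),
        )
        dt = DiffusionTensor(d * np.eye(3))
        sig = forward_signal(1.0, dt, isotropic_kt(k), scheme)
        expected = np.exp(-b * d + b**2 / 6.0 * d**2 * k)
        assert sig[-1] == pytest.approx(expected, rel=1e-12)


class TestFit:
    def test_noiseless_roundtrip(self, scheme, rng):
        for _ in range(20):
            dt, kt = random_tensor_pair(rng)
            s0 = rng.uniform(50, 500)
            fit = fit_dki(forward_signal(s0, dt, kt, scheme), scheme)
            assert fit.valid
            assert fit.s0 == pytest.approx(s0, rel=1e-8)
            np.testing.assert_allclose(fit.dt.unique, dt.unique, rtol=0, atol=1e-6 * np.abs(dt.unique).max())
            np.testing.assert_allclose(fit.kt.unique, kt.unique, rtol=0, atol=1e-6 * np.abs(kt.unique).max())
            assert fit.residual_norm < 1e-8

    def test_constant_signals_flagged_invalid(self, scheme):
        fit = fit_dki(np.full(len(scheme), 80.0), scheme)
        assert not fit.valid

    def test_nonpositive_signals_rejected(self, scheme):
        sig = np.full(len(scheme), 10.0)
        sig[3] = -1.0
        with pytest.raises(ValueError, match="positive"):
            fit_dki(sig, scheme)

    def test_rank_deficient_scheme_raises(self):
        # 15 distinct directions but only along a degenerate two-shell layout
        # with every direction duplicated across shells is still full rank;
        # force deficiency by collapsing all directions to a great circle
        theta = 2 * np.pi * np.arange(20) / 20
        circ = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(20)])
        sch = GradientScheme(
            np.r_[0.0, np.full(20, 1000.0), np.full(20, 2000.0)],
            np.vstack([np.zeros(3), circ, circ]),
        )
        with pytest.raises(SchemeError, match="rank"):
            fit_dki_array(np.full((41, 1), 10.0), sch)

    def test_rician_snr40_median_md_within_10pct(self, scheme):
        # WM-like voxel, 500 Monte-Carlo replicates at SNR 40
        from dktihist.synthetic import RegionSpec, build_tensors

        dt, kt = build_tensors(RegionSpec("wm", "WM", 1.10e-3, 0.35e-3, k_mean=1.17))
        s0 = 100.0
        clean = forward_signal(s0, dt, kt, scheme)
        rng = np.random.default_rng(99)
        sigma = s0 / 40.0
        noisy = np.sqrt(
            (clean[:, None] + rng.normal(0, sigma, (len(scheme), 500))) ** 2
            + rng.normal(0, sigma, (len(scheme), 500)) ** 2
        )
        _, dtu, _, _, valid = fit_dki_array(noisy, scheme)
        md_fit = dtu[valid, :3].mean(axis=1)
        md_true = dt.md
        assert abs(np.median(md_fit) - md_true) / md_true < 0.10


class TestEigendecompose:
    def test_diagonal(self):
        dt = DiffusionTensor(np.diag([3e-3, 2e-3, 1e-3]))
        lam, vecs = eigendecompose(dt)
        np.testing.assert_allclose(lam, [3e-3, 2e-3, 1e-3])
        np.testing.assert_allclose(np.abs(vecs), np.eye(3), atol=1e-12)

    def test_rotation_preserves_eigenvalues(self, rng):
        lam0 = np.array([1.7e-3, 0.5e-3, 0.2e-3])
        rot = random_rotation(rng)
        dt = DiffusionTensor(rot @ np.diag(lam0) @ rot.T)
        lam, vecs = eigendecompose(dt)
        np.testing.assert_allclose(lam, lam0, rtol=1e-10)
        # reconstruction
        recon = sum(lam[i] * np.outer(vecs[:, i], vecs[:, i]) for i in range(3))
        np.testing.assert_allclose(recon, dt.matrix, atol=1e-10)


class TestDiffusionMetrics:
    def test_isotropic(self):
        dm, da, dr, fa = diffusion_metrics(DiffusionTensor(0.8e-3 * np.eye(3)))
        assert fa == pytest.approx(0.0, abs=1e-12)
        assert dm == da == dr == pytest.approx(0.8e-3)

    def test_fully_anisotropic_limit(self):
        _, _, _, fa = diffusion_metrics(DiffusionTensor(np.diag([1e-3, 0, 0])))
        assert fa == pytest.approx(1.0, rel=1e-12)

    def test_hand_evaluated_fa(self):
        lam = np.array([1.7e-3, 0.3e-3, 0.1e-3])
        expected = np.sqrt(1.5 * np.sum((lam - lam.mean()) ** 2) / np.sum(lam**2))
        dm, da, dr, fa = diffusion_metrics(DiffusionTensor(np.diag(lam)))
        assert fa == pytest.approx(expected, rel=1e-12)
        assert da == pytest.approx(1.7e-3)
        assert dr == pytest.approx(0.2e-3)

    def test_d_mean_invariant_to_convention(self, rng):
        dt, _ = random_tensor_pair(rng)
        dm1 = diffusion_metrics(dt, "principal_eigenvector")[0]
        dm2 = diffusion_metrics(dt, "anteroposterior")[0]
        assert dm1 == pytest.approx(dm2, rel=1e-12)

    def test_anteroposterior_axis_projection(self, rng):
        dt, _ = random_tensor_pair(rng)
        _, da, dr, _ = diffusion_metrics(dt, "anteroposterior")
        y = ANTEROPOSTERIOR_AXIS
        assert da == pytest.approx(float(y @ dt.matrix @ y), rel=1e-12)
        # great-circle mean of a quadratic form: (trace - axial)/2
        assert dr == pytest.approx((np.trace(dt.matrix) - da) / 2.0, rel=1e-10)

    def test_zero_tensor_fa_defined_zero(self):
        assert diffusion_metrics(DiffusionTensor(np.zeros((3, 3))))[3] == 0.0


class TestKurtosisMetrics:
    def test_zero_kt_gives_zeros(self, rng):
        dt, _ = random_tensor_pair(rng)
        km, ka, kr = kurtosis_metrics(dt, KurtosisTensor.zero())
        assert km == ka == kr == 0.0

    def test_isotropy_identity(self):
        dt = DiffusionTensor(1.1e-3 * np.eye(3))
        km, ka, kr = kurtosis_metrics(dt, isotropic_kt(0.7))
        assert km == pytest.approx(0.7, abs=1e-6)
        assert ka == pytest.approx(0.7, abs=1e-6)
        assert kr == pytest.approx(0.7, abs=1e-6)

    def test_quadrature_matches_monte_carlo(self, rng):
        from dktihist.dki import DT_MULT, KT_MULT, quadratic_products, quartic_products

        from conftest import random_valid_tensor_pair

        mc = rng.normal(size=(200_000, 3))
        mc /= np.linalg.norm(mc, axis=1, keepdims=True)
        qp, qq = quadratic_products(mc), quartic_products(mc)
        for _ in range(3):
            dt, kt = random_valid_tensor_pair(rng)
            km, _, _ = kurtosis_metrics(dt, kt)
            d_app = qp @ (dt.unique * DT_MULT)
            w_app = qq @ (kt.unique * KT_MULT)
            km_mc = float(np.mean(dt.md**2 / d_app**2 * w_app))
            assert km == pytest.approx(km_mc, rel=0.01)

    def test_requires_enough_directions(self, rng):
        dt, kt = random_tensor_pair(rng)
        with pytest.raises(ValueError, match="60"):
            kurtosis_metrics(dt, kt, sphere=sphere_directions(30))


class TestKfa:
    def test_isotropic_tensor_zero(self):
        assert kfa(isotropic_kt(1.3)) == 0.0

    def test_single_element_closed_form(self):
        # only W1111 = 1: brute-force Frobenius norms over all 81 elements
        u = np.zeros(15)
        u[0] = 1.0
        kt = KurtosisTensor.from_unique(u)
        w = kt.tensor
        wbar = (w[0, 0, 0, 0] + w[1, 1, 1, 1] + w[2, 2, 2, 2]
                + 2 * (w[0, 0, 1, 1] + w[0, 0, 2, 2] + w[1, 1, 2, 2])) / 5.0
        iso = isotropic_kt(1.0).tensor
        expected = np.sqrt(np.sum((w - wbar * iso) ** 2) / np.sum(w**2))
        assert kfa(kt) == pytest.approx(expected, rel=1e-12)
        assert kfa(kt) == pytest.approx(np.sqrt(0.8), rel=1e-12)

    def test_scale_invariance(self, rng):
        _, kt = random_tensor_pair(rng)
        assert kfa(kt) == pytest.approx(kfa(KurtosisTensor(3.7 * kt.tensor)), rel=1e-12)

    def test_zero_tensor_defined_zero(self):
        assert kfa(KurtosisTensor.zero()) == 0.0

    def test_bounds_on_random_tensors(self, rng):
        for _ in range(200):
            _, kt = random_tensor_pair(rng)
            assert 0.0 <= kfa(kt) <= 1.0


class TestRotationEquivariance:
    def test_scalar_metrics_rotation_invariant(self, rng):
        dt, kt = random_tensor_pair(rng)
        rot = random_rotation(rng)
        dtr, ktr = dt.rotated(rot), kt.rotated(rot)
        assert diffusion_metrics(dt)[0] == pytest.approx(diffusion_metrics(dtr)[0], abs=1e-8)
        assert diffusion_metrics(dt)[3] == pytest.approx(diffusion_metrics(dtr)[3], abs=1e-8)
        assert kfa(kt) == pytest.approx(kfa(ktr), abs=1e-8)
        km = kurtosis_metrics(dt, kt)[0]
        kmr = kurtosis_metrics(dtr, ktr)[0]
        # quadrature set is fixed in space, so rotation changes only the
        # quadrature error, not the underlying spherical mean
        assert km == pytest.approx(kmr, abs=5e-4)

    def test_fa_bounds_on_random_tensors(self, rng):
        for _ in range(500):
            dt, _ = random_tensor_pair(rng)
            fa = diffusion_metrics(dt)[3]
            assert 0.0 <= fa <= 1.0
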