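"""Forward models: SM kernel, Legendre/Watson projections, DKI, noise."""

import numpy as np
import pytest
from numpy.polynomial.legendre import leggauss
from scipy.special import erf

from microtract.forward_models import (
    SMParams,
    TensorKurtosisParams,
    add_noise,
    dki_signal,
    kernel_projection,
    sm_kernel,
    sm_signal,
    watson_pl,
)
from microtract.protocol import GradientScheme, generate_directions


def quadrature_sphere_signal(params, b, gvec, n_nodes=160):
    """Brute-force ODF-kernel spherical convolution (independent oracle)."""
    xq, wq = leggauss(n_nodes)
    phi = np.linspace(0, 2 * np.pi, 2 * n_nodes + 1)[:-1]
    wphi = 2 * np.pi / len(phi)
    ct, ph = np.meshgrid(xq, phi, indexing="ij")
    stheta = np.sqrt(1 - ct**2)
    n = np.stack([stheta * np.cos(ph), stheta * np.sin(ph), ct], -1).reshape(-1, 3)
    wts = (np.ones_like(ph) * wq[:, None] * wphi).ravel()
    # rotate z to mu
    z = np.array([0.0, 0.0, 1.0])
    mu = params.mu
    if np.allclose(mu, z):
        R = np.eye(3)
    else:
        v = np.cross(z, mu)
        c = z @ mu
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + K + K @ K / (1 + c)
    nr = n @ R.T
    w_odf = np.exp(params.kappa * n[:, 2] ** 2) * wts
    w_odf /= w_odf.sum()
    xi = np.clip(nr @ gvec, -1, 1)
    return params.s0 * np.sum(w_odf * sm_kernel(b, xi, params))


class TestKernel:
    def test_no_weighting_at_b0(self, baseline_params):
        assert sm_kernel(0.0, 0.3, baseline_params) == pytest.approx(1.0)

    def test_isotropic_zeppelin_independent_of_angle(self):
        p = SMParams(f=0.0, d_c=0.0, de_par=1.3, de_perp=1.3, kappa=0.0)
        vals = [sm_kernel(2.0, xi, p) for xi in (-1, -0.4, 0.0, 0.7, 1.0)]
        assert np.allclose(vals, np.exp(-2.0 * 1.3))

    def test_transverse_stick_unattenuated(self):
        p = SMParams(f=1.0, d_c=2.0, de_par=0.0, de_perp=0.0, kappa=0.0)
        assert sm_kernel(6.0, 0.0, p) == pytest.approx(1.0)

    def test_parameter_invariants_enforced(self):
        with pytest.raises(ValueError):
            SMParams(f=1.2, d_c=2.0, de_par=2.0, de_perp=0.5, kappa=1.0)
        with pytest.raises(ValueError):
            SMParams(f=0.5, d_c=2.0, de_par=0.5, de_perp=2.0, kappa=1.0)


class TestKernelProjection:
    def test_stick_spherical_mean_closed_form(self):
        # K_0 for a stick: sqrt(pi/(4 b D)) * erf(sqrt(b D)); bD = 12
        p = SMParams(f=1.0, d_c=2.0, de_par=0.0, de_perp=0.0, kappa=0.0)
        bd = 12.0
        closed = np.sqrt(np.pi / (4 * bd)) * erf(np.sqrt(bd))
        assert kernel_projection(6.0, p, 0) == pytest.approx(closed, abs=1e-9)
        # cross-check against a denser quadrature oracle
        assert kernel_projection(6.0, p, 0, n_nodes=256) == pytest.approx(
            closed, abs=1e-12
        )

    def test_b0_projections(self, baseline_params):
        assert kernel_projection(0.0, baseline_params, 0) == pytest.approx(1.0)
        assert kernel_projection(0.0, baseline_params, 2) == pytest.approx(0.0, abs=1e-14)

    def test_odd_order_rejected(self, baseline_params):
        with pytest.raises(ValueError):
            kernel_projection(1.0, baseline_params, 3)


class TestWatsonMoments:
    def test_uniform_odf_has_zero_p2(self):
        assert watson_pl(0.0, 2) == pytest.approx(0.0, abs=1e-14)

    def test_delta_limit(self):
        assert watson_pl(1000.0, 2) > 0.99

    def test_p0_is_one_for_any_kappa(self):
        for k in (0.0, 1.0, 16.0, 200.0):
            assert watson_pl(k, 0) == pytest.approx(1.0)

    def test_p2_monotone_in_kappa(self):
        ks = np.linspace(0, 64, 30)
        p2 = watson_pl(ks, 2)
        assert np.all(np.diff(p2) > 0)

    def test_p2_matches_rejection_sampling(self, rng):
        kappa = 16.0
        n = 10**6
        xi = rng.uniform(0, 1, 2 * n)
        accept = rng.uniform(0, 1, 2 * n) < np.exp(kappa * (xi**2 - 1.0))
        xs = xi[accept][:n]
        p2_mc = np.mean(1.5 * xs**2 - 0.5)
        se = np.std(1.5 * xs**2 - 0.5) / np.sqrt(len(xs))
        assert watson_pl(kappa, 2) == pytest.approx(p2_mc, abs=3 * se)


class TestSMSignal:
    def test_b0_returns_s0(self, baseline_params, scheme):
        sig = sm_signal(baseline_params, scheme)
        assert np.allclose(sig[scheme.b0_mask], baseline_params.s0)

    def test_coherent_stick_along_fiber(self):
        p = SMParams(f=1.0, d_c=2.0, de_par=0.0, de_perp=0.0, kappa=1e4,
                     mu=np.array([0.0, 0.0, 1.0]))
        sch = GradientScheme(np.array([6.0]), np.array([[0.0, 0.0, 1.0]]))
        assert sm_signal(p, sch)[0] == pytest.approx(np.exp(-12.0), rel=5e-2)

    def test_matches_spherical_quadrature(self, baseline_params, scheme):
        rng = np.random.default_rng(0)
        pick = rng.choice(np.flatnonzero(~scheme.b0_mask), 12, replace=False)
        sig = sm_signal(baseline_params, scheme)
        for i in pick:
            oracle = quadrature_sphere_signal(
                baseline_params, scheme.bvals[i], scheme.bvecs[i]
            )
            assert sig[i] == pytest.approx(oracle, rel=1e-4)

    def test_rotation_equivariance(self, baseline_params, scheme):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec([0.3, -0.5, 1.1]).as_matrix()
        mu_r = R @ baseline_params.mu
        p_r = SMParams(
            f=baseline_params.f, d_c=baseline_params.d_c,
            de_par=baseline_params.de_par, de_perp=baseline_params.de_perp,
            kappa=baseline_params.kappa, mu=mu_r / np.linalg.norm(mu_r),
        )
        sch_r = GradientScheme(scheme.bvals, scheme.bvecs @ R.T)
        assert np.allclose(
            sm_signal(baseline_params, scheme), sm_signal(p_r, sch_r), atol=1e-6
        )

    def test_monotone_nonincreasing_in_b(self, baseline_params):
        g = np.array([0.0, 0.6, 0.8])
        bs = np.linspace(0, 6, 13)
        sch = GradientScheme(bs, np.tile(g, (13, 1)) * (bs > 0)[:, None]
                             + np.array([0.0, 0.0, 0.0]))
        # directions must be unit for b>0: rebuild properly
        vecs = np.tile(g, (13, 1))
        vecs[bs == 0] = 0.0
        sch = GradientScheme(bs, vecs)
        sig = sm_signal(baseline_params, sch)
        assert np.all(np.diff(sig) <= 1e-12)

    def test_truncation_error_decreases_with_lmax(self, baseline_params, scheme):
        ref = sm_signal(baseline_params, scheme, l_max=40)
        errs = [
            np.max(np.abs(sm_signal(baseline_params, scheme, l_max=lm) - ref))
            for lm in (8, 16, 24, 32)
        ]
        assert all(a >= b for a, b in zip(errs, errs[1:]))


class TestDKISignal:
    def test_isotropic_gaussian_is_monoexponential(self, scheme):
        tk = TensorKurtosisParams(1.0, 1.1 * np.eye(3), np.zeros((3, 3, 3, 3)))
        sig = dki_signal(tk, scheme)
        assert np.allclose(sig, np.exp(-1.1 * scheme.bvals))

    def test_b0_returns_s0(self, scheme):
        tk = TensorKurtosisParams(2.5, np.eye(3), np.zeros((3, 3, 3, 3)))
        assert np.allclose(dki_signal(tk, scheme)[scheme.b0_mask], 2.5)

    def test_mixture_apparent_kurtosis_by_finite_difference(self):
        # ln S of a 50/50 mixture of D=1 and D=2 along one axis:
        # d²/db² ln S at b->0 equals Var(D) = 0.25, so
        # K = 3 Var/E² = 1/3 in the cumulant parametrization.
        b = np.array([1e-4, 2e-4, 3e-4])
        lnS = np.log(0.5 * np.exp(-b) + 0.5 * np.exp(-2 * b))
        d2 = np.diff(lnS, 2) / (1e-4) ** 2
        var = d2[0]
        mean = 1.5
        assert 3 * var / mean**2 == pytest.approx(1.0 / 3.0, rel=1e-2)

    def test_psd_and_symmetry_enforced(self):
        with pytest.raises(ValueError):
            TensorKurtosisParams(1.0, np.diag([1.0, -0.5, 1.0]), np.zeros((3, 3, 3, 3)))
        W = np.zeros((3, 3, 3, 3))
        W[0, 0, 0, 1] = 1.0  # not symmetrized
        with pytest.raises(ValueError):
            TensorKurtosisParams(1.0, np.eye(3), W)


class TestNoise:
    def test_infinite_snr_identity(self, rng):
        sig = rng.uniform(0.1, 1.0, 50)
        assert np.array_equal(add_noise(sig, np.inf, seed=3), sig)

    def test_seed_determinism(self, rng):
        sig = rng.uniform(0.1, 1.0, 50)
        a = add_noise(sig, 30.0, seed=9)
        b = add_noise(sig, 30.0, seed=9)
        assert np.array_equal(a, b)

    def test_rician_mean_at_zero_signal_is_rayleigh(self):
        snr = 25.0
        sigma = 1.0 / snr
        noisy = add_noise(np.zeros(10**5), snr, model="rician", seed=0)
        expected = sigma * np.sqrt(np.pi / 2.0)
        se = sigma * np.sqrt((4 - np.pi) / 2) / np.sqrt(10**5)
        assert noisy.mean() == pytest.approx(expected, abs=4 * se)

    def test_gaussian_noise_scale(self):
        noisy = add_noise(np.full(10**5, 0.5), 20.0, model="gaussian", seed=1)
        assert noisy.std() == pytest.approx(1 / 20.0, rel=0.02)
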