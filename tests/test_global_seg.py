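"""Global stage: Heaviside pair, three-region model, DR Chan-Vese."""

import numpy as np
import pytest

from mammoseg import global_seg, metrics, mico
from mammoseg._levelset import grad_mag, signed_distance

from conftest import disc_image, make_disc


class TestHeaviside:
    def test_center_value_and_symmetry(self):
        z = np.linspace(-5, 5, 41)
        H = global_seg.smoothed_heaviside(z, 1.0)
        assert H[20] == pytest.approx(0.5)
        np.testing.assert_allclose(H + H[::-1], 1.0, atol=1e-14)

    @pytest.mark.parametrize("z0", [-2.0, 0.0, 2.0])
    def test_dirac_is_derivative(self, z0):
        h = 1e-6
        fd = (
            global_seg.smoothed_heaviside(np.array([z0 + h]), 1.0)
            - global_seg.smoothed_heaviside(np.array([z0 - h]), 1.0)
        ) / (2 * h)
        assert fd[0] == pytest.approx(global_seg.smoothed_dirac(np.array([z0]), 1.0)[0], abs=1e-6)

    def test_partition_of_unity(self):
        rng = np.random.default_rng(0)
        mu1 = rng.normal(0, 3, (16, 16))
        mu2 = rng.normal(0, 3, (16, 16))
        Mc = global_seg.region_indicators(mu1, mu2, crisp=True)
        np.testing.assert_array_equal(sum(Mc), 1.0)
        Ms = global_seg.region_indicators(mu1, mu2, eps=1.0)
        np.testing.assert_allclose(sum(Ms), 1.0, atol=1e-9)


class TestInitLevelsets:
    def test_disc_membership_signed_distance(self):
        disc = make_disc(radius=12)
        mu1, mu2 = global_seg.init_levelsets(disc.astype(float))
        assert (mu1[disc] > 0).all() and (mu1[~disc] < 0).all()
        # signed-distance property away from the interface
        band = np.abs(mu1) > 2
        assert np.percentile(np.abs(grad_mag(mu1)[band] - 1), 90) < 0.2

    def test_three_class_stack_partitions_by_brightness(self):
        inner = make_disc(radius=8)
        outer = make_disc(radius=20)
        M = np.stack([(~outer), outer & ~inner, inner]).astype(float)
        mu1, mu2 = global_seg.init_levelsets(M)
        M1, M2, M3 = global_seg.region_indicators(mu1, mu2, crisp=True)
        assert np.array_equal(M1 > 0, inner)
        assert np.array_equal(M2 > 0, outer & ~inner)
        assert np.array_equal(M3 > 0, ~outer)

    def test_degenerate_membership_warns(self):
        with pytest.warns(UserWarning, match="no interface"):
            global_seg.init_levelsets(np.ones((16, 16)))


class TestMultiphaseEnergy:
    def _state(self, mu1, mu2, means=(200.0, 120.0, 60.0), nu=1.0, mu_dr=1.0):
        return global_seg.MultiphaseState(
            mu1=mu1,
            mu2=mu2,
            means=np.asarray(means, dtype=float),
            bias=mico.BiasField(values=np.ones(mu1.shape)),
            nu=nu,
            mu_dr=mu_dr,
        )

    def test_signed_distance_zeroes_dr_term(self):
        phi = signed_distance(make_disc(radius=12))
        img = disc_image(radius=12, lo=60.0, hi=200.0)
        e_lo = self._state(phi, phi, mu_dr=0.0)
        e_hi = self._state(phi, phi, mu_dr=10.0)
        a = global_seg.multiphase_energy(img, e_lo)
        b = global_seg.multiphase_energy(img, e_hi)
        # DR contribution grows 10x but stays a tiny fraction of the data term
        assert (b - a) / max(a, 1.0) < 0.35

    def test_doubling_nu_doubles_length_term_only(self):
        rng = np.random.default_rng(1)
        mu1 = rng.normal(0, 3, (32, 32))
        mu2 = rng.normal(0, 3, (32, 32))
        img = rng.uniform(0, 255, (32, 32))
        e1 = global_seg.multiphase_energy(img, self._state(mu1, mu2, nu=1.0))
        e2 = global_seg.multiphase_energy(img, self._state(mu1, mu2, nu=2.0))
        e3 = global_seg.multiphase_energy(img, self._state(mu1, mu2, nu=3.0))
        assert e3 - e2 == pytest.approx(e2 - e1, rel=1e-9)


class TestBiasSmoothed:
    def test_constant_one_class(self):
        phi = np.full((32, 32), 5.0)  # everything inside both level sets
        st = global_seg.MultiphaseState(
            mu1=phi, mu2=phi, means=np.array([50.0, 1.0, 1.0]),
            bias=mico.BiasField(values=np.ones((32, 32))),
        )
        bf = global_seg.update_bias_smoothed(np.full((32, 32), 100.0), st, sigma=3.0)
        np.testing.assert_allclose(bf.values, 2.0, atol=0.05)

    def test_narrow_kernel_approaches_pointwise_ratio(self):
        rng = np.random.default_rng(2)
        mu1 = rng.normal(0, 3, (32, 32))
        mu2 = rng.normal(0, 3, (32, 32))
        img = rng.uniform(50, 200, (32, 32))
        st = global_seg.MultiphaseState(
            mu1=mu1, mu2=mu2, means=np.array([180.0, 110.0, 60.0]),
            bias=mico.BiasField(values=np.ones((32, 32))),
        )
        M = global_seg.region_indicators(mu1, mu2, 1.0)
        s1 = sum(c * Mi for c, Mi in zip(st.means, M))
        s2 = sum(c**2 * Mi for c, Mi in zip(st.means, M))
        bf = global_seg.update_bias_smoothed(img, st, sigma=0.05)
        np.testing.assert_allclose(bf.values, img * s1 / s2, rtol=1e-3)


class TestMultiphaseEvolution:
    def test_mirror_symmetry_preserved(self):
        img = np.full((48, 64), 60.0)
        img[make_disc((48, 64), (24, 20), 8)] = 200.0
        img[make_disc((48, 64), (24, 43), 8)] = 200.0  # mirror of col 20 on a 64-wide grid
        assert np.array_equal(img, img[:, ::-1])
        bright = img == 200.0
        mu1 = signed_distance(bright)
        st = global_seg.MultiphaseState(
            mu1=mu1.copy(), mu2=mu1.copy(), means=np.array([200.0, 60.0, 60.0]),
            bias=mico.BiasField(values=np.ones(img.shape)),
        )
        for _ in range(10):
            st = global_seg.evolve_multiphase_step(img, st)
        np.testing.assert_allclose(st.mu1, st.mu1[:, ::-1], atol=1e-6)
        np.testing.assert_allclose(st.mu2, st.mu2[:, ::-1], atol=1e-6)

    def test_three_class_phantom_recovered(self):
        inner = make_disc((64, 64), (32, 32), 10)
        outer = make_disc((64, 64), (32, 32), 24)
        img = np.where(inner, 200.0, np.where(outer, 120.0, 60.0))
        # deliberately imperfect init: dilated/shifted regions
        init_inner = make_disc((64, 64), (34, 34), 12)
        init_outer = make_disc((64, 64), (33, 31), 27)
        st = global_seg.MultiphaseState(
            mu1=signed_distance(init_outer),
            mu2=signed_distance(init_inner),
            means=np.array([200.0, 120.0, 60.0]),
            bias=mico.BiasField(values=np.ones(img.shape)),
        )
        st = global_seg.evolve_multiphase(img, st, iters=200)
        M1, M2, M3 = global_seg.region_indicators(st.mu1, st.mu2, crisp=True)
        assert metrics.dice(inner, M1 > 0) >= 0.95
        assert metrics.dice(outer & ~inner, M2 > 0) >= 0.95
        assert metrics.dice(~outer, M3 > 0) >= 0.95

    def test_reconstruct_cartoon_three_values(self):
        phi = signed_distance(make_disc(radius=10))
        st = global_seg.MultiphaseState(
            mu1=phi, mu2=phi - 4.0, means=np.array([200.0, 120.0, 60.0]),
            bias=mico.BiasField(values=np.ones(phi.shape)),
        )
        cartoon, labels = global_seg.reconstruct_segmented(st)
        assert set(np.unique(cartoon)) <= {200.0, 120.0, 60.0}
        assert set(np.unique(labels)) <= {1, 2, 3}
        assert (labels > 0).all()  # partition: every pixel labeled


class TestDRCV:
    def test_disc_converges_from_offset_init(self):
        img = disc_image((64, 64), (32, 32), 15)
        phi0 = signed_distance(make_disc((64, 64), (24, 24), 10))
        phi = global_seg.evolve_drcv(img, phi0, iters=250)
        assert metrics.dice(make_disc((64, 64), (32, 32), 15), phi > 0) >= 0.98

    def test_constant_image_contour_shrinks(self):
        img = np.full((64, 64), 100.0)
        phi0 = signed_distance(make_disc(radius=20))
        phi = global_seg.evolve_drcv(img, phi0, iters=150)
        assert (phi > 0).sum() < (phi0 > 0).sum()

    def test_step_edge_stationary_when_balanced(self):
        img = np.full((32, 64), 50.0)
        img[:, 32:] = 150.0
        phi0 = np.tile(np.arange(64, dtype=float) - 31.5, (32, 1))
        phi = global_seg.evolve_drcv(img, phi0, iters=100, nu=0.0)
        cross = np.argmax(phi > 0, axis=1)
        assert np.abs(cross - 32).max() <= 1

    def test_signed_distance_property_in_band(self):
        img = disc_image((64, 64), (32, 32), 15)
        phi0 = signed_distance(make_disc((64, 64), (28, 28), 12))
        phi = global_seg.evolve_drcv(img, phi0, iters=250)
        band = np.abs(phi) < 3
        g = grad_mag(phi)[band]
        assert ((g > 0.8) & (g < 1.2)).mean() >= 0.9


class TestGlobalMask:
    def test_explicit_threshold(self):
        I_bc = np.array([[10.0, 200.0], [30.0, 250.0]])
        I_bc = np.kron(I_bc, np.ones((4, 4)))  # meet the 8x8 minimum
        out = global_seg.global_mask(I_bc, 100.0)
        np.testing.assert_array_equal(out, np.kron(np.array([[0, 1], [0, 1]]), np.ones((4, 4), dtype=int)))

    def test_threshold_extremes(self):
        img = disc_image()
        assert global_seg.global_mask(img, 10.0).all()
        assert not global_seg.global_mask(img, 999.0).any()

    def test_auto_otsu_with_levelset_interior(self):
        img = disc_image((64, 64), (32, 32), 15, lo=60.0, hi=200.0)
        phi = signed_distance(make_disc((64, 64), (32, 32), 15))
        mask = global_seg.global_mask(img, "auto", phi=phi)
        assert metrics.dice(make_disc((64, 64), (32, 32), 15), mask) >= 0.99
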