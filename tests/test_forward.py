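"""Projection and Fresnel-propagation physics against closed forms and a
direct-integration oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xpct import Geometry, acquire_scan, fresnel_propagate, project_transmission
from xpct.forward import HC_KEV_M, wavelength_m


def slab_grids(n=32, thickness_vox=10, delta=2.6e-7, beta=1.2e-10):
    d = np.zeros((4, n, n))
    b = np.zeros((4, n, n))
    lo = (n - thickness_vox) // 2
    d[:, lo:lo + thickness_vox, :] = delta
    b[:, lo:lo + thickness_vox, :] = beta
    return d, b


class TestProjection:
    def test_uniform_slab_phase_closed_form(self):
        voxel = 3.5
        delta0 = 2.6e-7
        d, b = slab_grids(thickness_vox=10, delta=delta0, beta=0.0)
        geom = Geometry.micro_default(n_angles=1)
        t = project_transmission(d, b, 0.0, geom, voxel)
        T = 10 * voxel * 1e-6
        expected = -2 * np.pi * delta0 * T / geom.wavelength_m
        phase = np.angle(t) + 2 * np.pi * np.round((expected - np.angle(t)) / (2 * np.pi))
        assert np.allclose(phase, expected, rtol=1e-9)

    def test_zero_absorption_gives_unit_modulus(self):
        d, b = slab_grids(beta=0.0)
        geom = Geometry.micro_default(n_angles=1)
        t = project_transmission(d, b, 33.0, geom, 3.5)
        assert np.allclose(np.abs(t), 1.0, atol=1e-12)

    def test_sphere_projected_thickness_matches_chord_length(self):
        n, r = 64, 20
        zz, yy, xx = np.meshgrid(*([np.arange(n) - (n - 1) / 2] * 3), indexing="ij")
        sphere = (zz**2 + yy**2 + xx**2 <= r * r).astype(float)
        beta0 = 1e-10
        geom = Geometry.micro_default(n_angles=1)
        t = project_transmission(np.zeros_like(sphere), sphere * beta0, 0.0, geom, 3.5)
        thick_vox = -np.log(np.abs(t) ** 2) / (2 * (2 * np.pi / geom.wavelength_m)
                                               * beta0 * 3.5e-6)
        chord = 2 * np.sqrt(np.maximum(r * r - zz[:, 0, :] ** 2 - xx[0] ** 2, 0))
        inside = chord > 6  # away from the tangent rim
        assert np.max(np.abs(thick_vox - chord)[inside]) <= 1.0

    def test_projection_is_linear_in_the_object(self, rng):
        n = 32
        a = rng.random((4, n, n)) * 1e-8
        b = rng.random((4, n, n)) * 1e-8
        geom = Geometry.micro_default(n_angles=1)
        za = np.angle(project_transmission(a, np.zeros_like(a), 25.0, geom, 3.5))
        zb = np.angle(project_transmission(b, np.zeros_like(b), 25.0, geom, 3.5))
        zab = np.angle(project_transmission(a + b, np.zeros_like(a), 25.0, geom, 3.5))
        assert np.allclose(zab, za + zb, atol=1e-9)


class TestFresnel:
    def test_zero_distance_is_exact_identity(self, rng):
        t = np.exp(1j * rng.random((32, 32)))
        out = fresnel_propagate(t, 0.0, 4.1e-11, 3.5)
        assert np.array_equal(out, np.abs(t) ** 2)

    def test_pure_phase_energy_conservation(self):
        n = 64
        yy, xx = np.meshgrid(*([np.arange(n) - n / 2] * 2), indexing="ij")
        phi = 0.3 * np.exp(-(yy**2 + xx**2) / (2 * 6**2))  # compact bump
        t = np.exp(1j * phi)
        lam = wavelength_m(30.0)
        out = fresnel_propagate(t, 2.3, lam, 3.5)
        assert out.sum() == pytest.approx(n * n, rel=1e-4)
        assert np.all(out >= 0)

    def test_edge_fringe_spacing_matches_direct_integration_oracle(self):
        # 1-D direct (quadrature) Fresnel integral over a phase edge
        lam = wavelength_m(30.0)
        D = 2.3
        p = 3.5e-6
        n = 512
        x = (np.arange(n) - n / 2) * p
        phi_edge = np.where(x > 0, 0.3, 0.0)
        t1d = np.exp(1j * phi_edge)
        # oracle: direct quadrature of the Fresnel integral on a 16x
        # oversampled source grid (the kernel chirp must be resolved)
        ov = 16
        xs_src = (np.arange(n * ov) - n * ov / 2) * (p / ov)
        t_src = np.exp(1j * np.where(xs_src > 0, 0.3, 0.0))
        dx = x[:, None] - xs_src[None, :]
        # taper beyond the range where the sampled chirp is still resolved
        w = np.clip((200e-6 - np.abs(dx)) / 50e-6, 0, 1)
        w = 0.5 - 0.5 * np.cos(np.pi * w)
        kernel = np.exp(1j * np.pi * dx**2 / (lam * D)) * w
        I_direct = np.abs((kernel * t_src[None, :]).sum(axis=1) * (p / ov) /
                          np.sqrt(lam * D)) ** 2
        I_fft = fresnel_propagate(np.tile(t1d, (4, 1)), D, lam, 3.5)[0]
        peak_direct = x[np.argmax(I_direct[n // 2:n // 2 + 40]) + n // 2]
        peak_fft = x[np.argmax(I_fft[n // 2:n // 2 + 40]) + n // 2]
        assert abs(peak_direct - peak_fft) <= p
        assert peak_fft == pytest.approx(np.sqrt(lam * D), abs=3 * p)

    def test_low_fresnel_number_warns(self):
        with pytest.warns(UserWarning, match="Fresnel number"):
            fresnel_propagate(np.ones((16, 16), complex), 1.0, 1e-10, 0.5)


class TestGeometry:
    @given(st.floats(min_value=5.0, max_value=120.0))
    @settings(max_examples=25, deadline=None)
    def test_wavelength_energy_product_is_hc(self, energy):
        assert wavelength_m(energy) * energy == pytest.approx(HC_KEV_M, rel=1e-6)

    def test_cone_beam_magnification_matches_instrument(self):
        geom = Geometry.nano_default()
        assert geom.magnification == pytest.approx(3.0 / 0.13, rel=1e-9)
        assert round(geom.magnification) == 23
        assert geom.effective_pixel_um == pytest.approx(0.13, rel=1e-9)
        z1, z2 = geom.z1_m, geom.z2_m
        assert geom.effective_distance_m == pytest.approx(z1 * z2 / (z1 + z2))

    def test_default_angle_counts(self):
        assert Geometry.micro_default().n_angles == 2000
        assert Geometry.nano_default().n_angles == 1500
        a = Geometry.micro_default(n_angles=8).angles_deg
        assert a[0] == 0.0 and a[-1] < 360.0 and len(a) == 8


class TestAcquire:
    def test_empty_contrast_object_gives_unit_frames(self):
        d = np.zeros((8, 32, 32))
        geom = Geometry(distance_m=2.3, pixel_size_um=3.5, n_angles=4,
                        angular_range_deg=360.0, photon_count=0)
        ps = acquire_scan(d, d, geom, voxel_size_um=3.5)
        assert np.allclose(ps.frames, 1.0, atol=1e-9)

    def test_opposite_angles_are_mirror_images(self, rng):
        n = 48
        d = np.zeros((6, n, n))
        zz, yy, xx = np.meshgrid(np.arange(6), np.arange(n) - 23.5,
                                 np.arange(n) - 23.5, indexing="ij")
        disc = (yy - 6) ** 2 + (xx + 9) ** 2 < 49
        d[disc] = 2e-7
        geom = Geometry(distance_m=0.0, pixel_size_um=3.5, n_angles=8,
                        angular_range_deg=360.0, photon_count=0)
        ps = acquire_scan(d, d * 1e-3, geom, voxel_size_um=3.5)
        f0 = ps.frames[0, 0]
        f180 = ps.frames[0, 4]
        assert np.corrcoef(f0.ravel(), f180[:, ::-1].ravel())[0, 1] > 0.999

    def test_object_outside_window_raises(self):
        d = np.zeros((4, 32, 32))
        geom = Geometry(distance_m=0.1, pixel_size_um=3.5, n_angles=2,
                        angular_range_deg=360.0, detector_width=20,
                        axis_offset_px=12.0, photon_count=0)
        with pytest.raises(ValueError, match="field of view"):
            acquire_scan(d, d, geom, voxel_size_um=3.5)

    def test_poisson_noise_is_seeded(self):
        d = np.full((4, 16, 16), 1e-8)
        geom = Geometry(distance_m=0.5, pixel_size_um=3.5, n_angles=3,
                        angular_range_deg=180.0, photon_count=100)
        a = acquire_scan(d, d * 1e-3, geom, voxel_size_um=3.5, seed=5)
        b = acquire_scan(d, d * 1e-3, geom, voxel_size_um=3.5, seed=5)
        c = acquire_scan(d, d * 1e-3, geom, voxel_size_um=3.5, seed=6)
        assert np.array_equal(a.frames, b.frames)
        assert not np.array_equal(a.frames, c.frames)
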