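import numpy as np
import pytest
from scipy import ndimage
from scipy.optimize import brentq

from conftest import site_truth
from locrec.geometry import SubunitVector, point_group
from locrec.io import CtfParams, DensityMap, MaskMap, ParticleRecord
from locrec.simulate import render_blob_projection, render_blobs
from locrec.geometry import euler_to_matrix
from locrec.subtraction import (FourierProjector, apply_ctf, ctf_evaluate,
                                electron_wavelength, make_spherical_mask,
                                mask_to_background, project,
                                project_real_space, subtract_projection,
                                symmetrize_mask)


class TestSphericalMask:
    def test_binary_when_hard_edged(self):
        v = SubunitVector(direction=(0, 0, 1), length=20.0)
        m = make_spherical_mask(v, diameter=16.0, box_size=48, apix=2.0)
        assert set(np.unique(m.data)) <= {0.0, 1.0}

    def test_volume_tracks_sphere(self):
        v = SubunitVector(direction=(1, 0, 0), length=10.0)
        m = make_spherical_mask(v, diameter=24.0, box_size=64, apix=2.0)
        r_px = 6.0
        expect = 4.0 / 3.0 * np.pi * r_px ** 3
        assert abs(m.data.sum() - expect) / expect < 0.15

    def test_center_at_vector_endpoint(self):
        # a mask 100 A out on a threefold axis at 1.35 A/px sits 74.1 px
        # from the map center
        v = SubunitVector(direction=(1, 1, 1), length=100.0)
        m = make_spherical_mask(v, diameter=80.0, box_size=256, apix=1.35)
        com = np.array(ndimage.center_of_mass(m.data))[::-1]  # (x, y, z)
        d = np.linalg.norm(com - 128.0)
        assert abs(d - 100.0 / 1.35) < 0.5

    def test_soft_edge_stays_in_unit_interval(self):
        v = SubunitVector(direction=(0, 1, 0), length=15.0)
        m = make_spherical_mask(v, 20.0, 64, 2.0, soft_edge_px=3.0)
        assert m.data.min() >= 0.0 and m.data.max() <= 1.0
        assert np.any((m.data > 0.05) & (m.data < 0.95))  # the ramp exists

    def test_sphere_outside_grid_rejected(self):
        v = SubunitVector(direction=(0, 0, 1), length=100.0)
        with pytest.raises(ValueError, match="fit"):
            make_spherical_mask(v, diameter=40.0, box_size=64, apix=2.0)


class TestSymmetrizeMask:
    def test_c1_unchanged(self):
        v = SubunitVector(direction=(1, 0, 0), length=15.0)
        m = make_spherical_mask(v, 12.0, 48, 2.0)
        out = symmetrize_mask(m, point_group("C1"))
        assert np.array_equal(out.data, m.data)

    def test_threefold_axis_sphere_has_twenty_copies(self):
        v = SubunitVector(direction=(1, 1, 1), length=32.0)
        m = make_spherical_mask(v, 14.0, 64, 2.0)
        out = symmetrize_mask(m, point_group("I"))
        labels, n = ndimage.label(out.data > 0.5)
        assert n == 20
        # component centers coincide with the vector orbit
        coms = np.array(ndimage.center_of_mass(out.data > 0.5, labels,
                                               range(1, n + 1)))[:, ::-1]
        orbit = point_group("I").orbit(v.cartesian) / 2.0 + 32.0
        for c in coms:
            assert np.min(np.linalg.norm(orbit - c, axis=1)) < 0.5

    def test_union_bound_on_covered_volume(self):
        v = SubunitVector(direction=(0.3, 0.5, 0.81), length=30.0)
        m = make_spherical_mask(v, 10.0, 64, 2.0)
        out = symmetrize_mask(m, point_group("I"))
        assert out.data.sum() <= 60 * m.data.sum() * 1.05

    def test_idempotent_within_interpolation(self):
        v = SubunitVector(direction=(1, 1, 1), length=30.0)
        m = make_spherical_mask(v, 14.0, 48, 2.0, soft_edge_px=2.0)
        once = symmetrize_mask(m, point_group("T"))
        twice = symmetrize_mask(once, point_group("T"))
        assert np.abs(twice.data - once.data).mean() < 1e-3
        assert np.abs(twice.data - once.data).max() < 0.1


class TestMaskToBackground:
    def test_empty_mask_is_noop(self):
        rng = np.random.default_rng(0)
        d = DensityMap(rng.normal(size=(32, 32, 32)), apix=2.0)
        m = MaskMap(np.zeros((32, 32, 32)), apix=2.0)
        out = mask_to_background(d, m)
        assert np.allclose(out.data, d.data)

    def test_full_coverage_rejected(self):
        d = DensityMap(np.ones((16, 16, 16)), apix=1.0)
        with pytest.raises(ValueError, match="entire grid"):
            mask_to_background(d, MaskMap(np.ones((16, 16, 16)), apix=1.0))

    def test_grid_mismatch_rejected(self):
        d = DensityMap(np.ones((16, 16, 16)), apix=1.0)
        with pytest.raises(ValueError, match="grid"):
            mask_to_background(d, MaskMap(np.zeros((8, 8, 8)), apix=1.0))

    def test_residual_matches_shell_ground_truth(self):
        # masking the subunit sites out of the full phantom recovers the shell;
        # geometry chosen so the masks clear the shell density
        from locrec.simulate import PhantomSpec, make_phantom
        spec = PhantomSpec(shell_radius=60.0, shell_sigma=4.0,
                           vector=SubunitVector(direction=(1, 1, 1), length=28.0),
                           subunit_sigma=4.0, satellite_offset=7.0,
                           satellite_sigma=2.5, occupancy=0.7, seed=2)
        full, shell, _, _ = make_phantom(spec, 96, 2.0)
        m = make_spherical_mask(spec.vector, diameter=30.0, box_size=96, apix=2.0)
        msym = symmetrize_mask(m, point_group(spec.symmetry))
        out = mask_to_background(full, msym)
        a = out.data.ravel() - out.data.mean()
        b = shell.data.ravel() - shell.data.mean()
        corr = a @ b / np.sqrt((a @ a) * (b @ b))
        assert corr >= 0.99


class TestProjector:
    def test_identity_pose_equals_beam_sum(self):
        rng = np.random.default_rng(1)
        vol = DensityMap(
            ndimage.gaussian_filter(rng.normal(size=(32, 32, 32)), 2.0), apix=2.0)
        img = project(vol, (0, 0, 0))
        assert np.allclose(img, vol.data.sum(axis=0), atol=1e-6 * np.abs(img).max())

    def test_uniform_map_projects_uniformly(self):
        vol = DensityMap(np.full((32, 32, 32), 0.5), apix=1.0)
        img = project(vol, (0, 0, 0))
        assert np.allclose(img, 16.0, atol=1e-6)

    def test_linearity(self):
        rng = np.random.default_rng(2)
        m1 = ndimage.gaussian_filter(rng.normal(size=(24, 24, 24)), 1.5)
        m2 = ndimage.gaussian_filter(rng.normal(size=(24, 24, 24)), 1.5)
        e = (25.0, 70.0, -10.0)
        lhs = project(DensityMap(3 * m1 + 2 * m2, apix=1.0), e)
        rhs = 3 * project(DensityMap(m1, apix=1.0), e) + 2 * project(DensityMap(m2, apix=1.0), e)
        assert np.allclose(lhs, rhs, atol=1e-8 * np.abs(lhs).max())

    def test_fourier_agrees_with_real_space_rotate_and_sum(self):
        # band-limited phantom, many random poses
        rng = np.random.default_rng(3)
        centers = rng.uniform(-20, 20, size=(6, 3))
        vol = DensityMap(render_blobs(48, 2.0, centers, 5.0, 1.0), apix=2.0)
        projector = FourierProjector(vol)
        for _ in range(100):
            e = rng.uniform([-180, 0, -180], [180, 180, 180])
            origin = tuple(rng.uniform(-2, 2, 2))
            a = projector.project(e, origin)
            b = project_real_space(vol, e, origin)
            assert np.linalg.norm(a - b) / np.linalg.norm(b) < 1e-3


class TestCtf:
    def test_zero_frequency_equals_minus_amplitude_contrast(self):
        c = CtfParams(defocus_u=15000, defocus_v=15000, amplitude_contrast=0.07)
        assert np.isclose(ctf_evaluate(c, 0.0), -0.07)

    def test_astigmatism_axes(self):
        c = CtfParams(defocus_u=20000, defocus_v=10000, astig_angle=30.0)
        lam = electron_wavelength(c.voltage)
        s = 0.01
        chi_u = np.pi * lam * 20000 * s ** 2 - 0.5 * np.pi * c.cs * 1e7 * lam ** 3 * s ** 4
        expect = -(np.sqrt(1 - 0.1 ** 2) * np.sin(chi_u) + 0.1 * np.cos(chi_u))
        assert np.isclose(ctf_evaluate(c, s, azimuth=30.0), expect)

    def test_phase_flip_preserves_amplitudes(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(64, 64))
        c = CtfParams(defocus_u=15000, defocus_v=12000, astig_angle=10.0)
        out = apply_ctf(img, c, apix=1.35, mode="phase_flip")
        # the Nyquist row/column has no Hermitian partner on an even grid, so
        # an astigmatic sign field is undefined there; compare all other pixels
        keep = np.ones((64, 64), bool)
        keep[32, :] = keep[:, 32] = False
        fa = np.abs(np.fft.fft2(img))[keep]
        fb = np.abs(np.fft.fft2(out))[keep]
        assert np.allclose(fa, fb, rtol=1e-9, atol=1e-9)

    def test_first_zero_against_root_finder(self):
        # independent oracle: the first zero solves chi(s) + arcsin(A) = pi
        c = CtfParams(defocus_u=15000, defocus_v=15000, voltage=300.0, cs=2.0,
                      amplitude_contrast=0.07)
        lam = electron_wavelength(300.0)

        def chi(s):
            return np.pi * lam * 15000 * s ** 2 - 0.5 * np.pi * 2.0e7 * lam ** 3 * s ** 4

        s_oracle = brentq(lambda s: chi(s) + np.arcsin(0.07) - np.pi, 1e-4, 0.08)
        s_impl = brentq(lambda s: ctf_evaluate(c, s), 1e-4, s_oracle * 1.2)
        assert abs(s_impl - s_oracle) < 1e-4


class TestSubtraction:
    def test_zero_map_leaves_image_unchanged(self):
        img = np.random.default_rng(0).normal(size=(32, 32))
        p = ParticleRecord(euler=(10, 20, 30), pixel_size=2.0)
        out = subtract_projection(img, DensityMap(np.zeros((32, 32, 32)), apix=2.0), p)
        assert np.allclose(out, img)

    def test_pixel_size_mismatch_rejected(self):
        p = ParticleRecord(euler=(0, 0, 0), pixel_size=1.0)
        with pytest.raises(ValueError, match="pixel size"):
            subtract_projection(np.zeros((16, 16)),
                                DensityMap(np.zeros((16, 16, 16)), apix=2.0), p)

    def test_linearity_of_subtraction(self):
        rng = np.random.default_rng(5)
        a = render_blobs(32, 2.0, rng.uniform(-15, 15, (3, 3)), 4.0, 1.0)
        b = render_blobs(32, 2.0, rng.uniform(-15, 15, (3, 3)), 4.0, 1.0)
        img = rng.normal(size=(32, 32))
        p = ParticleRecord(euler=(15, 40, -60), origin=(0.5, -1.0), pixel_size=2.0)
        both = subtract_projection(img, DensityMap(a + b, apix=2.0), p, scale=False)
        seq = subtract_projection(
            subtract_projection(img, DensityMap(a, apix=2.0), p, scale=False),
            DensityMap(b, apix=2.0), p, scale=False)
        assert np.allclose(both, seq, atol=1e-6)

    def test_bulk_subtraction_leaves_subunit_projection(self, study):
        # particle images minus the shell map = CTF-projection of the subunits
        from locrec.simulate import _site_blobs
        spec, apix, box = study["spec"], study["apix"], study["box"]
        worst = 0.0
        for i in range(6):
            m = study["manifest"][i]
            bc, bs, ba = _site_blobs(spec, m["occupied"], m["orientation"])
            clean = render_blob_projection(box, apix, bc, bs, ba,
                                           euler_to_matrix(np.array(m["euler"])),
                                           m["origin"])
            ctf = CtfParams(defocus_u=m["defocus"], defocus_v=m["defocus"])
            expect = apply_ctf(clean, ctf, apix, "full")
            rel = (np.linalg.norm(study["subtracted"][i] - expect)
                   / np.linalg.norm(expect))
            worst = max(worst, rel)
        assert worst <= 0.05

    def test_empty_site_leaves_background(self):
        # an isolated single-site configuration: windows at unoccupied sites
        # carry only residual energy after bulk subtraction
        from locrec.simulate import PhantomSpec, make_phantom, simulate_particles
        from locrec.subparticles import FilterOptions, expand_star, extract_subparticles
        from locrec.subtraction import subtract_stack
        from locrec.io import particles_from_star

        spec = PhantomSpec(symmetry="C3", shell_radius=30.0,
                           vector=SubunitVector(direction=(0, 0, 1), length=30.0),
                           occupancy=0.5)
        box, apix = 64, 2.0
        stack, star, manifest = simulate_particles(spec, 30, box, apix,
                                                   noise_sigma=0.0, seed=4)
        _, shell, _, _ = make_phantom(spec, box, apix)
        sub_imgs = subtract_stack(stack, shell,
                                  particles_from_star(star, pixel_size=apix),
                                  scale=False)
        sub = expand_star(star, point_group("C3"), spec.vector,
                          FilterOptions(seed=1), pixel_size=apix, src_box=box)
        windows, wstar, _ = extract_subparticles(sub_imgs, sub, 32)
        occ = site_truth(wstar, manifest, "occupied").astype(bool)
        energy = np.array([np.linalg.norm(w) for w in windows])
        assert energy[~occ].max() < 0.1 * np.median(energy[occ])
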