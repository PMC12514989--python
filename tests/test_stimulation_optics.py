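import numpy as np
import pytest

from conespot import stimulation_optics as so


def make_lattice(n=20, spacing=1.1, types=None, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    cc, rr = np.meshgrid(np.arange(n), np.arange(n))
    pos = np.c_[(cc.ravel() + 0.5 * (rr.ravel() % 2)) * spacing,
                rr.ravel() * spacing * np.sqrt(3) / 2]
    pos = pos - pos.mean(axis=0)
    if jitter:
        pos = pos + rng.normal(0, jitter, pos.shape)
    if types is None:
        types = rng.choice(list("LMSU"), size=n * n, p=[0.55, 0.35, 0.05, 0.05])
    return so.ConeMosaic(pos, np.asarray(types))


class TestDiffractionPsf:
    def test_volume_normalized(self):
        for wl, dd in [(543.0, 0.0), (680.0, 0.05), (543.0, 0.05)]:
            psf = so.diffraction_psf(wl, 6.5, dd)
            assert abs(psf.integral() - 1.0) < 1e-3

    def test_airy_first_zero(self):
        """With zero defocus the radial profile is the Airy pattern with its
        first zero at 1.22 lambda / D."""
        psf = so.diffraction_psf(543.0, 6.5, 0.0, pitch=0.02)
        n = psf.values.shape[0]
        half = (n - 1) // 2
        prof = psf.values[half, half:]
        mins = np.nonzero((prof[1:-1] < prof[:-2]) & (prof[1:-1] <= prof[2:]))[0]
        first_zero = psf.pitch * (mins[0] + 1)
        theory = 1.22 * 543e-9 / 6.5e-3 * so.ARCMIN_PER_RAD
        assert abs(first_zero - theory) <= psf.pitch

    def test_fwhm_scales_with_wavelength(self):
        """680-nm PSF is wider than the 543-nm one by the wavelength ratio."""

        def fwhm(wl):
            psf = so.diffraction_psf(wl, 6.5, 0.0, pitch=0.01)
            n = psf.values.shape[0]
            half = (n - 1) // 2
            prof = psf.values[half, half:]
            r = psf.pitch * np.arange(prof.size)
            return 2.0 * np.interp(0.5, prof[::-1] / prof[0], r[::-1])

        ratio = fwhm(680.0) / fwhm(543.0)
        assert ratio == pytest.approx(680.0 / 543.0, rel=0.02)

    def test_coarse_grid_rejected(self):
        with pytest.raises(ValueError):
            so.diffraction_psf(543.0, pitch=0.2)


class TestStimulusLightField:
    def test_delta_psf_reproduces_square(self):
        """Convolution with a discrete delta returns the normalized square."""
        pitch = 0.025
        delta = np.zeros((41, 41))
        delta[20, 20] = 1.0 / pitch ** 2
        psf = so.RetinalLightField(delta, pitch, (-20 * pitch, -20 * pitch))
        stim = so.StimulusSpec(side_length=1.0, center=(0.0, 0.0))
        field = so.stimulus_light_field(stim, psf)
        assert abs(field.integral() - 1.0) < 1e-3
        # peak value of a unit-integral 1x1 arcmin square is 1
        assert field.values.max() == pytest.approx(1.0, rel=1e-6)

    def test_unit_integral_and_symmetry(self):
        psf = so.diffraction_psf(680.0, 6.5, 0.05)
        field = so.stimulus_light_field(so.StimulusSpec(wavelength=680.0), psf)
        assert abs(field.integral() - 1.0) < 1e-3
        # square + radially symmetric PSF: invariant under 90 deg rotation
        assert np.allclose(field.values, np.rot90(field.values), atol=1e-10)


class TestStimulatedConeCounts:
    def test_pure_l_mosaic_gives_prop_l_one(self, kernel543):
        m = make_lattice(types=["L"] * 400)
        stim = so.StimulusSpec(wavelength=543.0)
        summ = so.stimulate(m, stim)
        assert summ.prop_L == pytest.approx(1.0)
        assert summ.prop_L_range == (pytest.approx(1.0), pytest.approx(1.0))

    def test_uniform_field_counts_unit_volume_aperture(self):
        """One cone under a wide uniform field of height h contributes h."""
        pitch = 0.05
        n = 201
        half = (n - 1) // 2
        h = 0.37
        field = so.RetinalLightField(np.full((n, n), h), pitch,
                                     (-half * pitch, -half * pitch))
        m = so.ConeMosaic(np.array([[0.0, 0.0]]), np.array(["L"]))
        with pytest.raises(so.PropLUndefinedError):
            # no M cones is fine, but an S-only mosaic is undefined
            so.stimulated_cone_counts(
                field, so.ConeMosaic(np.array([[0.0, 0.0]]), np.array(["S"])))
        summ = so.stimulated_cone_counts(field, m)
        assert summ.n_L == pytest.approx(h, rel=1e-3)

    def test_kernel_matches_direct_computation(self, mosaic, kernel680):
        stim = so.StimulusSpec(wavelength=680.0)
        rng = np.random.default_rng(7)
        for _ in range(5):
            center = rng.uniform(-20, 20, 2)
            psf = so.diffraction_psf(680.0, 6.5, 0.05)
            shifted = so.StimulusSpec(wavelength=680.0, center=tuple(center))
            field = so.stimulus_light_field(shifted, psf)
            direct = so.stimulated_cone_counts(field, mosaic, scale=stim.area)
            fast = kernel680.summary(mosaic, center)
            assert fast.prop_L == pytest.approx(direct.prop_L, abs=2e-3)
            assert fast.total_cones == pytest.approx(direct.total_cones, rel=5e-3)

    def test_total_cones_tracks_density(self, mosaic):
        """~1 cone/arcmin^2 density x 2.25-arcmin square -> 3-6 cones."""
        summ = so.stimulate(mosaic, so.StimulusSpec(wavelength=543.0))
        assert 3.0 <= summ.total_cones <= 6.0

    def test_prop_l_monotone_under_relabeling(self, kernel543):
        """Relabeling an M cone as L never decreases prop_L, field fixed."""
        m = make_lattice(seed=3)
        base = kernel543.summary(m, (0.0, 0.0)).prop_L
        m_idx = np.nonzero(m.types == "M")[0]
        for i in m_idx[:10]:
            types = m.types.copy()
            types[i] = "L"
            relabeled = so.ConeMosaic(m.positions, types)
            assert kernel543.summary(relabeled, (0.0, 0.0)).prop_L >= base - 1e-12


class TestSConeDistance:
    def test_s_cone_at_center_and_at_one_spacing(self):
        m = so.ConeMosaic(np.array([[0.0, 0.0], [1.1, 0.0], [5.0, 5.0]]),
                          np.array(["S", "L", "M"]))
        assert so.s_cone_distance(m, (0.0, 0.0), 1.1) == 0.0
        assert so.s_cone_distance(m, (1.1, 0.0), 1.1) == pytest.approx(1.0)

    def test_matches_exhaustive_scan(self, mosaic):
        from scipy.spatial import cKDTree

        s_pos = mosaic.positions[mosaic.types == "S"]
        tree = cKDTree(s_pos)
        rng = np.random.default_rng(11)
        queries = rng.uniform(-30, 30, size=(1000, 2))
        spacing = 1.1
        expected = tree.query(queries)[0] / spacing
        got = np.array([so.s_cone_distance(mosaic, q, spacing) for q in queries])
        assert np.allclose(got, expected)

    def test_no_s_cones_signaled(self):
        m = so.ConeMosaic(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
                          np.array(["L", "M", "L"]))
        with pytest.raises(ValueError, match="S cone"):
            so.s_cone_distance(m, (0.0, 0.0), 1.0)


class TestConeSpacing:
    def test_hexagonal_patch(self):
        """Center plus its 6 lattice neighbors: all 12 Delaunay edges have
        length equal to the spacing."""
        s = 0.8
        ang = np.pi / 3 * np.arange(6)
        pos = np.r_[[[0.0, 0.0]], np.c_[s * np.cos(ang), s * np.sin(ang)]]
        m = so.ConeMosaic(pos, np.array(["L"] * 7))
        assert so.cone_spacing(m) == pytest.approx(s, rel=1e-9)

    def test_unit_square(self):
        """4 cones on a unit square: 4 sides + 1 diagonal -> (4 + sqrt 2)/5."""
        m = so.ConeMosaic(
            np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
            np.array(["L", "L", "M", "M"]))
        assert so.cone_spacing(m) == pytest.approx((4 + np.sqrt(2)) / 5)

    def test_euclidean_invariance(self):
        m = make_lattice(n=10, jitter=0.1, seed=5)
        base = so.cone_spacing(m)
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = so.ConeMosaic(m.positions @ rot.T + [3.0, -7.0], m.types)
        assert so.cone_spacing(moved) == pytest.approx(base, rel=1e-9)

    def test_collinear_mosaic_rejected(self):
        m = so.ConeMosaic(np.c_[np.arange(5.0), np.zeros(5)],
                          np.array(["L"] * 5))
        with pytest.raises(ValueError):
            so.cone_spacing(m)


class TestMosaicContainer:
    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            so.ConeMosaic(np.array([[0.0, 0.0], [0.0, 0.0]]),
                          np.array(["L", "M"]))

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            so.ConeMosaic(np.array([[0.0, 0.0]]), np.array(["X"]))

    def test_csv_round_trip(self, tmp_path):
        m = make_lattice(n=5, seed=9)
        path = tmp_path / "m.csv"
        m.to_csv(path)
        back = so.ConeMosaic.from_csv(path)
        assert np.allclose(back.positions, m.positions)
        assert (back.types == m.types).all()


def test_pixel_subtense_worked_example():
    """0.9 deg field over 512 samples subtends ~0.11 arcmin per pixel."""
    assert round(so.pixel_subtense_arcmin(0.9, 512), 2) == 0.11
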