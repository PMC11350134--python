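"""Phantom geometry, atrophy morphing, uptake model and PSF operators."""
import numpy as np
import pytest

import centistress.phantom as ph
from centistress.errors import (CannotSharpenError, DegenerateSubjectError,
                                GeometryError, ModelParameterError)
from centistress.phantom import (DEFAULT_TRACERS, PhantomSpec, SubjectParams,
                                 Tissue, TracerProfile, VolumeImage,
                                 apply_psf, build_template, harmonize_image,
                                 morph_subject, simulate_uptake, subject_seed)


def subj(**kw):
    base = dict(subject_id="s", true_cl=50.0, age=70.0, atrophy=1.0,
                tracer="FMM", diagnosis="MCI", native_fwhm=6.0)
    base.update(kw)
    return SubjectParams(**base)


class TestTemplate:
    def test_all_compartments_present_and_disjoint(self, template48):
        labels = set(np.unique(template48.grid))
        assert labels == set(range(7))
        # reference regions non-empty
        for t in (Tissue.CEREBELLAR_GM, Tissue.CEREBELLAR_WM,
                  Tissue.BRAINSTEM_PONS):
            assert template48.count(t) > 0

    def test_deterministic(self):
        spec = PhantomSpec(grid_shape=(48, 48, 48))
        a, b = build_template(spec), build_template(spec)
        assert np.array_equal(a.grid, b.grid)

    def test_empty_pons_is_geometry_error(self):
        geo = dict(ph.DEFAULT_GEOMETRY)
        geo["pons"] = {"center": (0.0, 0.16, -0.56), "radii": (0.0, 0.0, 0.0)}
        with pytest.raises(GeometryError):
            build_template(PhantomSpec(grid_shape=(48, 48, 48),
                                       region_geometry=geo))

    def test_overlapping_pons_is_geometry_error(self):
        geo = dict(ph.DEFAULT_GEOMETRY)
        geo["pons"] = {"center": geo["cerebellum"]["center"],
                       "radii": (0.1, 0.1, 0.1)}
        with pytest.raises(GeometryError):
            build_template(PhantomSpec(grid_shape=(48, 48, 48),
                                       region_geometry=geo))

    def test_small_grid_rejected(self):
        with pytest.raises(GeometryError):
            PhantomSpec(grid_shape=(16, 48, 48))


class TestMorph:
    def test_no_atrophy_is_identity(self, template48):
        out, affine = morph_subject(template48, subj(atrophy=1.0), seed=1)
        assert np.array_equal(out.grid, template48.grid)
        # jitter is small but generally nonzero
        assert np.allclose(affine, np.eye(4), atol=5.0)

    @pytest.mark.parametrize("atrophy", [0.95, 0.8, 0.7])
    def test_realized_gm_fraction(self, template48, atrophy):
        out, _ = morph_subject(template48, subj(atrophy=atrophy), seed=1)
        gm0 = template48.mask(*ph.GM_LABELS).sum()
        gm1 = out.mask(*ph.GM_LABELS).sum()
        assert abs(gm1 / gm0 - atrophy) < 0.02

    def test_erosion_monotone_and_deterministic(self, template48):
        counts = []
        for atrophy in (1.0, 0.9, 0.8, 0.7):
            out, _ = morph_subject(template48, subj(atrophy=atrophy), seed=1)
            counts.append(out.mask(*ph.GM_LABELS).sum())
        assert all(b < a or (a == b == counts[0]) for a, b in
                   zip(counts, counts[1:]))
        again, _ = morph_subject(template48, subj(atrophy=0.8), seed=1)
        ref, _ = morph_subject(template48, subj(atrophy=0.8), seed=99)
        assert np.array_equal(again.grid, ref.grid)  # labels ignore jitter rng

    def test_eroded_voxels_become_background(self, template48):
        out, _ = morph_subject(template48, subj(atrophy=0.8), seed=1)
        changed = out.grid != template48.grid
        assert (out.grid[changed] == int(Tissue.BACKGROUND)).all()

    def test_extreme_atrophy_is_degenerate(self, template48):
        with pytest.raises(DegenerateSubjectError):
            morph_subject(template48, subj(atrophy=0.01), seed=1)


class TestUptake:
    @pytest.mark.parametrize("cl,expected", [(0.0, None), (100.0, None),
                                             (50.0, 1.5), (-20.0, 0.8)])
    def test_ideal_suvr_matches_anchor_line(self, template48, cl, expected):
        tracer = TracerProfile("FMM", 1.0, 2.0, 1.8, 0.0, noise_sd=0.0)
        img = simulate_uptake(template48, subj(true_cl=cl), tracer,
                              noise_sd=0.0)
        wcb = template48.mask(Tissue.CEREBELLAR_GM, Tissue.CEREBELLAR_WM)
        target = template48.mask(Tissue.CORTICAL_TARGET_GM)
        suvr = img.grid[target].mean() / img.grid[wcb].mean()
        assert suvr == pytest.approx(expected if expected is not None
                                     else tracer.suvr_at(cl), abs=1e-12)

    def test_wm_age_slope_raises_pons_over_wcb(self, template48):
        tracer = DEFAULT_TRACERS["FBB"]
        ratios = []
        for age in (60.0, 70.0, 80.0):
            img = simulate_uptake(template48, subj(age=age, tracer="FBB"),
                                  tracer, noise_sd=0.0)
            pons = img.grid[template48.mask(Tissue.BRAINSTEM_PONS)].mean()
            wcb = img.grid[template48.mask(Tissue.CEREBELLAR_GM,
                                           Tissue.CEREBELLAR_WM)].mean()
            ratios.append(pons / wcb)
        assert ratios[0] < ratios[1] < ratios[2]

    def test_profile_validation(self):
        with pytest.raises(ModelParameterError):
            TracerProfile("bad", 2.0, 1.0, 1.8, 0.0)

    def test_mismatched_tracer_rejected(self, template48):
        with pytest.raises(ModelParameterError):
            simulate_uptake(template48, subj(tracer="FBB"),
                            DEFAULT_TRACERS["FMM"], noise_sd=0.0)

    def test_negative_target_intensity_rejected(self, template48):
        with pytest.raises(ModelParameterError):
            simulate_uptake(template48, subj(true_cl=-200.0),
                            TracerProfile("FMM", 1.0, 2.0, 1.8, 0.0),
                            noise_sd=0.0)

    def test_noise_keeps_intensities_nonnegative(self, template48):
        tracer = TracerProfile("FMM", 1.25, 2.0, 2.0, 0.0, noise_sd=2.0)
        img = simulate_uptake(template48, subj(), tracer, seed=3)
        assert (img.grid >= 0).all()


class TestPSF:
    def test_zero_fwhm_is_identity(self, template48):
        img = simulate_uptake(template48, subj(), DEFAULT_TRACERS["FMM"],
                              noise_sd=0.0)
        out = apply_psf(img, 0.0)
        assert np.array_equal(out.grid, img.grid)

    def test_mass_conserved_for_arbitrary_image(self):
        rng = np.random.default_rng(0)
        img = VolumeImage(rng.random((40, 40, 40)), 2.0, np.eye(4))
        out = apply_psf(img, 7.0)
        assert out.grid.sum() == pytest.approx(img.grid.sum(), rel=1e-6)

    def test_point_source_matches_discrete_gaussian(self):
        data = np.zeros((41, 41, 41))
        data[20, 20, 20] = 1.0
        img = VolumeImage(data, 2.0, np.eye(4))
        out = apply_psf(img, 6.0)
        sigma_vox = 6.0 / 2.354820045 / 2.0
        for k in (1, 2, 3):
            expected = np.exp(-k ** 2 / (2 * sigma_vox ** 2))
            assert out.grid[20 + k, 20, 20] / out.grid[20, 20, 20] == \
                pytest.approx(expected, rel=1e-6)

    def test_effective_fwhm_accumulates_in_quadrature(self):
        img = VolumeImage(np.ones((40, 40, 40)), 2.0, np.eye(4))
        out = apply_psf(apply_psf(img, 3.0), 4.0)
        assert out.effective_fwhm == pytest.approx(5.0)

    def test_negative_fwhm_rejected(self):
        img = VolumeImage(np.ones((40, 40, 40)), 2.0, np.eye(4))
        with pytest.raises(ValueError):
            apply_psf(img, -1.0)

    def test_smoothing_pulls_compartment_means_toward_neighbours(
            self, template48):
        """Bright exposed compartments lose signal monotonically; the
        embedded cerebellar GM gains from surrounding white matter."""
        img = simulate_uptake(template48, subj(true_cl=100.0, age=75.0,
                                               tracer="FBB"),
                              DEFAULT_TRACERS["FBB"], noise_sd=0.0)
        target = template48.mask(Tissue.CORTICAL_TARGET_GM)
        pons = template48.mask(Tissue.BRAINSTEM_PONS)
        cgm = template48.mask(Tissue.CEREBELLAR_GM)
        t_means, p_means, c_means = [], [], []
        for fwhm in (0.0, 3.0, 5.0, 8.0):
            out = apply_psf(img, fwhm)
            t_means.append(out.grid[target].mean())
            p_means.append(out.grid[pons].mean())
            c_means.append(out.grid[cgm].mean())
        assert all(b < a for a, b in zip(t_means, t_means[1:]))
        assert all(b < a for a, b in zip(p_means, p_means[1:]))
        assert all(b > a for a, b in zip(c_means, c_means[1:]))


class TestHarmonize:
    def test_already_at_target_is_identity(self):
        img = VolumeImage(np.ones((40, 40, 40)), 2.0, np.eye(4),
                          effective_fwhm=8.0)
        out = harmonize_image(img, 8.0)
        assert np.array_equal(out.grid, img.grid)
        assert out.effective_fwhm == 8.0

    def test_quadrature_kernel(self, template48):
        img = simulate_uptake(template48, subj(), DEFAULT_TRACERS["FMM"],
                              noise_sd=0.0)
        five = apply_psf(img, 5.0)
        via_five = harmonize_image(five, 8.0)
        # the applied kernel is the quadrature complement sqrt(8^2 - 5^2)
        explicit = apply_psf(five, np.sqrt(64.0 - 25.0))
        assert np.allclose(via_five.grid, explicit.grid, atol=1e-12)
        assert via_five.effective_fwhm == 8.0
        # two-step smoothing approximates a single 8 mm kernel (semigroup)
        direct = apply_psf(img, 8.0)
        assert np.allclose(via_five.grid, direct.grid,
                           atol=2e-3 * direct.grid.max())

    def test_cannot_sharpen(self):
        img = VolumeImage(np.ones((40, 40, 40)), 2.0, np.eye(4),
                          effective_fwhm=9.0)
        with pytest.raises(CannotSharpenError):
            harmonize_image(img, 8.0)


def test_subject_seed_is_stable_and_bounded():
    assert subject_seed(42, "S0001") == subject_seed(42, "S0001")
    assert subject_seed(42, "S0001") != subject_seed(43, "S0001")
    assert 0 <= subject_seed(2 ** 30, "S9999") < 2 ** 31
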