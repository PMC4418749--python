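import numpy as np
import pytest

from octcornea import (
    BScanImage,
    CorneaTruth,
    GeometryError,
    OpticalGeometry,
    SegmentationError,
    SegmentationParams,
    ValidationError,
    apply_manual_override,
    build_profiles,
    detect_interfaces,
    generate_bscan,
    interfaces_to_thickness,
    locate_apex,
    preprocess,
    segment_bscan,
)
from octcornea.segmentation import AxialProfile, InterfaceSet, _parabolic_refine

from conftest import brute_force_ridge_positions, scaled_geometry


class TestPreprocess:
    def test_default_geometry_excludes_exactly_128_columns(self):
        truth = CorneaTruth()
        image, _ = generate_bscan(truth, noise_level=0.3, seed=1)
        pre = preprocess(image)
        assert len(pre.excluded_columns) == 128

    def test_exclusion_centered_on_injected_reflex(self, small_geometry):
        truth = CorneaTruth(anterior_radius_mm=float("inf"))
        image, bt = generate_bscan(
            truth, small_geometry, noise_level=0.5,
            artifact_flags={"specular_reflex"}, seed=2,
        )
        pre = preprocess(image)
        assert pre.reflex_column == bt.reflex_column
        assert pre.excluded_columns.start == bt.reflex_column - 64
        assert pre.excluded_columns.stop == bt.reflex_column + 64

    def test_analysis_regions_flank_exclusion_with_half_mm_width(self, small_geometry):
        truth = CorneaTruth()
        image, _ = generate_bscan(truth, small_geometry, noise_level=0.5, seed=3)
        pre = preprocess(image)
        left, right = pre.analysis_regions
        expected = round(500.0 / small_geometry.lateral_pitch_um)
        assert len(left) == len(right) == expected
        assert left.stop == pre.excluded_columns.start
        assert right.start == pre.excluded_columns.stop
        excl = set(pre.excluded_columns)
        assert excl.isdisjoint(left) and excl.isdisjoint(right)

    def test_excluded_columns_are_zeroed(self, small_geometry):
        truth = CorneaTruth()
        image, _ = generate_bscan(truth, small_geometry, noise_level=0.5, seed=3)
        pre = preprocess(image)
        assert np.all(pre.pixels[:, pre.excluded_columns.start:pre.excluded_columns.stop] == 0)

    def test_too_narrow_image_rejected(self):
        geom = scaled_geometry(width_px=300)
        truth = CorneaTruth(anterior_radius_mm=float("inf"))
        image, _ = generate_bscan(truth, geom, noise_level=0, artifact_flags=set(), seed=1)
        with pytest.raises(GeometryError):
            preprocess(image)

    def test_preprocessing_preserves_ridge_maxima(self, clean_flat_scan):
        """On an artifact-free noiseless image the filters must not move
        any ridge maximum by more than half a pixel."""
        image, truth = clean_flat_scan
        pre = preprocess(image)
        col = pre.analysis_regions[0].start + 5
        before = brute_force_ridge_positions(image.pixels, col)
        after = brute_force_ridge_positions(pre.pixels, col)
        assert len(before) == len(after)
        for b, a in zip(before, after):
            assert a == pytest.approx(b, abs=0.5)

    def test_horizontal_bands_removed(self, small_geometry):
        truth = CorneaTruth(anterior_radius_mm=float("inf"))
        image, _ = generate_bscan(
            truth, small_geometry, noise_level=0.0,
            artifact_flags={"horizontal_bands"}, seed=4,
        )
        pre = preprocess(image)
        # after baseline subtraction, off-ridge rows are (near) zero
        region = pre.analysis_regions[0]
        sub = pre.pixels[:, region.start:region.stop]
        deep = sub[-60:, :]  # well below the endothelium
        assert deep.max() < 0.02


class TestLocateApex:
    def test_flat_cornea_ties_resolve_to_mid_image(self, clean_flat_scan):
        image, _ = clean_flat_scan
        assert locate_apex(image) == image.geometry.width_px // 2

    def test_curved_apex_found_at_center(self, clean_curved_scan):
        image, _ = clean_curved_scan
        center = (image.geometry.width_px - 1) / 2
        assert locate_apex(image) == pytest.approx(center, abs=2)

    def test_lateral_shift_moves_apex(self, small_geometry):
        shifted = CorneaTruth(apex_offset_px=-120.0)
        image, _ = generate_bscan(
            shifted, small_geometry, noise_level=0, artifact_flags=set(), seed=1
        )
        baseline = CorneaTruth()
        image0, _ = generate_bscan(
            baseline, small_geometry, noise_level=0, artifact_flags=set(), seed=1
        )
        assert locate_apex(image) - locate_apex(image0) == pytest.approx(-120, abs=2)

    def test_empty_image_raises(self, small_geometry):
        blank = BScanImage(
            pixels=np.zeros((small_geometry.depth_px, small_geometry.width_px)),
            geometry=small_geometry,
        )
        with pytest.raises(Exception):
            locate_apex(blank)


class TestBuildProfiles:
    def test_two_profiles_one_per_region(self, clean_flat_scan):
        pre = preprocess(clean_flat_scan[0])
        profiles = build_profiles(pre)
        assert len(profiles) == 2
        assert profiles[0].provenance != profiles[1].provenance

    def test_flat_profile_equals_single_ascan(self, clean_flat_scan):
        """All columns of a flat noiseless cornea are identical, so the
        averaged profile must equal any single preprocessed A-scan."""
        pre = preprocess(clean_flat_scan[0])
        profile = build_profiles(pre)[0]
        col = pre.pixels[:, pre.analysis_regions[0].start + 3]
        assert np.allclose(profile.reflectivity, col, atol=1e-9)

    def test_flattening_keeps_peak_width_near_psf(self, clean_curved_scan):
        """With depth alignment, averaging over the curved region must
        not broaden the surface peak by more than 10% of the PSF width."""
        image, _ = clean_curved_scan
        pre = preprocess(image)
        profile = build_profiles(pre)[0]
        y = profile.reflectivity
        p = int(np.argmax(y))

        def fwhm(yv, peak):
            half = yv[peak] / 2.0
            lo = peak
            while yv[lo] > half:
                lo -= 1
            hi = peak
            while yv[hi] > half:
                hi += 1
            # linear interpolation at the crossings
            left = lo + (half - yv[lo]) / (yv[lo + 1] - yv[lo])
            right = hi - (half - yv[hi]) / (yv[hi - 1] - yv[hi])
            return right - left

        psf_fwhm_px = image.geometry.axial_psf_fwhm_um / image.geometry.axial_pitch_um
        assert fwhm(y, p) == pytest.approx(psf_fwhm_px, rel=0.10)


class TestDetectInterfaces:
    def _profile(self, geometry, centers_px, amps):
        z = np.arange(geometry.depth_px, dtype=float)
        sigma = geometry.axial_psf_sigma_px
        y = np.zeros_like(z)
        for c, a in zip(centers_px, amps):
            y += a * np.exp(-0.5 * ((z - c) / sigma) ** 2)
        return AxialProfile(depth_px=z, reflectivity=y, geometry=geometry)

    def test_five_gaussian_peaks_recovered_subpixel(self, small_geometry):
        g = small_geometry
        to_px = g.geometric_um_to_optical_px
        surf = 110.3
        centers = [surf, surf + to_px(53.1), surf + to_px(70.1),
                   surf + to_px(95.8), surf + to_px(439.5)]
        prof = self._profile(g, centers, [1.0, 0.5, 0.4, 0.35, 0.7])
        iset = detect_interfaces(prof, post_op=True)
        oracle = brute_force_ridge_positions(prof.reflectivity[:, None], 0)
        for found, expect in zip(iset.depths().values(), oracle):
            assert found == pytest.approx(expect, abs=1e-9)
        for found, c in zip(iset.depths().values(), centers):
            assert found == pytest.approx(c, abs=0.2)

    def test_preop_four_peaks_no_flap(self, small_geometry):
        g = small_geometry
        to_px = g.geometric_um_to_optical_px
        surf = 110.0
        centers = [surf, surf + to_px(53.1), surf + to_px(70.1), surf + to_px(525.8)]
        prof = self._profile(g, centers, [1.0, 0.5, 0.4, 0.7])
        iset = detect_interfaces(prof, post_op=False)
        assert iset.flap_px is None
        assert len(iset.depths()) == 4

    def test_monotone_profile_fails_with_flags(self, small_geometry):
        z = np.arange(small_geometry.depth_px, dtype=float)
        prof = AxialProfile(
            depth_px=z, reflectivity=np.exp(-z / 200.0), geometry=small_geometry
        )
        with pytest.raises(SegmentationError) as err:
            detect_interfaces(prof, post_op=False)
        assert err.value.qc_flags

    def test_missing_flap_peak_flagged(self, small_geometry):
        g = small_geometry
        to_px = g.geometric_um_to_optical_px
        surf = 110.0
        centers = [surf, surf + to_px(53.1), surf + to_px(70.1), surf + to_px(439.5)]
        prof = self._profile(g, centers, [1.0, 0.5, 0.4, 0.7])
        with pytest.raises(SegmentationError) as err:
            detect_interfaces(prof, post_op=True)
        assert "missing:flap" in err.value.qc_flags


class TestManualOverride:
    iset = InterfaceSet(
        air_epi_px=100.0, epi_bowman_px=150.0, bowman_stroma_px=166.0,
        endo_aqueous_px=590.0, provenance={"air_epi": "auto"},
    )

    def test_empty_override_is_identity(self):
        assert apply_manual_override(self.iset, {}) is self.iset

    def test_full_override_replaces_everything(self):
        depths = {"air_epi": 90.0, "epi_bowman": 140.0, "bowman_stroma": 155.0,
                  "flap": 190.0, "endo_aqueous": 580.0}
        out = apply_manual_override(self.iset, depths)
        assert out.depths() == depths
        assert all(v == "manual" for k, v in out.provenance.items() if k in depths)

    def test_flap_only_insert_preserves_others(self):
        out = apply_manual_override(self.iset, {"flap": 200.0})
        assert out.flap_px == 200.0
        assert out.air_epi_px == self.iset.air_epi_px
        assert out.provenance["air_epi"] == "auto"
        assert out.provenance["flap"] == "manual"

    def test_non_monotonic_override_rejected(self):
        with pytest.raises(ValidationError):
            apply_manual_override(self.iset, {"epi_bowman": 50.0})  # above surface
        with pytest.raises(ValidationError):
            apply_manual_override(
                self.iset, {"air_epi": 120.0, "epi_bowman": 110.0}
            )


class TestEndToEnd:
    def test_noiseless_oracle_equivalence(self, clean_flat_scan):
        """Full segmentation of a flat noiseless cornea matches the
        brute-force argmax + parabola oracle to within 0.2 px."""
        image, _ = clean_flat_scan
        iset = segment_bscan(image, post_op=False)
        oracle = brute_force_ridge_positions(image.pixels, 50)
        for found, expect in zip(iset.depths().values(), oracle):
            assert found == pytest.approx(expect, abs=0.2)

    def test_interface_sets_always_monotone(self, small_geometry):
        for seed in range(4):
            post = seed % 2 == 1
            truth = CorneaTruth(
                stroma_to_flap_um=25.7 if post else None,
                total_um=439.5 if post else 525.8,
            )
            image, _ = generate_bscan(truth, small_geometry, noise_level=1.0, seed=seed)
            vals = list(segment_bscan(image, post_op=post).depths().values())
            assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_noisy_thickness_error_below_axial_resolution(self, small_geometry):
        """Mean absolute thickness error under full speckle stays below
        the instrument's 3-um axial resolution (reduced problem size;
        the 50-scan study runs in the acceptance suite)."""
        from octcornea import evaluate_segmentation_accuracy, mean_absolute_error

        errors = evaluate_segmentation_accuracy(
            n_images=8, seed=99, geometry=small_geometry
        )
        assert mean_absolute_error(errors) <= 3.0

    def test_parabolic_refine_edges(self):
        y = np.array([1.0, 0.5, 0.2])
        assert _parabolic_refine(y, 0) == 0.0
        assert _parabolic_refine(y, 2) == 2.0
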