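"""ROI statistics, the CNR/noise formulas, and the per-module metrics."""

import math

import numpy as np
import pytest

from acrqa.dicom_io import PhantomImageSeries
from acrqa.localization import localize
from acrqa.metrics import (
    MetricSettings,
    RoiStats,
    compute_cnr,
    compute_noise,
    extract_roi_stats,
    measure_inplane_distance,
    measure_slice_thickness,
    measure_uniformity,
    run_session,
    score_high_contrast,
    score_low_contrast,
)
from acrqa.phantom_model import CircularRoi, default_geometry, roi_template
from acrqa.synthetic import (
    cbct_preset,
    crescent_mask,
    ct_preset,
    CrescentSpec,
    expected_uniformity,
    render_phantom,
)


def flat_series(value=0.0, n=128, spacing=0.5):
    origin = -(n - 1) / 2.0 * spacing
    return PhantomImageSeries(
        hu=np.full((1, n, n), float(value)),
        pixel_spacing=(spacing, spacing),
        slice_thickness=2.5,
        z_positions=[0.0],
        origin=(origin, origin),
    )


class TestRoiStats:
    def test_constant_disc(self):
        series = flat_series(100.0)
        stats = extract_roi_stats(series, 0, CircularRoi("x", (0, 0), 8.0))
        assert stats.mean == 100.0
        assert stats.sd == 0.0
        assert stats.area_mm2 == pytest.approx(math.pi * 64, rel=0.05)

    def test_gaussian_noise_sd_recovered(self):
        rng = np.random.default_rng(42)
        series = flat_series(0.0)
        series.hu[0] += rng.normal(0, 10.0, series.hu.shape[1:])
        roi = CircularRoi("x", (0, 0), math.sqrt(400 / math.pi))
        stats = extract_roi_stats(series, 0, roi)
        assert stats.n_pixels >= 700
        assert stats.sd == pytest.approx(10.0, abs=1.0)

    def test_mask_halves_pixel_count_and_flags(self):
        series = flat_series(50.0)
        roi = CircularRoi("x", (0, 0), 8.0)
        full = extract_roi_stats(series, 0, roi)
        mask = np.zeros(series.hu.shape[1:], dtype=bool)
        mask[:, series.hu.shape[2] // 2 :] = True  # right half-plane
        half = extract_roi_stats(series, 0, roi, artifact_mask=mask)
        assert half.n_pixels == pytest.approx(full.n_pixels / 2, rel=0.05)
        assert "artifact_overlap" in half.flags

    def test_roi_outside_image_raises(self):
        series = flat_series()
        with pytest.raises(ValueError, match="outside the image"):
            extract_roi_stats(series, 0, CircularRoi("x", (500, 500), 5.0))


class TestFormulas:
    """The CNR and noise definitions, pinned by hand-computed values."""

    def make(self, mean, sd):
        return RoiStats("x", mean, sd, 100, 25.0, (0, 0))

    def test_cnr_hand_computed(self):
        assert compute_cnr(self.make(120, 5), self.make(0, 60)) == pytest.approx(2.0)

    def test_cnr_zero_contrast(self):
        assert compute_cnr(self.make(7, 1), self.make(7, 3)) == 0.0

    def test_cnr_undefined_for_zero_background_sd(self):
        with pytest.raises(ValueError, match="background SD is zero"):
            compute_cnr(self.make(120, 5), self.make(0, 0))

    def test_noise_hand_computed(self):
        assert compute_noise(self.make(0, 0)) == 0.0
        assert compute_noise(self.make(0, 10)) == pytest.approx(1.0)
        assert compute_noise(self.make(120, 5)) == pytest.approx(0.446, abs=0.001)

    def test_noise_undefined_below_minus_1000(self):
        with pytest.raises(ValueError, match="not positive"):
            compute_noise(self.make(-1000.0, 5))

    def test_cnr_offset_invariant_noise_is_not(self):
        """A global HU shift cancels in CNR but shifts the noise
        denominator — this pins the +1000 HU rescale of the noise
        formula."""
        plug, bg = self.make(120, 5), self.make(0, 60)
        shifted_plug, shifted_bg = self.make(170, 5), self.make(50, 60)
        assert compute_cnr(plug, bg) == compute_cnr(shifted_plug, shifted_bg)
        assert compute_noise(plug) != compute_noise(shifted_plug)
        assert compute_noise(shifted_plug) == pytest.approx(
            100 * 5 / (170 + 1000)
        )

    def test_cnr_halves_when_background_sd_doubles(self):
        assert compute_cnr(self.make(120, 5), self.make(0, 120)) == pytest.approx(
            compute_cnr(self.make(120, 5), self.make(0, 60)) / 2
        )


class TestHuAccuracy:
    def test_noiseless_plug_means_exact(self, noiseless_session, noiseless_render):
        _, _, truth = noiseless_render
        for plug, expected in truth["expected_plug_means"].items():
            assert noiseless_session.results[f"hu_{plug}"] == pytest.approx(
                expected, abs=0.05
            )

    def test_out_of_range_plug_flagged(self, ct_session):
        # water accepted range is ±7 HU; measured value sits inside
        assert ct_session.hu_details["water"]["in_range"]
        # shifting the accepted range turns the check into a failure
        g = default_geometry()
        g.plug("water").accepted_range = (-0.001, 0.001)
        lo, hi = g.plug("water").accepted_range
        mean = ct_session.results["hu_water"]
        assert not (lo <= mean <= hi)


class TestUniformity:
    def test_constant_field_gives_zero(self):
        series = flat_series(0.0, n=256, spacing=1.0)
        template = roi_template(3)
        result = measure_uniformity(series, 0, template, default_geometry())
        assert result.value == 0.0
        assert result.center_within_limit and result.edge_within_limit

    def test_tracks_cupping_amplitude(self):
        cfg = ct_preset(seed=31, noise_sigma=0.0, cupping_hu=20.0,
                        z_range=(60.0, 100.0))
        series, _ = render_phantom(cfg)
        template = roi_template(3)
        result = measure_uniformity(series, series.slice_index_at(80.0),
                                    template, cfg.geometry)
        expected = expected_uniformity(cfg)
        assert expected == pytest.approx(20.0, rel=0.02)
        assert result.value == pytest.approx(expected, rel=0.15)

    def test_crescent_artifact_triggers_reseat(self):
        cfg = cbct_preset(
            seed=32, crescent=CrescentSpec(amplitude_hu=200.0, angle_deg=90.0),
            z_range=(60.0, 100.0), cupping_hu=0.0,
        )
        series, _ = render_phantom(cfg)
        mask = crescent_mask(cfg)
        template = roi_template(3)
        idx = series.slice_index_at(80.0)
        with_mask = measure_uniformity(
            series, idx, template, cfg.geometry, artifact_mask=mask,
            reseat_about=(0.0, 0.0),
        )
        without = measure_uniformity(series, idx, template, cfg.geometry)
        assert "reseated" in with_mask.flags
        # avoiding the 200 HU arc must bring uniformity down substantially
        assert with_mask.value < without.value / 2


class TestDistance:
    def test_noiseless_distance_subpixel(self, noiseless_render):
        cfg, series, truth = noiseless_render
        loc = localize(series)
        d = measure_inplane_distance(loc)
        assert d == pytest.approx(truth["distance_mm"], abs=0.5 * cfg.pixel_spacing)

    def test_short_separation_recovered_and_out_of_tolerance(self):
        g = default_geometry()
        g.distance_bb_positions = ((-49.0, 0.0), (49.0, 0.0))
        cfg = ct_preset(seed=33, geometry=g, noise_sigma=0.0)
        series, _ = render_phantom(cfg)
        d = measure_inplane_distance(localize(series, g))
        assert d == pytest.approx(98.0, abs=0.5 * cfg.pixel_spacing)
        assert abs(d - 100.0) > 1.0  # outside the ±1.0 mm band

    def test_missing_bb_not_evaluable(self):
        g = default_geometry()
        g.distance_bb_positions = ((-50.0, 0.0),)
        cfg = ct_preset(seed=34, geometry=g, noise_sigma=0.0)
        series, _ = render_phantom(cfg)
        with pytest.raises(ValueError, match="distance"):
            measure_inplane_distance(localize(series, g))


class TestSliceThickness:
    @pytest.mark.parametrize("thickness,expected_wires", [(2.5, 5), (3.0, 6)])
    def test_wire_count_recovers_thickness(self, thickness, expected_wires):
        cfg = ct_preset(seed=35, noise_sigma=0.0, slice_thickness=thickness,
                        z_range=(-20.0, 20.0))
        series, _ = render_phantom(cfg)
        idx = series.slice_index_at(0.0)
        value, counts = measure_slice_thickness(
            series, idx, cfg.geometry, (0.0, 0.0)
        )
        assert counts == [expected_wires, expected_wires]
        assert value == pytest.approx(thickness)

    def test_no_wires_not_evaluable(self):
        series = flat_series(0.0, n=256, spacing=1.0)
        with pytest.raises(ValueError, match="no wires"):
            measure_slice_thickness(series, 0, default_geometry(), (0.0, 0.0))


class TestLowContrast:
    def test_rods_visible_at_ct_noise(self):
        cfg = ct_preset(seed=36, noise_sigma=3.0, z_range=(20.0, 60.0))
        series, _ = render_phantom(cfg)
        template = roi_template(2)
        result = score_low_contrast(series, series.slice_index_at(40.0), template)
        assert result.rods_visible == 4
        # constructed so rod contrast / background SD ~ 2 > k = 1
        assert min(result.rod_contrasts.values()) > result.background_sd

    def test_rods_drown_in_cbct_noise(self):
        cfg = cbct_preset(seed=37, z_range=(20.0, 60.0))  # SD >= 3 x contrast
        series, _ = render_phantom(cfg)
        template = roi_template(2)
        result = score_low_contrast(series, series.slice_index_at(40.0), template)
        assert result.rods_visible == 0

    def test_zero_contrast_rods_invisible(self):
        cfg = ct_preset(seed=38, rod_contrast_hu=0.0, z_range=(20.0, 60.0))
        series, _ = render_phantom(cfg)
        template = roi_template(2)
        result = score_low_contrast(series, series.slice_index_at(40.0), template)
        assert result.rods_visible == 0


class TestHighContrast:
    def test_monotone_in_psf_width(self):
        scores = []
        for psf in (0.4, 0.6, 0.8):
            cfg = ct_preset(seed=39, noise_sigma=0.0, psf_sigma_mm=psf)
            series, _ = render_phantom(cfg)
            loc = localize(series)
            result = score_high_contrast(
                series, loc.module_slices[4], roi_template(4), cfg.geometry,
                loc.center_mean,
            )
            scores.append(result.lp_cm)
        assert all(s is not None for s in scores)
        assert scores[0] >= scores[1] >= scores[2]

    def test_heavy_blur_not_evaluable(self):
        cfg = cbct_preset(seed=40, psf_sigma_mm=2.5, cupping_hu=0.0)
        series, _ = render_phantom(cfg)
        loc = localize(series)
        result = score_high_contrast(
            series, loc.module_slices[4], roi_template(4), cfg.geometry,
            loc.center_mean,
        )
        assert result.lp_cm is None
        assert "coarsest_pattern_below_noise_floor" in result.flags

    def test_modulation_matches_analytic_square_wave(self):
        """Independent oracle: a brute-force 1D model of the blurred bar
        pattern — exact box-aperture average of the square wave at the
        pixel centers, Gaussian-blurred, weighted by the circular-ROI
        chord lengths — predicts the measured in-ROI SD of the coarse
        patterns."""
        from scipy import ndimage

        cfg = ct_preset(seed=41, noise_sigma=0.0)
        series, _ = render_phantom(cfg)
        loc = localize(series)
        result = score_high_contrast(
            series, loc.module_slices[4], roi_template(4), cfg.geometry,
            loc.center_mean,
        )
        dx = cfg.pixel_spacing
        g = cfg.geometry
        x_mm, y_mm = series.pixel_coords_mm()
        template = roi_template(4)
        centers = dict(
            zip(g.bar_patterns.frequencies_lp_cm, g.bar_patterns.pattern_centers())
        )
        for lp_cm in (4.0, 5.0, 6.0):
            cx, cy = centers[lp_cm]
            roi = next(r for r in template.rois if r.label == f"{lp_cm:g}lp")
            mask = (x_mm - cx) ** 2 + (y_mm - cy) ** 2 <= roi.radius**2
            cols = np.unique(np.nonzero(mask)[1])
            weights = mask.sum(axis=0)[cols].astype(float)
            xs = x_mm[0, cols]
            bar = 5.0 / lp_cm  # bar width (mm); period is one line pair

            def on_length(t):
                # cumulative 'on'-bar length of the square wave on [0, t)
                k, r = np.divmod(t + 1000 * 2 * bar, 2 * bar)
                return k * bar + np.minimum(r, bar)

            pad = 40
            wide_x = np.concatenate(
                [xs[0] - dx * np.arange(pad, 0, -1), xs,
                 xs[-1] + dx * np.arange(1, pad + 1)]
            )
            lo, hi = wide_x - cx - dx / 2, wide_x - cx + dx / 2
            duty = (on_length(hi) - on_length(lo)) / dx
            signal = cfg.bar_amplitude_hu * duty
            signal[np.abs(wide_x - cx) > g.bar_patterns.size_mm / 2] = 0.0
            blurred = ndimage.gaussian_filter(
                signal, cfg.psf_sigma_mm / dx, mode="nearest"
            )[pad:-pad]
            mean = np.average(blurred, weights=weights)
            oracle_sd = math.sqrt(
                np.average((blurred - mean) ** 2, weights=weights)
            )
            assert result.statistics[lp_cm] == pytest.approx(oracle_sd, rel=0.08)


class TestRunSession:
    def test_ct_preset_all_metric_groups_evaluable(self, ct_session):
        expected = {
            "hu_air", "hu_polyethylene", "hu_water", "hu_acrylic", "hu_bone",
            "cnr_polyethylene", "cnr_acrylic",
            "noise_polyethylene", "noise_acrylic",
            "uniformity_hu", "uniformity_center_hu",
            "distance_mm", "slice_thickness_mm",
            "low_contrast_cnr", "low_contrast_rods_visible",
            "high_contrast_lp_cm",
        }
        assert expected <= set(ct_session.results)
        assert ct_session.not_evaluable == {}

    def test_cbct_preset_rods_invisible_rest_evaluable(self, cbct_session):
        assert cbct_session.results["low_contrast_rods_visible"] == 0
        for metric in ("hu_water", "uniformity_hu", "distance_mm",
                       "slice_thickness_mm", "high_contrast_lp_cm"):
            assert metric in cbct_session.results

    def test_truncated_volume_yields_partial_session_with_flag(self):
        cfg = ct_preset(seed=42, z_range=(-20.0, 20.0))  # module 1 only
        series, _ = render_phantom(cfg)
        session = run_session(series)
        assert session.flags.get("incomplete_phantom_coverage")
        assert "hu_water" in session.results
        assert "high_contrast" in session.not_evaluable

    def test_noiseless_input_marks_cnr_not_evaluable(self, noiseless_session):
        # rounding of a noiseless render can leave the background SD at
        # exactly zero; either a finite CNR or an explicit reason is fine,
        # but silence is not
        has_value = "cnr_polyethylene" in noiseless_session.results
        has_reason = "cnr_polyethylene" in noiseless_session.not_evaluable
        assert has_value or has_reason

    def test_session_json_round_trip(self, ct_session, tmp_path):
        import json

        path = tmp_path / "session.json"
        ct_session.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["results"]["slice_thickness_mm"] == pytest.approx(2.5)
        assert payload["hu"]["water"]["in_range"] is True

    def test_history_rows_one_per_metric(self, ct_session):
        rows = ct_session.history_rows()
        assert len(rows) == len(ct_session.results)
        assert {r["metric"] for r in rows} == set(ct_session.results)


class TestStatisticalRecovery:
    """Seeded multi-realization accuracy of the estimators."""

    def test_plug_hu_bias_below_2hu_at_sigma10(self):
        errors = {name: [] for name in ("air", "polyethylene", "water",
                                        "acrylic", "bone")}
        for seed in range(20):
            cfg = ct_preset(seed=100 + seed, noise_sigma=10.0,
                            z_range=(-20.0, 20.0))
            series, truth = render_phantom(cfg)
            session = run_session(series)
            for name in errors:
                errors[name].append(
                    session.results[f"hu_{name}"]
                    - truth["expected_plug_means"][name]
                )
        for name, errs in errors.items():
            assert abs(np.mean(errs)) < 1.0, name
            assert np.mean(np.abs(errs)) < 1.0, name

    def test_distance_unbiased_at_sigma20(self):
        errors = []
        for seed in range(20):
            cfg = ct_preset(seed=200 + seed, noise_sigma=20.0,
                            z_range=(60.0, 100.0))
            series, truth = render_phantom(cfg)
            # the module-3 crop contains exactly the two distance BBs
            from acrqa.localization import detect_bbs

            detections = detect_bbs(series)
            dist_dets = sorted(detections, key=lambda d: d.centroid[0])
            assert len(dist_dets) == 2
            (x1, y1, _), (x2, y2, _) = (d.centroid for d in dist_dets)
            errors.append(math.hypot(x2 - x1, y2 - y1) - truth["distance_mm"])
        assert abs(np.mean(errors)) < 0.1
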