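"""Activity-intensity-profile classification."""

import numpy as np
import pytest

import actiprofile as ap
from actiprofile.synthetic import make_archetype
from conftest import log_points_on_line


def fitted(points, config=ap.COUNTS):
    return ap.fit_breakpoints(points, config)


class TestVigorousPointCount:
    def test_counts_points_strictly_above_b3(self):
        pts = log_points_on_line([100.0, 1951.0, 5725.0],
                                 [-0.004, -0.001, -0.0005, -0.0002])
        fit = fitted(pts)
        b3 = fit.breakpoints[-1]
        expected = int(np.sum(pts.x > b3))
        assert ap.vigorous_point_count(pts, fit) == expected
        assert expected > 5

    def test_no_points_above_b3(self):
        pts = log_points_on_line(
            [100.0, 1951.0, 5725.0], [-0.004, -0.001, -0.0005, -0.0002],
            x=np.arange(50.0, 4000.0, 100.0),
        )
        fit = ap.PiecewiseFit(4, np.array([100.0, 1951.0, 5725.0]),
                              np.array([-0.004, -0.001, -0.0005, -0.0002]),
                              intercept=-1.0, r2=1.0, sse=0.0, x_range=(50.0, 3950.0))
        assert ap.vigorous_point_count(pts, fit) == 0

    def test_three_segment_fit_rejected(self):
        fit = ap.PiecewiseFit(3, np.array([100.0, 2000.0]),
                              np.array([-0.004, -0.001, -0.0005]),
                              intercept=-1.0, r2=1.0, sse=0.0, x_range=(50.0, 3950.0))
        pts = log_points_on_line([100.0, 2000.0], [-0.004, -0.001, -0.0005],
                                 x=np.arange(50.0, 3000.0, 100.0))
        with pytest.raises(ValueError):
            ap.vigorous_point_count(pts, fit)


class TestRefitThreeSegment:
    def test_noiseless_three_segment_recovery(self, counts_config):
        pts = log_points_on_line(
            [100.0, 1951.0], [-0.004, -0.001, -0.0004],
            x=np.arange(50.0, 3500.0, 100.0),
        )
        refit = ap.refit_three_segment(pts, counts_config)
        assert refit.n_segments == 3
        assert refit.r2 == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(refit.slopes, [-0.004, -0.001, -0.0004], atol=1e-6)

    def test_breakpoints_respect_first_two_bounds(self, counts_config):
        series = make_archetype("non_vigorous", counts_config, seed=0)
        _, pts = ap.prepare_distribution(series, counts_config)
        refit = ap.refit_three_segment(pts, counts_config)
        (lo1, hi1), (lo2, hi2) = counts_config.breakpoint_bounds[:2]
        assert lo1 <= refit.breakpoints[0] <= hi1
        assert lo2 <= refit.breakpoints[1] <= hi2

    def test_refit_quality_close_to_four_segment(self, counts_config):
        series = make_archetype("non_vigorous", counts_config, seed=1)
        _, pts = ap.prepare_distribution(series, counts_config)
        fit4 = ap.fit_breakpoints(pts, counts_config)
        refit = ap.refit_three_segment(pts, counts_config)
        assert refit.r2 >= fit4.r2 - 0.05


class TestAucRatio:
    def test_points_on_model_give_unit_ratio(self):
        pts = log_points_on_line([100.0, 1951.0, 5725.0],
                                 [-0.004, -0.001, -0.0005, -0.0002])
        fit = fitted(pts)
        assert ap.vigorous_auc_ratio(pts, fit) == pytest.approx(1.0, abs=1e-6)

    def test_doubled_empirical_probabilities_halve_ratio(self):
        bps, slopes = [100.0, 1951.0, 5725.0], [-0.004, -0.001, -0.0005, -0.0002]
        pts = log_points_on_line(bps, slopes)
        fit = ap.PiecewiseFit(4, np.array(bps), np.array(slopes), intercept=-1.0,
                              r2=1.0, sse=0.0, x_range=(float(pts.x.min()), float(pts.x.max())))
        shifted = ap.LogPoints(
            pts.x, np.where(pts.x > 5725.0, pts.y + np.log(2.0), pts.y)
        )
        assert ap.vigorous_auc_ratio(shifted, fit) == pytest.approx(0.5, abs=1e-9)

    def test_highest_tail_point_excluded_from_both_curves(self):
        bps, slopes = [100.0, 1951.0, 5725.0], [-0.004, -0.001, -0.0005, -0.0002]
        pts = log_points_on_line(bps, slopes)
        fit = ap.PiecewiseFit(4, np.array(bps), np.array(slopes), intercept=-1.0,
                              r2=1.0, sse=0.0, x_range=(float(pts.x.min()), float(pts.x.max())))
        # a wild highest-x point must not change the ratio at all
        spiked = pts.y.copy()
        spiked[-1] += 5.0
        assert ap.vigorous_auc_ratio(ap.LogPoints(pts.x, spiked), fit) == pytest.approx(
            ap.vigorous_auc_ratio(pts, fit), abs=1e-12
        )

    def test_undefined_with_too_few_tail_points(self):
        bps, slopes = [100.0, 1951.0, 5725.0], [-0.004, -0.001, -0.0005, -0.0002]
        pts = log_points_on_line(bps, slopes, x=np.arange(50.0, 5900.0, 100.0))
        fit = ap.PiecewiseFit(4, np.array(bps), np.array(slopes), intercept=-1.0,
                              r2=1.0, sse=0.0, x_range=(float(pts.x.min()), float(pts.x.max())))
        # two points above b3 -> one survives the exclusion -> undefined
        assert ap.vigorous_auc_ratio(pts, fit) is None


class TestAngle:
    def test_equal_slopes_give_zero(self):
        fit = ap.PiecewiseFit(4, np.array([100.0, 2000.0, 5500.0]),
                              np.array([-0.01, -0.001, -0.001, -0.0002]),
                              intercept=-1.0, r2=1.0, sse=0.0, x_range=(0.0, 7000.0))
        assert ap.slope_angle_difference(fit) == 0.0

    def test_small_angle_arctan_difference(self):
        fit = ap.PiecewiseFit(4, np.array([100.0, 2000.0, 5500.0]),
                              np.array([-0.01, -0.001, -0.002, -0.0002]),
                              intercept=-1.0, r2=1.0, sse=0.0, x_range=(0.0, 7000.0))
        assert ap.slope_angle_difference(fit) == pytest.approx(1.0e-3, abs=1e-8)


class TestClassify:
    @pytest.mark.parametrize(
        "name, seed",
        [
            ("consistent", 0),
            ("moderately_active", 0),
            ("non_vigorous", 0),
            ("extremely_active", 0),
            ("outlier", 0),
        ],
    )
    def test_counts_archetypes_get_intended_label(self, counts_config, name, seed):
        rec = ap.analyze_participant(make_archetype(name, counts_config, seed=seed),
                                     counts_config)
        assert rec.profile.label == name

    @pytest.mark.parametrize(
        "name, seed",
        [
            ("consistent", 0),
            ("moderately_active", 1),
            ("non_vigorous", 0),
            ("extremely_active", 0),
            ("outlier", 2),
        ],
    )
    def test_mims_archetypes_get_intended_label(self, mims_config, name, seed):
        rec = ap.analyze_participant(make_archetype(name, mims_config, seed=seed),
                                     mims_config)
        assert rec.profile.label == name

    def test_angle_threshold_straddle(self, counts_config):
        # s2 == s3 -> consistent; arctan gap 0.002 rad -> moderately active
        flat = log_points_on_line([110.0, 2000.0, 5500.0],
                                  [-0.01, -0.001, -0.001, -0.0002])
        fit = fitted(flat)
        assert ap.classify(flat, fit, counts_config).label == "consistent"
        kinked = log_points_on_line([110.0, 2000.0, 5500.0],
                                    [-0.01, -0.001, -0.003, -0.0002])
        fit2 = fitted(kinked)
        res = ap.classify(kinked, fit2, counts_config)
        assert res.label == "moderately_active"
        assert res.angle_diff == pytest.approx(0.002, abs=1e-5)

    def test_low_r2_marks_outlier(self, counts_config):
        rng = np.random.default_rng(0)
        base = log_points_on_line([110.0, 2000.0, 5500.0],
                                  [-0.01, -0.001, -0.0008, -0.0003])
        # heavy smooth distortion below the vigorous range
        wobble = 1.8 * np.sin(base.x / 350.0)
        wobble[base.x > 4000.0] = 0.0
        pts = ap.LogPoints(base.x, base.y + wobble)
        fit = fitted(pts)
        res = ap.classify(pts, fit, counts_config)
        assert res.label == "outlier"
        assert res.r2 < 0.9

    def test_label_invariant_to_probability_rescaling(self, counts_config):
        for name in ("consistent", "extremely_active", "non_vigorous"):
            series = make_archetype(name, counts_config, seed=3)
            _, pts = ap.prepare_distribution(series, counts_config)
            shifted = ap.LogPoints(pts.x, pts.y + np.log(10.0), pts.minutes)
            r1 = ap.classify(pts, ap.fit_breakpoints(pts, counts_config), counts_config)
            r2 = ap.classify(shifted, ap.fit_breakpoints(shifted, counts_config), counts_config)
            assert r1.label == r2.label

    def test_spike_weight_monotonicity(self, counts_config):
        # once the spike makes a participant extremely active, heavier spikes
        # must never demote them back to consistent/moderately active
        from actiprofile.synthetic import SimulationParams, Spike, sample_minutes

        labels = []
        for w in (0.0, 0.01, 0.03, 0.06, 0.1):
            spike = None if w == 0 else Spike(location=7900.0, log_sd=0.06, weight=w)
            params = SimulationParams(
                config=counts_config, breakpoints=(110.0, 2000.0, 5500.0),
                rates=(-0.04, -0.001, -0.001, -0.0004), spike=spike, seed=42,
            )
            rec = ap.analyze_participant(sample_minutes(params), counts_config)
            labels.append(rec.profile.label)
        seen_extreme = False
        for label in labels:
            if label == "extremely_active":
                seen_extreme = True
            elif seen_extreme:
                assert label not in ("consistent", "moderately_active")
        assert seen_extreme

    def test_every_participant_gets_exactly_one_known_label(self, counts_config):
        for seed in range(3):
            for name in ("consistent", "outlier", "extremely_active"):
                rec = ap.analyze_participant(
                    make_archetype(name, counts_config, seed=seed), counts_config
                )
                assert rec.profile.label in ap.PROFILE_LABELS
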