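"""Stabilogram parameters: closed-form oracles, dual implementations,
structural counts, and the feature-table assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import swayrisk as sr
from swayrisk.features import (
    FeatureConfig,
    distance_measures,
    ellipse_area_95,
    fractal_dimension,
    mean_frequency,
    spectral_features,
    sway_area_per_second,
)
from .conftest import sinusoid_trial

FS = 90.0


def circle_path(radius=5.0, rev_per_s=0.5, fs=FS, duration=30.0):
    t = np.arange(int(duration * fs)) / fs
    ang = 2 * np.pi * rev_per_s * t
    return radius * np.cos(ang), radius * np.sin(ang), t


# --------------------------------------------------------------------------
# independent brute-force re-implementations (the dual oracle)


def oracle_distance(ml, ap, fs):
    n = len(ml)
    dur = (n - 1) / fs
    r = [np.sqrt(ml[i] ** 2 + ap[i] ** 2) for i in range(n)]
    out = {}
    for nm, s in (("ml", ml), ("ap", ap)):
        absd = [abs(v) for v in s]
        out[f"mean_dist_{nm}"] = sum(absd) / n
        out[f"max_dist_{nm}"] = max(absd)
        out[f"rms_dist_{nm}"] = np.sqrt(sum(v * v for v in s) / n)
        out[f"range_{nm}"] = max(s) - min(s)
        out[f"mean_velocity_{nm}"] = (
            sum(abs(s[i + 1] - s[i]) for i in range(n - 1)) / dur
        )
    out["mean_dist_r"] = sum(r) / n
    out["max_dist_r"] = max(r)
    out["rms_dist_r"] = np.sqrt(sum(v * v for v in r) / n)
    out["range_r"] = max(r)
    out["mean_velocity_r"] = (
        sum(
            np.sqrt((ml[i + 1] - ml[i]) ** 2 + (ap[i + 1] - ap[i]) ** 2)
            for i in range(n - 1)
        )
        / dur
    )
    return out


def oracle_sway_area(ml, ap, duration):
    return sum(
        abs(ap[i + 1] * ml[i] - ap[i] * ml[i + 1]) / 2 for i in range(len(ml) - 1)
    ) / duration


def oracle_fd(ml, ap, diameter="max_radius"):
    n = len(ml)
    L = sum(
        np.sqrt((ml[i + 1] - ml[i]) ** 2 + (ap[i + 1] - ap[i]) ** 2)
        for i in range(n - 1)
    )
    if diameter == "max_radius":
        d = max(np.sqrt(ml[i] ** 2 + ap[i] ** 2) for i in range(n))
    else:
        d = max(
            np.sqrt((ml[i] - ml[j]) ** 2 + (ap[i] - ap[j]) ** 2)
            for i in range(n)
            for j in range(n)
        )
    return np.log(n) / np.log(n * d / L)


class TestDualOracle:
    """Every formula agrees with a straightforward re-implementation."""

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_distance_measures_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ml, ap = rng.standard_normal(200), rng.standard_normal(200)
        got = distance_measures(ml, ap, FS)
        want = oracle_distance(list(ml), list(ap), FS)
        for k in want:
            assert got[k] == pytest.approx(want[k], rel=1e-9), k

    def test_sway_area_matches_oracle(self):
        rng = np.random.default_rng(3)
        ml, ap = rng.standard_normal(300), rng.standard_normal(300)
        dur = 299 / FS
        assert sway_area_per_second(ml, ap, dur) == pytest.approx(
            oracle_sway_area(list(ml), list(ap), dur), rel=1e-9
        )

    @pytest.mark.parametrize("diameter", ["max_radius", "farthest_pair"])
    def test_fractal_dimension_matches_oracle(self, diameter):
        rng = np.random.default_rng(4)
        steps = rng.standard_normal((2, 200))
        ml, ap = np.cumsum(steps[0]), np.cumsum(steps[1])
        ml, ap = ml - ml.mean(), ap - ap.mean()
        assert fractal_dimension(ml, ap, diameter) == pytest.approx(
            oracle_fd(list(ml), list(ap), diameter), rel=1e-12
        )


class TestDistanceClosedForms:
    def test_all_zero_input_gives_zeros(self):
        got = distance_measures(np.zeros(100), np.zeros(100), FS)
        assert all(v == 0 for v in got.values())

    def test_sinusoid_closed_forms(self):
        """A = 10 mm, f = 0.5 Hz: RMS = A/sqrt2, range = 2A, mean = 2A/pi, MV = 4Af."""
        tr = sinusoid_trial(freq=0.5, amp_ap=10.0)
        got = distance_measures(tr.ml, tr.ap, FS)
        assert got["rms_dist_ap"] == pytest.approx(10 / np.sqrt(2), rel=0.02)
        assert got["range_ap"] == pytest.approx(20.0, rel=0.02)
        assert got["mean_dist_ap"] == pytest.approx(20 / np.pi, rel=0.02)
        assert got["mean_velocity_ap"] == pytest.approx(4 * 10 * 0.5, rel=0.02)

    def test_circle_constant_radius(self):
        ml, ap, t = circle_path(radius=5.0)
        got = distance_measures(ml, ap, FS)
        assert got["mean_dist_r"] == pytest.approx(5.0, rel=1e-9)
        assert got["rms_dist_r"] == pytest.approx(5.0, rel=1e-9)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            distance_measures(np.array([1.0]), np.array([1.0]), FS)


class TestEllipseArea:
    def test_zero_variance_gives_zero(self):
        assert ellipse_area_95(np.zeros(50), np.zeros(50)) == 0.0

    def test_collinear_axes_give_zero(self):
        x = np.linspace(-1, 1, 100)
        assert ellipse_area_95(x, 2 * x) == pytest.approx(0.0, abs=1e-9)

    def test_independent_gaussians_match_closed_form(self):
        """sigma = 2 mm on both axes: area ~ 2*pi*3*sigma^2 = 75.4 mm^2."""
        areas = [
            ellipse_area_95(*np.random.default_rng(s).normal(0, 2, (2, 2700)))
            for s in range(10)
        ]
        assert np.mean(areas) == pytest.approx(2 * np.pi * 3 * 4, rel=0.10)


class TestSwayArea:
    def test_stationary_point_zero(self):
        assert sway_area_per_second(np.zeros(50), np.zeros(50), 1.0) == 0.0

    def test_pure_one_dimensional_motion_zero(self):
        ap = np.sin(np.linspace(0, 10, 300))
        assert sway_area_per_second(np.zeros(300), ap, 1.0) == 0.0

    def test_circle_sweeps_area_times_revolutions(self):
        """Radius 5 at 0.5 rev/s sweeps 0.5 * pi * 25 = 39.27 mm^2/s."""
        ml, ap, t = circle_path(radius=5.0, rev_per_s=0.5)
        got = sway_area_per_second(ml, ap, (len(t) - 1) / FS)
        assert got == pytest.approx(0.5 * np.pi * 25, rel=0.01)


class TestMeanFrequency:
    def test_sinusoid_recovers_its_frequency(self):
        tr = sinusoid_trial(freq=0.5, amp_ap=10.0)
        d = distance_measures(tr.ml, tr.ap, FS)
        mf = mean_frequency(d["mean_velocity_ap"], d["mean_dist_ap"])
        # MVELO/(2*pi*MDIST) = 4Af / (2*pi*(2A/pi)) = 4Af / 4A = f
        assert mf == pytest.approx(0.5, rel=0.02)

    def test_circle_recovers_rotation_frequency(self):
        ml, ap, t = circle_path(radius=5.0, rev_per_s=0.5)
        d = distance_measures(ml, ap, FS)
        mf = mean_frequency(d["mean_velocity_r"], d["mean_dist_r"])
        assert mf == pytest.approx(0.5, rel=0.02)

    def test_zero_motion_is_undefined(self):
        assert np.isnan(mean_frequency(0.0, 0.0))


class TestFractalDimension:
    def test_straight_traversal_is_one(self):
        """When the path length equals the diameter, FD = ln N / ln N = 1."""
        x = np.linspace(0.0, 10.0, 100)
        assert fractal_dimension(x, np.zeros(100), "farthest_pair") == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        ml, ap = np.cumsum(rng.standard_normal((2, 500)), axis=1)
        fd1 = fractal_dimension(ml, ap)
        fd2 = fractal_dimension(17.3 * ml, 17.3 * ap)
        assert fd1 == pytest.approx(fd2, rel=1e-12)

    def test_degenerate_path_is_nan(self):
        assert np.isnan(fractal_dimension(np.zeros(10), np.zeros(10)))


class TestSpectralFeatures:
    def test_pure_tone_concentrates_spectrum(self):
        t = np.arange(2700) / FS
        x = 3.0 * np.sin(2 * np.pi * 1.0 * t)
        got = spectral_features(x, FS)
        assert got["f50"] == pytest.approx(1.0, abs=0.25)
        assert got["f95"] == pytest.approx(1.0, abs=0.25)
        assert got["centroid_freq"] == pytest.approx(1.0, abs=0.25)
        # a spectral line broadened only by the Welch resolution (0.2 Hz
        # bins at 5 s segments) has relative spread ~0.13 around 1 Hz
        assert got["freq_dispersion"] <= 0.15

    def test_total_power_parseval(self):
        """Band-integrated PSD of an in-band tone ~ its variance A^2/2."""
        t = np.arange(2700) / FS
        x = 4.0 * np.sin(2 * np.pi * 1.0 * t)
        got = spectral_features(x, FS)
        assert got["total_power"] == pytest.approx(16 / 2, rel=0.05)

    def test_broadband_disperses_more_than_tone(self):
        t = np.arange(2700) / FS
        tone = spectral_features(np.sin(2 * np.pi * t), FS)
        noise = spectral_features(np.random.default_rng(0).standard_normal(2700), FS)
        assert noise["freq_dispersion"] > tone["freq_dispersion"]

    def test_silent_signal_policy(self):
        got = spectral_features(np.zeros(2700), FS)
        assert got["total_power"] == 0.0
        assert np.isnan(got["f50"])


class TestExtractTrialFeatures:
    def test_returns_31_finite_named_values(self, small_cohort):
        _, trials = small_cohort
        tr = sr.preprocess(trials[0])
        feats = sr.extract_trial_features(tr)
        assert tuple(feats) == sr.PARAMETER_NAMES
        assert len(feats) == 31
        assert all(np.isfinite(v) for v in feats.values())

    def test_deterministic(self, small_cohort):
        _, trials = small_cohort
        tr = sr.preprocess(trials[0])
        assert sr.extract_trial_features(tr) == sr.extract_trial_features(tr)

    def test_amplitude_homogeneity(self, small_cohort):
        """Doubling the trajectory doubles distances, squares areas, and
        leaves frequency measures unchanged."""
        import dataclasses

        _, trials = small_cohort
        tr = sr.preprocess(trials[0])
        f1 = sr.extract_trial_features(tr)
        f2 = sr.extract_trial_features(
            dataclasses.replace(tr, ml=2 * tr.ml, ap=2 * tr.ap)
        )
        for d in ("ml", "ap", "r"):
            assert f2[f"rms_dist_{d}"] == pytest.approx(2 * f1[f"rms_dist_{d}"], rel=1e-9)
            assert f2[f"mean_velocity_{d}"] == pytest.approx(
                2 * f1[f"mean_velocity_{d}"], rel=1e-9
            )
            assert f2[f"mean_freq_{d}"] == pytest.approx(f1[f"mean_freq_{d}"], rel=1e-9)
        assert f2["ellipse_area_95"] == pytest.approx(4 * f1["ellipse_area_95"], rel=1e-9)
        for ax in ("ml", "ap"):
            assert f2[f"f50_{ax}"] == pytest.approx(f1[f"f50_{ax}"], rel=1e-9)
            assert f2[f"centroid_freq_{ax}"] == pytest.approx(
                f1[f"centroid_freq_{ax}"], rel=1e-9
            )


class TestFeatureTable:
    def test_shape_and_columns(self, small_table):
        assert small_table.shape == (12, 124 + 5 + 2)
        posturo = sr.posturographic_columns()
        assert len(posturo) == 124
        assert list(small_table.columns[:124]) == posturo
        assert not small_table.isna().any().any()
        assert small_table.columns.is_unique

    def test_incomplete_participant_excluded_and_logged(self, small_spec):
        ps, trials = sr.generate_cohort(small_spec)
        dropped = ps[0].id
        trials = [
            t for t in trials if not (t.participant_id == dropped and t.condition == "N-EC")
        ]
        table, log = sr.build_feature_table(ps, trials)
        assert dropped not in table.index
        assert dropped in log.excluded and "N-EC" in log.excluded[dropped]
        assert len(table) == len(ps) - 1

    def test_duplicate_trial_key_raises(self, small_cohort):
        ps, trials = small_cohort
        with pytest.raises(ValueError, match="duplicate"):
            sr.build_feature_table(ps, list(trials) + [trials[0]])

    def test_condition_averaging_is_arithmetic_mean(self, small_spec, small_cohort):
        ps, trials = small_cohort
        table, _ = sr.build_feature_table(ps, trials)
        p = ps[0]
        per_trial = {}
        for tr in trials:
            if tr.participant_id == p.id and tr.condition == "W-EO":
                per_trial[tr.trial_index] = sr.extract_trial_features(sr.preprocess(tr))
        want = 0.5 * (per_trial[1]["rms_dist_ap"] + per_trial[2]["rms_dist_ap"])
        assert table.loc[p.id, "W-EO__rms_dist_ap"] == pytest.approx(want, rel=1e-12)

    def test_labels_match_participants(self, small_cohort, small_table):
        ps, _ = small_cohort
        for p in ps:
            assert small_table.loc[p.id, "criteria_I"] == int(p.fell_last_year)
            assert small_table.loc[p.id, "criteria_II"] == int(p.slow_tug)
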