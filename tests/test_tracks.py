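"""Trace pipeline: normalization, smoothing, QC, slope fitting, summaries."""

import numpy as np
import pandas as pd
import pytest

from notchdyn.exceptions import DataError, ParameterError
from notchdyn.tracks import (
    PATTERN_DOWN,
    PATTERN_UP,
    PATTERN_UPDOWN,
    QCThresholds,
    classify_pattern,
    moving_average,
    normalize_movie,
    pattern_summary,
    process_tracks,
    qc_track,
    rate_summary,
    smooth_track,
    split_and_fit,
)
from oracles import moving_average_ref


def track_frame(gfp, rfp=None, movie="m1", cell="c1", condition="healthy"):
    gfp = np.asarray(gfp, dtype=float)
    rfp = np.full_like(gfp, 0.5) if rfp is None else np.asarray(rfp, dtype=float)
    return pd.DataFrame(
        {
            "movie_id": movie,
            "cell_id": cell,
            "condition": condition,
            "frame": np.arange(len(gfp)),
            "time_min": np.arange(len(gfp)) * 7.5,
            "gfp": gfp,
            "rfp": rfp,
        }
    )


def triangle(rise=0.02, fall=-0.03, n_up=40, n_down=40, base=0.1):
    up = base + rise * np.arange(n_up + 1)
    down = up[-1] + fall * np.arange(1, n_down + 1)
    return np.concatenate([up, down])


class TestNormalization:
    def test_scales_by_movie_channel_maximum(self):
        df = track_frame([50.0, 200.0, 100.0])
        out = normalize_movie(df)
        assert list(out["gfp_norm"]) == [0.25, 1.0, 0.5]

    def test_movies_normalized_independently(self):
        df = pd.concat(
            [track_frame([10.0, 20.0], movie="m1"), track_frame([100.0, 400.0], movie="m2")],
            ignore_index=True,
        )
        out = normalize_movie(df)
        assert out.groupby("movie_id")["gfp_norm"].max().eq(1.0).all()

    def test_idempotent(self):
        df = normalize_movie(track_frame([50.0, 200.0, 100.0]))
        again = normalize_movie(df.assign(gfp=df["gfp_norm"], rfp=df["rfp_norm"]))
        assert np.allclose(again["gfp_norm"], df["gfp_norm"])

    def test_negative_and_all_zero_rejected(self):
        with pytest.raises(DataError):
            normalize_movie(track_frame([-1.0, 2.0]))
        with pytest.raises(DataError):
            normalize_movie(track_frame([1.0, 2.0], rfp=[0.0, 0.0]))


class TestSmoothing:
    def test_reproduces_constants_and_lines(self):
        const = np.full(30, 0.4)
        assert np.allclose(smooth_track(const), const, atol=1e-12)
        line = 0.01 * np.arange(50) + 0.2
        assert np.allclose(smooth_track(line), line, atol=1e-9)

    def test_robustly_suppresses_single_spike_below_moving_average(self):
        y = np.full(31, 0.2)
        y[15] += 1.0
        smoothed_peak = smooth_track(y)[15] - 0.2
        ma_peak = moving_average_ref(y, 5)[15] - 0.2
        assert smoothed_peak < ma_peak  # bisquare downweights the outlier

    def test_moving_average_matches_reference(self, rng):
        y = rng.random(25)
        assert np.allclose(moving_average(y, 5), moving_average_ref(y, 5), atol=1e-12)

    def test_even_or_tiny_window_rejected(self):
        with pytest.raises(ParameterError):
            smooth_track(np.zeros(10), window=4)
        with pytest.raises(ParameterError):
            smooth_track(np.zeros(10), window=1)


class TestQC:
    def test_short_track_excluded(self):
        qc = qc_track(np.full(6, 0.5), np.full(6, 0.5))
        assert qc.status == "excluded_short" and qc.n_points == 6

    def test_recently_notch_off_cell_flagged(self):
        # visible RFP but GFP never reaches 0.1: recently deactivated Notch
        qc = qc_track(np.full(40, 0.05), np.full(40, 0.3))
        assert qc.status == "notch_off"

    def test_dim_first_half_excluded_as_low_signal(self):
        gfp = np.concatenate([np.full(20, 0.05), np.full(20, 0.9)])
        qc = qc_track(gfp, np.full(40, 0.05))
        assert qc.status == "excluded_low_signal"
        assert qc.first_half_mean_gfp == pytest.approx(0.05)

    def test_noisy_track_excluded(self, rng):
        gfp = np.clip(0.4 + rng.normal(0, 0.2, 40), 0, 1)
        assert qc_track(gfp, np.full(40, 0.5)).status == "excluded_noisy"

    def test_clean_ramp_included(self):
        gfp = np.linspace(0.3, 0.9, 40)
        qc = qc_track(gfp, np.full(40, 0.5))
        assert qc.status == "included" and qc.noise_score < 0.01

    def test_qc_judges_each_track_alone(self, rng):
        gfp = np.linspace(0.3, 0.9, 40)
        alone = qc_track(gfp, np.full(40, 0.5)).status
        assert alone == qc_track(gfp, np.full(40, 0.5)).status == "included"


class TestSplitAndFit:
    def test_pure_ramp_gives_single_exact_rising_fit(self):
        y = 0.1 + 0.03 * np.arange(40)
        fit = split_and_fit(y)
        assert fit.falling is None and fit.split_index == 39
        assert fit.rising.slope == pytest.approx(0.03, abs=1e-10)

    def test_triangle_recovers_both_construction_slopes_exactly(self):
        fit = split_and_fit(triangle())
        assert fit.split_index == 40
        assert fit.rising.slope == pytest.approx(0.02, abs=1e-10)
        assert fit.falling.slope == pytest.approx(-0.03, abs=1e-10)
        # split conservation: the shared maximum is counted in both segments
        assert fit.rising.n_points + fit.falling.n_points == len(triangle()) + 1

    def test_argmax_tie_broken_to_earliest_index(self):
        y = np.array([0.0, 1.0, 0.5, 1.0, 0.0, 0.0])
        assert split_and_fit(y, min_seg_points=2).split_index == 1

    def test_noisy_slope_recovery_within_tolerance(self, rng):
        true_slope = 0.02
        errs = []
        for _ in range(30):
            y = 0.1 + true_slope * np.arange(60) + rng.normal(0, 0.02, 60)
            fit = split_and_fit(smooth_track(np.clip(y, 0, None)))
            seg = fit.rising if fit.rising is not None else fit.falling
            errs.append(abs(seg.slope - true_slope) / true_slope)
        assert max(errs) < 0.15

    def test_unfittable_track_flagged(self):
        with pytest.raises(DataError):
            split_and_fit(np.array([1.0, 0.5]), min_seg_points=3)


class TestPatternsAndSummaries:
    def test_ramp_and_triangle_patterns(self):
        assert classify_pattern(split_and_fit(0.1 + 0.02 * np.arange(40))) == PATTERN_UP
        assert classify_pattern(split_and_fit(triangle())) == PATTERN_UPDOWN
        assert classify_pattern(split_and_fit(0.9 - 0.02 * np.arange(40))) == PATTERN_DOWN

    def test_pattern_summary_reproduces_printed_proportions(self):
        qc = pd.DataFrame(
            {
                "condition": "injured",
                "status": "included",
                "pattern": [PATTERN_UPDOWN] * 53 + [PATTERN_UP] * 20 + [PATTERN_DOWN] * 20,
            }
        )
        out = pattern_summary(qc)
        row = out[(out["pattern"] == PATTERN_UPDOWN)].iloc[0]
        assert row["n"] == 53 and row["n_total"] == 93
        assert round(row["pct"]) == 57

    def test_rate_summary_median_and_rapid_fraction(self):
        slopes = pd.DataFrame(
            {"condition": "healthy", "segment": "rising", "slope": [0.01, 0.02, 0.03]}
        )
        out = rate_summary(slopes)
        assert out["median_slope"].iloc[0] == pytest.approx(0.02)
        assert out["rapid_fraction"].iloc[0] == pytest.approx(1 / 3)

    def test_all_slow_slopes_give_zero_rapid_fraction(self):
        slopes = pd.DataFrame(
            {"condition": "healthy", "segment": "falling", "slope": [-0.01, -0.02]}
        )
        assert rate_summary(slopes)["rapid_fraction"].iloc[0] == 0.0


class TestPipeline:
    def test_noiseless_triangle_movie_classified_perfectly(self):
        frames = []
        for k in range(4):
            frames.append(track_frame(100 * triangle(n_down=25), cell=f"tri{k}"))
            frames.append(track_frame(10 + 2.0 * np.arange(40), cell=f"up{k}"))
        qc, slopes = process_tracks(pd.concat(frames, ignore_index=True))
        assert (qc["status"] == "included").all()
        tri = qc[qc["cell_id"].str.startswith("tri")]
        up = qc[qc["cell_id"].str.startswith("up")]
        assert (tri["pattern"] == PATTERN_UPDOWN).all()
        assert (up["pattern"] == PATTERN_UP).all()

    def test_missing_columns_rejected(self):
        with pytest.raises(DataError):
            process_tracks(pd.DataFrame({"movie_id": [], "cell_id": []}))


class TestConditionOrdering:
    def test_faster_generative_rates_yield_faster_measured_upregulation(self):
        """A movie generated with injury-like fast activity rates must show a
        larger median rising slope than a healthy-like movie."""
        from notchdyn.synth import gen_movie

        medians = {}
        for preset, seed in (("healthy", 21), ("injured", 22)):
            tracks, _ = gen_movie(preset=preset, seed=seed)
            _, slopes = process_tracks(tracks)
            rising = slopes[slopes["segment"] == "rising"]["slope"]
            medians[preset] = rising.median()
        assert medians["injured"] > medians["healthy"]
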