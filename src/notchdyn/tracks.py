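"""Single-cell dual-fluorophore timer trace pipeline.

Live movies of the NRE-driven TransTimer reporter yield, per tracked cell, a
dGFP and an RFP mean-intensity series sampled every 7.5 minutes.  The
pipeline: (1) normalizes each channel to [0, 1] per movie by its movie-wide
maximum; (2) smooths each track with a robust 5-point local-linear regression
('rlowess'); (3) applies QC exclusions (too short, low signal, recently
Notch-OFF, too noisy); (4) splits each included track at the smoothed maximum
into rising and falling segments and fits a least-squares line to each;
(5) classifies the phase pattern (up_only / down_only / up_down) and
summarizes rates per condition.

Slopes are in normalized intensity per frame (7.5-min sampling); "rapid"
activation/deactivation means |slope| > 0.025 per frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, ParameterError
from .stats import mann_whitney

__all__ = [
    "TrackQC",
    "SlopeResult",
    "TrackFit",
    "QCThresholds",
    "FRAME_INTERVAL_MIN",
    "PER_HOUR_FACTOR",
    "normalize_movie",
    "smooth_track",
    "moving_average",
    "qc_track",
    "split_and_fit",
    "classify_pattern",
    "process_tracks",
    "pattern_summary",
    "rate_summary",
]

#: Sampling interval of the live movies, minutes per frame.
FRAME_INTERVAL_MIN = 7.5
#: Multiply a per-frame slope by this to express it per hour.
PER_HOUR_FACTOR = 60.0 / FRAME_INTERVAL_MIN

STATUS_INCLUDED = "included"
STATUS_SHORT = "excluded_short"
STATUS_LOW = "excluded_low_signal"
STATUS_OFF = "notch_off"
STATUS_NOISY = "excluded_noisy"


@dataclass(frozen=True)
class QCThresholds:
    """Track inclusion rules.

    first_half_floor: minimum mean normalized GFP over the first half of the
        track; dimmer tracks never activated within the window.
    min_points: minimum number of frames for slope analysis.
    off_gfp: whole-track GFP ceiling below which a cell with visible RFP is a
        recently Notch-OFF cell (excluded from slope analysis as its own
        category).
    rfp_present: RFP mean above which RFP is considered "visible".
    noise_cap: maximum residual-noise score
        SD(raw - smoothed) / (max - min of smoothed).
    """

    first_half_floor: float = 0.1
    min_points: int = 8
    off_gfp: float = 0.1
    rfp_present: float = 0.1
    noise_cap: float = 0.15


@dataclass
class TrackQC:
    status: str
    first_half_mean_gfp: float
    n_points: int
    noise_score: float


@dataclass
class SlopeResult:
    segment: str  # "rising" | "falling"
    slope: float
    intercept: float
    n_points: int


@dataclass
class TrackFit:
    rising: SlopeResult | None
    falling: SlopeResult | None
    split_index: int
    pattern: str | None = None


def normalize_movie(
    tracks: pd.DataFrame, channels: tuple[str, ...] = ("gfp", "rfp")
) -> pd.DataFrame:
    """Normalize each channel to [0, 1] independently within each movie.

    Every value is divided by the movie-wide per-channel maximum, so exactly
    one measurement per (movie, channel) maps to 1.  Idempotent.
    """
    if len(tracks) == 0:
        raise DataError("no tracks to normalize")
    out = tracks.copy()
    for ch in channels:
        if ch not in out.columns:
            raise DataError(f"channel column {ch!r} not present")
        if (out[ch] < 0).any():
            raise DataError(f"negative intensities in channel {ch!r}")
        peak = out.groupby("movie_id")[ch].transform("max")
        if (peak <= 0).any():
            bad = sorted(out.loc[peak <= 0, "movie_id"].unique())
            raise DataError(f"all-zero channel {ch!r} in movie(s) {bad}")
        out[f"{ch}_norm"] = out[ch] / peak
    return out


def _local_linear(x: np.ndarray, y: np.ndarray, w: np.ndarray, x0: float) -> float:
    """Weighted least-squares line through (x, y) evaluated at x0."""
    sw = w.sum()
    if sw <= 0:
        return float(np.mean(y))
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx <= 1e-300:
        return float(ym)
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    return float(ym + slope * (x0 - xm))


def smooth_track(values: np.ndarray, window: int = 5, robustness_iters: int = 2) -> np.ndarray:
    """Robust local-linear ('rlowess') smoothing with a 5-point span.

    For each point, a line is fitted to the ``window`` nearest points with
    tricube distance weights, then ``robustness_iters`` bisquare re-weighting
    passes (weights zeroed beyond 6x the median absolute residual) downweight
    outliers.  Local linear fits reproduce constant and exactly linear series
    unchanged.
    """
    if window < 3 or window % 2 == 0:
        raise ParameterError(f"window must be an odd integer >= 3, got {window}")
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < window:
        raise DataError(f"need at least {window} points, got {n}")
    x = np.arange(n, dtype=float)
    half = window // 2
    neighborhoods = []
    for i in range(n):
        lo = min(max(0, i - half), n - window)
        idx = np.arange(lo, lo + window)
        dist = np.abs(x[idx] - x[i])
        dmax = dist.max()
        tricube = (1.0 - (dist / dmax) ** 3) ** 3 if dmax > 0 else np.ones(window)
        neighborhoods.append((idx, tricube))

    robust_w = np.ones(n)
    smoothed = values.copy()
    for iteration in range(robustness_iters + 1):
        for i, (idx, tricube) in enumerate(neighborhoods):
            w = tricube * robust_w[idx]
            if w.sum() <= 0:
                w = tricube  # every neighbor flagged: fall back to distance weights
            smoothed[i] = _local_linear(x[idx], values[idx], w, x[i])
        if iteration == robustness_iters:
            break
        resid = values - smoothed
        s = 6.0 * np.median(np.abs(resid))
        if s <= 0:
            # MAD degenerates to 0 when most points fit exactly (e.g. a flat
            # baseline with isolated spikes); fall back to the mean scale
            s = 6.0 * np.mean(np.abs(resid))
        if s <= 1e-9 * (np.max(np.abs(values)) + 1.0):
            break  # residuals at floating-point roundoff: nothing to re-weight
        u = np.clip(resid / s, -1.0, 1.0)
        robust_w = (1.0 - u**2) ** 2
    return smoothed


def moving_average(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average with truncated edges (sensitivity-analysis companion)."""
    if window < 3 or window % 2 == 0:
        raise ParameterError(f"window must be an odd integer >= 3, got {window}")
    values = np.asarray(values, dtype=float)
    half = window // 2
    out = np.empty_like(values)
    for i in range(values.shape[0]):
        lo, hi = max(0, i - half), min(values.shape[0], i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def qc_track(
    gfp_norm: np.ndarray,
    rfp_norm: np.ndarray,
    smoothed: np.ndarray | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> TrackQC:
    """Assign one QC status per track.

    Rules, first match wins: too short; recently Notch-OFF (visible RFP but
    whole-track GFP below the off threshold); low signal (first-half mean GFP
    below the floor); too noisy (residual score above the cap); included.
    Each track is judged alone, so QC is order-independent across tracks.
    """
    gfp = np.asarray(gfp_norm, dtype=float)
    rfp = np.asarray(rfp_norm, dtype=float)
    n = gfp.shape[0]
    first_half = gfp[: math.ceil(n / 2)]
    fh_mean = float(first_half.mean()) if n else np.nan

    if n < thresholds.min_points:
        return TrackQC(STATUS_SHORT, fh_mean, n, np.nan)
    if np.all(gfp < thresholds.off_gfp) and rfp.mean() >= thresholds.rfp_present:
        return TrackQC(STATUS_OFF, fh_mean, n, np.nan)
    if fh_mean < thresholds.first_half_floor:
        return TrackQC(STATUS_LOW, fh_mean, n, np.nan)
    if smoothed is None:
        smoothed = smooth_track(gfp)
    resid_sd = float(np.std(gfp - smoothed))
    span = float(smoothed.max() - smoothed.min())
    if span == 0.0:
        score = 0.0 if resid_sd == 0.0 else np.inf
    else:
        score = resid_sd / span
    if score > thresholds.noise_cap:
        return TrackQC(STATUS_NOISY, fh_mean, n, score)
    return TrackQC(STATUS_INCLUDED, fh_mean, n, score)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def split_and_fit(smoothed: np.ndarray, min_seg_points: int = 3) -> TrackFit:
    """Split a smoothed track at its maximum and fit y = m*x + b per segment.

    The maximum (earliest index on ties) belongs to both segments.  Segments
    shorter than ``min_seg_points`` are not fitted; an argmax at the first or
    last index yields a single-segment result.  x is the frame offset within
    the track (0, 1, 2, ...), so slopes are per frame.
    """
    y = np.asarray(smoothed, dtype=float)
    n = y.shape[0]
    x = np.arange(n, dtype=float)
    imax = int(np.argmax(y))
    rising = falling = None
    if imax + 1 >= min_seg_points:
        m, b = _ols_line(x[: imax + 1], y[: imax + 1])
        rising = SlopeResult("rising", m, b, imax + 1)
    if n - imax >= min_seg_points:
        m, b = _ols_line(x[imax:], y[imax:])
        falling = SlopeResult("falling", m, b, n - imax)
    if rising is None and falling is None:
        raise DataError(
            f"track unfittable: both segments below {min_seg_points} points (argmax={imax}, n={n})"
        )
    return TrackFit(rising=rising, falling=falling, split_index=imax)


PATTERN_UP = "up_only"
PATTERN_DOWN = "down_only"
PATTERN_UPDOWN = "up_down"
PATTERN_INDET = "indeterminate"


def classify_pattern(
    fit: TrackFit,
    rise_floor: float = 0.002,
    fall_floor: float = 0.002,
    min_amplitude: float = 0.1,
) -> str:
    """Phase pattern from the fitted segment slopes.

    up_down requires both a qualifying rising segment (slope > rise_floor)
    and a qualifying falling segment (slope < -fall_floor); otherwise the
    single qualifying segment decides.  Returns 'indeterminate' when no
    segment qualifies.

    To qualify, a segment must also traverse at least ``min_amplitude``
    normalized intensity units (|slope| x segment span).  Slope floors alone
    cannot reject the short, steep spurious segments that noise creates when
    the track maximum wanders onto a plateau or track edge, because those can
    be steeper than genuine slow phases; real signaling phases instead sweep
    a large fraction of the track's range.
    """

    def qualifies(seg, sign: float) -> bool:
        if seg is None:
            return False
        floor = rise_floor if sign > 0 else fall_floor
        if sign * seg.slope <= floor:
            return False
        return abs(seg.slope) * (seg.n_points - 1) >= min_amplitude

    has_rise = qualifies(fit.rising, +1.0)
    has_fall = qualifies(fit.falling, -1.0)
    if has_rise and has_fall:
        return PATTERN_UPDOWN
    if has_rise:
        return PATTERN_UP
    if has_fall:
        return PATTERN_DOWN
    return PATTERN_INDET


def process_tracks(
    tracks: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
    window: int = 5,
    rise_floor: float = 0.002,
    fall_floor: float = 0.002,
    min_amplitude: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full trace pipeline on a long-format track table.

    Expects columns movie_id, cell_id, condition, frame, gfp, rfp (raw
    intensities); returns ``(qc_frame, slope_frame)``: one row per track with
    QC status and, for included tracks, the fitted pattern; and one row per
    fitted segment with its slope.
    """
    required = {"movie_id", "cell_id", "condition", "frame", "gfp", "rfp"}
    missing = required - set(tracks.columns)
    if missing:
        raise DataError(f"track table missing columns {sorted(missing)}")
    norm = normalize_movie(tracks)
    qc_rows: list[dict] = []
    slope_rows: list[dict] = []
    for (movie_id, cell_id), grp in norm.groupby(["movie_id", "cell_id"], sort=True):
        grp = grp.sort_values("frame")
        condition = grp["condition"].iloc[0]
        gfp = grp["gfp_norm"].to_numpy()
        rfp = grp["rfp_norm"].to_numpy()
        smoothed = smooth_track(gfp, window=window) if len(gfp) >= window else None
        qc = qc_track(gfp, rfp, smoothed=smoothed, thresholds=thresholds)
        row = {
            "movie_id": movie_id,
            "cell_id": cell_id,
            "condition": condition,
            "status": qc.status,
            "n_points": qc.n_points,
            "first_half_mean_gfp": qc.first_half_mean_gfp,
            "noise_score": qc.noise_score,
            "pattern": None,
        }
        if qc.status == STATUS_INCLUDED:
            try:
                fit = split_and_fit(smoothed)
            except DataError:
                row["pattern"] = PATTERN_INDET
            else:
                row["pattern"] = classify_pattern(fit, rise_floor, fall_floor, min_amplitude)
                for seg in (fit.rising, fit.falling):
                    if seg is None:
                        continue
                    slope_rows.append(
                        {
                            "movie_id": movie_id,
                            "cell_id": cell_id,
                            "condition": condition,
                            "segment": seg.segment,
                            "slope": seg.slope,
                            "intercept": seg.intercept,
                            "n_points": seg.n_points,
                        }
                    )
        qc_rows.append(row)
    slope_cols = ["movie_id", "cell_id", "condition", "segment", "slope", "intercept", "n_points"]
    return pd.DataFrame(qc_rows), pd.DataFrame(slope_rows, columns=slope_cols)


def pattern_summary(qc_frame: pd.DataFrame, by: str = "condition") -> pd.DataFrame:
    """Per-group counts and percentages of each phase pattern among included tracks.

    ``pct`` is the exact proportion times 100; integer counts are retained so
    the proportions reproduce the printed "n/N" figures exactly.
    """
    inc = qc_frame[qc_frame["status"] == STATUS_INCLUDED]
    if len(inc) == 0:
        raise DataError("no included tracks to summarize")
    rows = []
    for group, grp in inc.groupby(by, sort=True):
        total = len(grp)
        for pattern in (PATTERN_UP, PATTERN_DOWN, PATTERN_UPDOWN, PATTERN_INDET):
            n = int((grp["pattern"] == pattern).sum())
            rows.append(
                {by: group, "pattern": pattern, "n": n, "n_total": total, "pct": 100.0 * n / total}
            )
    return pd.DataFrame(rows)


def rate_summary(
    slopes: pd.DataFrame,
    rapid_threshold: float = 0.025,
    compare: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Median slope, n, and rapid-signaling fraction per (condition, direction).

    "Rapid" means slope > threshold for rising segments and slope < -threshold
    for falling ones.  When ``compare`` names two conditions, a two-sided
    Mann-Whitney p-value for the slope difference is attached per direction.
    """
    if len(slopes) == 0:
        raise DataError("no slopes to summarize")
    rows = []
    for (condition, segment), grp in slopes.groupby(["condition", "segment"], sort=True):
        vals = grp["slope"].to_numpy()
        rapid = (vals > rapid_threshold) if segment == "rising" else (vals < -rapid_threshold)
        rows.append(
            {
                "condition": condition,
                "segment": segment,
                "n": len(vals),
                "median_slope": float(np.median(vals)) if len(vals) else np.nan,
                "rapid_fraction": float(rapid.mean()) if len(vals) else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    if compare is not None:
        a, b = compare
        out["mw_p_vs_other"] = np.nan
        for segment in out["segment"].unique():
            sa = slopes.query("condition == @a and segment == @segment")["slope"]
            sb = slopes.query("condition == @b and segment == @segment")["slope"]
            if len(sa) and len(sb):
                _, p = mann_whitney(sa, sb)
                out.loc[out["segment"] == segment, "mw_p_vs_other"] = p
    return out
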