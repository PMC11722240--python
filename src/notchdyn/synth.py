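"""Synthetic inputs with known ground truth for the whole pipeline.

Two generators:

* ``gen_population`` draws bimodal log10-intensity populations with
  marker flags (Delta+, PH3+) correlated to the generating component — the
  stand-in for fixed-tissue reporter measurements.
* ``gen_movie`` builds dual-channel timer traces: each cell gets a
  piecewise-linear promoter-activity profile A(t) in [0, 1], which drives a
  two-compartment (immature -> mature) linear ODE per fluorophore:

      dI/dt = A(t) - (k_m + k_d) * I
      dM/dt = k_m * I - k_d * M

  with k_m = ln2 / maturation half-time and k_d = ln2 / half-life.  The
  fast-folding, destabilized dGFP (maturation ~0.1 h, half-life ~2 h) tracks
  A(t) closely; the slow-folding, stable RFP (maturation ~1.5 h, half-life
  ~20 h) lags and persists, so its peak trails the dGFP peak.  Traces are
  sampled every 7.5 min over 20.5 h, like the live movies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .exceptions import DataError, ParameterError, SolverError

__all__ = [
    "PopulationSpec",
    "TimerKinetics",
    "ActivityProfile",
    "HEALTHY_POPULATION",
    "INJURED_POPULATION",
    "MOVIE_PRESETS",
    "default_pattern_counts",
    "gen_population",
    "mature_steady_state",
    "timer_forward",
    "activity_from_trajectory",
    "gen_movie",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Generative parameters for a bimodal reporter-intensity population.

    Means and SDs are on the log10-intensity scale; ``weight_high`` is the
    fraction of cells in the high (NRE^hi) component; marker probabilities
    are conditional on the generating component.
    """

    n_cells: int = 5000
    mean_low: float = 1.0
    mean_high: float = 2.5
    sd_low: float = 0.2
    sd_high: float = 0.2
    weight_high: float = 0.3
    p_delta_low: float = 0.84
    p_delta_high: float = 0.10
    p_ph3_low: float = 0.02
    p_ph3_high: float = 0.001
    condition: str = "healthy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ParameterError(f"n_cells must be >= 1, got {self.n_cells}")
        if not (0.0 <= self.weight_high <= 1.0):
            raise ParameterError(f"weight_high must be in [0, 1], got {self.weight_high}")
        for name in ("p_delta_low", "p_delta_high", "p_ph3_low", "p_ph3_high"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1], got {p}")
        if self.sd_low <= 0 or self.sd_high <= 0:
            raise ParameterError("component SDs must be > 0")


#: Healthy-like condition: a minority of cells in the high-Notch mode, and
#: Delta expression strongly anti-correlated with Notch activity.
HEALTHY_POPULATION = PopulationSpec()
#: Injured-like condition: more high-Notch cells, and Delta persisting in the
#: high-Notch mode (feedback disruption).
INJURED_POPULATION = PopulationSpec(
    weight_high=0.5, p_delta_low=0.75, p_delta_high=0.62, condition="injured", seed=1
)


def gen_population(spec: PopulationSpec) -> pd.DataFrame:
    """Draw a marker-flagged single-cell intensity table.

    Returns one row per cell with the pipeline's input schema plus a
    ``true_component`` ground-truth column (0 = low, 1 = high).  All cells
    are esg+ progenitors.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    comp = (rng.random(spec.n_cells) < spec.weight_high).astype(int)
    mu = np.where(comp == 1, spec.mean_high, spec.mean_low)
    sd = np.where(comp == 1, spec.sd_high, spec.sd_low)
    log_intensity = rng.normal(mu, sd)
    p_delta = np.where(comp == 1, spec.p_delta_high, spec.p_delta_low)
    p_ph3 = np.where(comp == 1, spec.p_ph3_high, spec.p_ph3_low)
    return pd.DataFrame(
        {
            "cell_id": [f"{spec.condition}_c{i:05d}" for i in range(spec.n_cells)],
            "gut_id": "synthetic_gut_1",
            "condition": spec.condition,
            "intensity": 10.0**log_intensity,
            "esg_pos": True,
            "delta_pos": rng.random(spec.n_cells) < p_delta,
            "ph3_pos": rng.random(spec.n_cells) < p_ph3,
            "true_component": comp,
        }
    )


@dataclass(frozen=True)
class TimerKinetics:
    """Dual-fluorophore timer constants (hours) and sampling scheme.

    Maturation times and half-lives are converted to first-order rates by
    k = ln2 / t (half-time convention).  ``noise_sd`` is additive Gaussian
    noise on the movie-normalized intensity scale.
    """

    gfp_maturation_h: float = 0.1
    gfp_halflife_h: float = 2.0
    rfp_maturation_h: float = 1.5
    rfp_halflife_h: float = 20.0
    noise_sd: float = 0.02
    sampling_interval_min: float = 7.5
    duration_h: float = 20.5

    def __post_init__(self) -> None:
        for name in (
            "gfp_maturation_h", "gfp_halflife_h", "rfp_maturation_h",
            "rfp_halflife_h", "sampling_interval_min", "duration_h",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    @property
    def sample_times_h(self) -> np.ndarray:
        dt = self.sampling_interval_min / 60.0
        n = int(math.floor(self.duration_h / dt)) + 1
        return np.arange(n) * dt

    def rates(self, channel: str) -> tuple[float, float]:
        """(k_m, k_d) in 1/h for 'gfp' or 'rfp'."""
        if channel == "gfp":
            return math.log(2) / self.gfp_maturation_h, math.log(2) / self.gfp_halflife_h
        if channel == "rfp":
            return math.log(2) / self.rfp_maturation_h, math.log(2) / self.rfp_halflife_h
        raise ParameterError(f"unknown channel {channel!r}")


@dataclass(frozen=True)
class ActivityProfile:
    """Piecewise-linear promoter activity A(t) in [0, 1] over the movie window.

    pattern: up_only (rise, then hold), down_only (hold, then fall),
    up_down (rise, hold, fall), sustained (constant 1).
    onset_h: time the rise starts (up patterns) or the pre-fall hold length
    is measured from 0 (down_only ignores it).
    rise_rate / fall_rate: activity units per hour.
    plateau_h: hold time at 1 between rise completion and fall onset.
    """

    pattern: str = "up_down"
    onset_h: float = 2.0
    rise_rate: float = 0.5
    plateau_h: float = 1.0
    fall_rate: float = 0.4

    def __post_init__(self) -> None:
        if self.pattern not in ("up_only", "down_only", "up_down", "sustained"):
            raise ParameterError(f"unknown pattern {self.pattern!r}")
        if self.rise_rate <= 0 or self.fall_rate <= 0:
            raise ParameterError("rise_rate and fall_rate must be > 0")
        if self.onset_h < 0 or self.plateau_h < 0:
            raise ParameterError("onset_h and plateau_h must be >= 0")

    def activity(self, t: np.ndarray) -> np.ndarray:
        """Vectorized A(t); always clipped to [0, 1]."""
        t = np.asarray(t, dtype=float)
        if self.pattern == "sustained":
            return np.ones_like(t)
        if self.pattern == "down_only":
            fall_start = self.plateau_h
            a = 1.0 - self.fall_rate * (t - fall_start)
            return np.clip(np.where(t < fall_start, 1.0, a), 0.0, 1.0)
        rise = self.rise_rate * (t - self.onset_h)
        a = np.clip(np.where(t < self.onset_h, 0.0, rise), 0.0, 1.0)
        if self.pattern == "up_down":
            fall_start = self.onset_h + 1.0 / self.rise_rate + self.plateau_h
            falling = 1.0 - self.fall_rate * (t - fall_start)
            a = np.where(t >= fall_start, np.clip(falling, 0.0, 1.0), a)
        return a


def mature_steady_state(a: float, maturation_h: float, halflife_h: float) -> float:
    """Analytic mature-fluorophore level under constant activity ``a``."""
    k_m = math.log(2) / maturation_h
    k_d = math.log(2) / halflife_h
    return a * k_m / ((k_m + k_d) * k_d)


def timer_forward(
    profile,
    kinetics: TimerKinetics = TimerKinetics(),
    start_at_steady_state: bool = True,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noiseless (times_h, gfp, rfp) mature-fluorophore series for one cell.

    ``profile`` is an :class:`ActivityProfile` or any callable t -> A(t).
    With ``start_at_steady_state`` the immature/mature pools start at the
    steady state of A(0), so cells already signaling before the movie begins
    (down_only profiles) open at their plateau level.
    """
    if isinstance(profile, ActivityProfile):
        def act(t: float) -> float:
            return float(profile.activity(np.array([t]))[0])
    else:
        def act(t: float) -> float:
            return float(profile(t))

    times = kinetics.sample_times_h
    rates = [kinetics.rates("gfp"), kinetics.rates("rfp")]

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        a = act(t)
        out = np.empty(4)
        for c, (k_m, k_d) in enumerate(rates):
            immature, mature = y[2 * c], y[2 * c + 1]
            out[2 * c] = a - (k_m + k_d) * immature
            out[2 * c + 1] = k_m * immature - k_d * mature
        return out

    a0 = act(0.0)
    y0 = np.zeros(4)
    if start_at_steady_state:
        for c, (k_m, k_d) in enumerate(rates):
            y0[2 * c] = a0 / (k_m + k_d)
            y0[2 * c + 1] = a0 * k_m / ((k_m + k_d) * k_d)
    sol = solve_ivp(
        rhs, (times[0], times[-1]), y0, t_eval=times, method="RK45",
        rtol=rtol, atol=atol, max_step=0.1,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise SolverError(f"timer forward model failed: {sol.message!r}")
    return times, sol.y[1], sol.y[3]


def activity_from_trajectory(traj, cell: int, t_scale_h: float = 2.0):
    """Adapt a circuit-model Notch trajectory into an activity callable.

    Dimensionless simulation time is mapped to hours via ``t_scale_h``
    (hours per dimensionless time unit); Notch levels (already in [0, 1] for
    default parameters) are interpolated and held at their final value beyond
    the simulated window.
    """
    times_h = traj.times * t_scale_h
    notch = np.clip(traj.notch[:, cell], 0.0, 1.0)

    def activity(t):
        return np.interp(np.asarray(t, dtype=float), times_h, notch)

    return activity


@dataclass(frozen=True)
class MoviePreset:
    """Condition-specific activity-rate distributions (per hour)."""

    rise_rate: float
    fall_rate: float
    rate_jitter_sd: float = 0.2  # lognormal sigma on the rates
    onset_range_h: tuple[float, float] = (0.5, 3.0)
    plateau_range_h: tuple[float, float] = (0.5, 2.0)


#: Healthy guts: slow activity rates, so most cells complete at most one
#: signaling phase within the 20.5 h window.  Injured guts: ~2-3x faster
#: rates, so most cells traverse both up- and downregulation.
MOVIE_PRESETS: dict[str, MoviePreset] = {
    "healthy": MoviePreset(rise_rate=0.22, fall_rate=0.18),
    "injured": MoviePreset(rise_rate=0.55, fall_rate=0.42),
}

#: Default per-pattern cell counts reproducing the observed phase-pattern
#: mixes: healthy 8/32 up_down (25%), injured 53/93 up_down (57%).
def default_pattern_counts(preset: str) -> dict[str, int]:
    if preset == "healthy":
        return {"up_only": 13, "down_only": 11, "up_down": 8}
    if preset == "injured":
        return {"up_only": 18, "down_only": 22, "up_down": 53}
    raise ParameterError(f"unknown preset {preset!r}")


def gen_movie(
    counts: dict[str, int] | None = None,
    kinetics: TimerKinetics = TimerKinetics(),
    preset: str = "healthy",
    seed: int = 0,
    movie_id: str | None = None,
    gain: float = 1000.0,
    gain_jitter: float = 0.1,
    max_trim_frames: int = 6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one movie's track table plus its ground truth.

    Each cell draws an activity profile of its assigned pattern from the
    condition preset, runs the timer forward model, is scaled to arbitrary
    raw intensity units with a per-cell gain, truncated by a random number of
    frames (up to ``max_trim_frames`` per side) to mimic cells entering or
    leaving the field, and finally perturbed with additive Gaussian noise of
    SD ``kinetics.noise_sd`` on the movie-normalized scale.  Deterministic
    given ``seed``.

    Returns ``(tracks, truth)``: the pipeline-schema long table and one row
    per cell with pattern and profile parameters.
    """
    if preset not in MOVIE_PRESETS:
        raise ParameterError(f"unknown preset {preset!r}")
    if counts is None:
        counts = default_pattern_counts(preset)
    for pattern, n in counts.items():
        if pattern not in ("up_only", "down_only", "up_down", "sustained"):
            raise ParameterError(f"unknown pattern {pattern!r}")
        if n < 0:
            raise ParameterError(f"negative count for pattern {pattern!r}")
    if sum(counts.values()) == 0:
        raise ParameterError("no cells requested")
    p = MOVIE_PRESETS[preset]
    rng = np.random.default_rng(seed)
    movie_id = movie_id or f"{preset}_movie_{seed}"
    times = kinetics.sample_times_h
    n_frames = times.shape[0]

    cells: list[tuple[str, ActivityProfile, float, int, int]] = []
    truth_rows = []
    for pattern in sorted(counts):
        for k in range(counts[pattern]):
            cell_id = f"{pattern}_{k:03d}"
            profile = ActivityProfile(
                pattern=pattern,
                onset_h=rng.uniform(*p.onset_range_h),
                rise_rate=p.rise_rate * rng.lognormal(0.0, p.rate_jitter_sd),
                plateau_h=rng.uniform(*p.plateau_range_h),
                fall_rate=p.fall_rate * rng.lognormal(0.0, p.rate_jitter_sd),
            )
            cell_gain = gain * rng.uniform(1.0 - gain_jitter, 1.0 + gain_jitter)
            trim_start = int(rng.integers(0, max_trim_frames + 1))
            trim_end = int(rng.integers(0, max_trim_frames + 1))
            cells.append((cell_id, profile, cell_gain, trim_start, trim_end))
            truth_rows.append(
                {
                    "movie_id": movie_id,
                    "cell_id": cell_id,
                    "condition": preset,
                    "pattern": pattern,
                    "onset_h": profile.onset_h,
                    "rise_rate": profile.rise_rate,
                    "plateau_h": profile.plateau_h,
                    "fall_rate": profile.fall_rate,
                    "trim_start": trim_start,
                    "trim_end": trim_end,
                }
            )

    full_traces = {}
    for cell_id, profile, cell_gain, trim_start, trim_end in cells:
        _, gfp, rfp = timer_forward(profile, kinetics)
        full_traces[cell_id] = (cell_gain * gfp, cell_gain * rfp, trim_start, trim_end)

    gfp_max = max(g.max() for g, _, _, _ in full_traces.values())
    rfp_max = max(r.max() for _, r, _, _ in full_traces.values())

    # Cells are tracked from their first appearance until signal loss or the
    # movie's end: the observation window spans the frames where dGFP clears
    # the visibility floor (10% of the movie maximum, the same threshold the
    # QC rules treat as visible signal), with a 2-frame margin on each side.  Pre-onset dark frames and the GFP-dark tail after complete
    # downregulation (a recently Notch-OFF cell, not an analyzable GFP trace)
    # are outside the track.
    rows = []
    for row, (cell_id, profile, cell_gain, trim_start, trim_end) in zip(truth_rows, cells):
        gfp_trace, rfp_trace, _, _ = full_traces[cell_id]
        visible = np.nonzero(gfp_trace > 0.1 * gfp_max)[0]
        det_start = max(0, int(visible[0]) - 2) if visible.size else 0
        det_stop = min(n_frames, int(visible[-1]) + 3) if visible.size else n_frames
        start = min(det_start + trim_start, n_frames - 12)
        stop = max(start + 12, det_stop - trim_end)
        row["start_frame"] = start
        sl = slice(start, stop)
        gfp_trace, rfp_trace = gfp_trace[sl], rfp_trace[sl]
        frames = np.arange(sl.start, sl.stop)
        noisy_gfp = gfp_trace + rng.normal(0.0, kinetics.noise_sd * gfp_max, gfp_trace.shape)
        noisy_rfp = rfp_trace + rng.normal(0.0, kinetics.noise_sd * rfp_max, rfp_trace.shape)
        rows.append(
            pd.DataFrame(
                {
                    "movie_id": movie_id,
                    "cell_id": cell_id,
                    "condition": preset,
                    "frame": frames,
                    "time_min": frames * kinetics.sampling_interval_min,
                    "gfp": np.clip(noisy_gfp, 0.0, None),
                    "rfp": np.clip(noisy_rfp, 0.0, None),
                }
            )
        )
    tracks = pd.concat(rows, ignore_index=True)
    return tracks, pd.DataFrame(truth_rows)
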