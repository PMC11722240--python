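"""Dimensionless Notch-Delta lateral-inhibition circuit for cell pairs and triplets.

The model couples two (or three) cells through trans-activation and
cis-repression Hill functions:

    dN_i/dt = Dbar_i^r / (KN^r + Dbar_i^r) - N_i
    dD_i/dt = v * ( 1 / (1 + (N_i/KD)^h) - D_i )

where ``Dbar_i`` is the Delta input a cell receives from its neighbors (the
single neighbor's Delta for a pair; the arithmetic mean over neighbors for
larger groups).  ``KN`` is the threshold for Notch activation by neighbor
Delta, ``KD`` the threshold for same-cell Delta repression by activated Notch,
and ``v`` the Notch/Delta degradation-rate ratio.  A downstream transcriptional
reporter accumulates as ``beta * integral(N dt)`` (the production-dominated
approximation) or, optionally, with first-order turnover
``dR/dt = beta*N - alpha*R``.

Elevating KD — weakened Delta repression, the injury state — yields cells that
are simultaneously high-Notch and high-Delta and accelerates reporter
accumulation ("signaling speed").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp

from .exceptions import ParameterError, SolverError, TopologyError

__all__ = [
    "CircuitParams",
    "Trajectory",
    "PhaseMap",
    "PAIR_TOPOLOGY",
    "TRIPLET_TOPOLOGY",
    "DEFAULT_PAIR_INIT",
    "DEFAULT_TRIPLET_INIT",
    "derivatives",
    "simulate",
    "simulate_pair",
    "simulate_triplet",
    "reporter_accumulation",
    "high_notch_cell",
    "steady_state_delta",
    "signaling_speed",
    "phase_map",
]

#: Two mutually signaling cells.
PAIR_TOPOLOGY: tuple[tuple[int, ...], ...] = ((1,), (0,))
#: Three mutually connected cells (injury-induced cluster).
TRIPLET_TOPOLOGY: tuple[tuple[int, ...], ...] = ((1, 2), (0, 2), (0, 1))

#: Low-Notch/high-Delta start; cell 2 gets a slight Notch head start
#: (0.011 vs 0.010) to break symmetry.
DEFAULT_PAIR_INIT = (np.array([0.010, 0.011]), np.array([1.0, 1.0]))
DEFAULT_TRIPLET_INIT = (np.array([0.010, 0.010, 0.011]), np.array([1.0, 1.0, 1.0]))


@dataclass(frozen=True)
class CircuitParams:
    """Dimensionless circuit parameters plus reporter constants.

    Parameters
    ----------
    kn : threshold of Notch activation by neighbor Delta (> 0).
    kd : threshold of Delta inhibition by same-cell Notch (> 0).
    v : ratio of Notch to Delta degradation rates (> 0; default 1).
    r, h : Hill coefficients for activation / inhibition (integers >= 1).
    beta : maximal reporter production rate (>= 0; default 1).
    alpha : reporter degradation rate, used only by the ODE reporter mode.
    """

    kn: float
    kd: float
    v: float = 1.0
    r: int = 2
    h: int = 2
    beta: float = 1.0
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if not (self.kn > 0 and self.kd > 0):
            raise ParameterError(f"kn and kd must be > 0, got kn={self.kn}, kd={self.kd}")
        if not self.v > 0:
            raise ParameterError(f"v must be > 0, got {self.v}")
        if self.r < 1 or self.h < 1 or int(self.r) != self.r or int(self.h) != self.h:
            raise ParameterError(f"Hill coefficients must be integers >= 1, got r={self.r}, h={self.h}")
        if self.beta < 0:
            raise ParameterError(f"beta must be >= 0, got {self.beta}")
        if self.alpha < 0:
            raise ParameterError(f"alpha must be >= 0, got {self.alpha}")


@dataclass
class Trajectory:
    """Dense per-cell time series from one simulation.

    ``notch``, ``delta`` and ``reporter`` are arrays of shape
    ``(len(times), n_cells)``.
    """

    times: np.ndarray
    notch: np.ndarray
    delta: np.ndarray
    reporter: np.ndarray
    params: CircuitParams
    topology: tuple[tuple[int, ...], ...]

    @property
    def n_cells(self) -> int:
        return self.notch.shape[1]


@dataclass
class PhaseMap:
    """Metric values on a (kn, kd) grid; ``values[i, j]`` is at ``(kn_values[i], kd_values[j])``."""

    kn_values: np.ndarray
    kd_values: np.ndarray
    values: np.ndarray
    metric: str


def _validate_topology(topology, n_cells: int) -> tuple[tuple[int, ...], ...]:
    topology = tuple(tuple(nb) for nb in topology)
    if len(topology) != n_cells:
        raise TopologyError(f"topology has {len(topology)} entries for {n_cells} cells")
    for i, nb in enumerate(topology):
        if len(nb) == 0:
            raise TopologyError(f"cell {i} has no neighbors")
        if any(j < 0 or j >= n_cells or j == i for j in nb):
            raise TopologyError(f"cell {i} has an invalid neighbor set {nb}")
    return topology


def _neighbor_reduce(neighbor_input: str):
    if neighbor_input == "mean":
        return np.mean
    if neighbor_input == "sum":
        return np.sum
    raise ParameterError(f"neighbor_input must be 'mean' or 'sum', got {neighbor_input!r}")


def derivatives(
    notch: np.ndarray,
    delta: np.ndarray,
    params: CircuitParams,
    topology: tuple[tuple[int, ...], ...] = PAIR_TOPOLOGY,
    neighbor_input: str = "mean",
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives (dN/dt, dD/dt) for every cell.

    The neighbor Delta input defaults to the arithmetic mean of the
    neighbors' Delta levels, which reduces to the partner's Delta for a pair
    and keeps Dbar on the same [0, 1] scale for larger groups; pass
    ``neighbor_input='sum'`` for additive ligand pooling.
    """
    reduce = _neighbor_reduce(neighbor_input)
    notch = np.asarray(notch, dtype=float)
    delta = np.asarray(delta, dtype=float)
    topology = _validate_topology(topology, notch.shape[0])
    dbar = np.array([reduce(delta[list(nb)]) for nb in topology])
    activation = dbar**params.r / (params.kn**params.r + dbar**params.r)
    dn = activation - notch
    dd = params.v * (1.0 / (1.0 + (notch / params.kd) ** params.h) - delta)
    return dn, dd


def simulate(
    params: CircuitParams,
    init_notch: np.ndarray,
    init_delta: np.ndarray,
    topology: tuple[tuple[int, ...], ...],
    t_end: float = 10.0,
    dt_out: float = 0.01,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    reporter_mode: str = "integral",
    neighbor_input: str = "mean",
) -> Trajectory:
    """Integrate the circuit on [0, t_end] with adaptive Runge-Kutta.

    ``reporter_mode='integral'`` computes the reporter as
    ``beta * cumulative integral of N`` on the output grid (the default,
    production-dominated approximation); ``'ode'`` co-integrates
    ``dR/dt = beta*N - alpha*R``.
    """
    if t_end <= 0:
        raise ParameterError(f"t_end must be > 0, got {t_end}")
    if reporter_mode not in ("integral", "ode"):
        raise ParameterError(f"unknown reporter_mode {reporter_mode!r}")
    reduce = _neighbor_reduce(neighbor_input)
    init_notch = np.asarray(init_notch, dtype=float)
    init_delta = np.asarray(init_delta, dtype=float)
    n_cells = init_notch.shape[0]
    if init_delta.shape[0] != n_cells:
        raise ParameterError("init_notch and init_delta must have the same length")
    if np.any(init_notch < 0) or np.any(init_delta < 0):
        raise ParameterError("initial Notch and Delta levels must be >= 0")
    topology = _validate_topology(topology, n_cells)
    neighbor_idx = [list(nb) for nb in topology]

    with_reporter = reporter_mode == "ode"

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        notch = y[:n_cells]
        delta = y[n_cells : 2 * n_cells]
        dbar = np.array([reduce(delta[nb]) for nb in neighbor_idx])
        activation = dbar**params.r / (params.kn**params.r + dbar**params.r)
        dn = activation - notch
        dd = params.v * (1.0 / (1.0 + (notch / params.kd) ** params.h) - delta)
        if with_reporter:
            rep = y[2 * n_cells :]
            dr = params.beta * notch - params.alpha * rep
            return np.concatenate([dn, dd, dr])
        return np.concatenate([dn, dd])

    y0 = np.concatenate([init_notch, init_delta] + ([np.zeros(n_cells)] if with_reporter else []))
    times = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    times[-1] = min(times[-1], t_end)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="RK45", t_eval=times, rtol=rtol, atol=atol)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise SolverError(
            f"integration failed for params={params}: {sol.message!r}, "
            f"finite={np.all(np.isfinite(sol.y))}"
        )
    notch = sol.y[:n_cells].T
    delta = sol.y[n_cells : 2 * n_cells].T
    if with_reporter:
        reporter = sol.y[2 * n_cells :].T
    else:
        reporter = reporter_accumulation(sol.t, notch, beta=params.beta)
    return Trajectory(sol.t, notch, delta, reporter, params, topology)


def simulate_pair(
    params: CircuitParams,
    init_notch: np.ndarray | None = None,
    init_delta: np.ndarray | None = None,
    t_end: float = 10.0,
    **solver_options,
) -> Trajectory:
    """Two mutually signaling cells; defaults N=(0.010, 0.011), D=(1, 1)."""
    if init_notch is None:
        init_notch = DEFAULT_PAIR_INIT[0]
    if init_delta is None:
        init_delta = DEFAULT_PAIR_INIT[1]
    return simulate(params, init_notch, init_delta, PAIR_TOPOLOGY, t_end=t_end, **solver_options)


def simulate_triplet(
    params: CircuitParams,
    init_notch: np.ndarray | None = None,
    init_delta: np.ndarray | None = None,
    t_end: float = 10.0,
    topology: tuple[tuple[int, ...], ...] = TRIPLET_TOPOLOGY,
    **solver_options,
) -> Trajectory:
    """Three mutually connected cells; the last cell's Notch starts slightly higher."""
    if init_notch is None:
        init_notch = DEFAULT_TRIPLET_INIT[0]
    if init_delta is None:
        init_delta = DEFAULT_TRIPLET_INIT[1]
    return simulate(params, init_notch, init_delta, topology, t_end=t_end, **solver_options)


def reporter_accumulation(
    times: np.ndarray | Trajectory, notch: np.ndarray | None = None, beta: float = 1.0
) -> np.ndarray:
    """Reporter_i(t) = beta * cumulative trapezoidal integral of N_i from 0 to t.

    Accepts either a :class:`Trajectory` or explicit ``(times, notch)`` arrays.
    """
    if isinstance(times, Trajectory):
        traj = times
        times, notch = traj.times, traj.notch
    if beta < 0:
        raise ParameterError(f"beta must be >= 0, got {beta}")
    times = np.asarray(times, dtype=float)
    notch = np.asarray(notch, dtype=float)
    if times.shape[0] < 2:
        raise ParameterError("need at least 2 time points to accumulate the reporter")
    return beta * cumulative_trapezoid(notch, times, axis=0, initial=0.0)


def high_notch_cell(traj: Trajectory) -> int:
    """Index of the cell with the largest Notch at t_end (ties: lowest index)."""
    return int(np.argmax(traj.notch[-1]))


def steady_state_delta(params: CircuitParams, t_end: float = 10.0, **solver_options) -> float:
    """Delta level of the high-Notch cell at t_end in a default pair simulation."""
    traj = simulate_pair(params, t_end=t_end, **solver_options)
    return float(traj.delta[-1, high_notch_cell(traj)])


def signaling_speed(
    params: CircuitParams,
    t_start: float = 4.0,
    t_stop: float = 10.0,
    **solver_options,
) -> float:
    """Mean reporter accumulation rate of the high-Notch cell over [t_start, t_stop].

    The reporter uses beta = 1 regardless of ``params.beta`` so speeds are
    comparable across parameter sets; values at the window bounds come from
    linear interpolation on the dense output grid.
    """
    traj = simulate_pair(params, t_end=max(t_stop, 10.0), **solver_options)
    cell = high_notch_cell(traj)
    rep = reporter_accumulation(traj.times, traj.notch[:, [cell]], beta=1.0)[:, 0]
    r_start = float(np.interp(t_start, traj.times, rep))
    r_stop = float(np.interp(t_stop, traj.times, rep))
    return (r_stop - r_start) / (t_stop - t_start)


_METRICS = {"steady_state_delta": steady_state_delta, "signaling_speed": signaling_speed}

#: Default sweep ranges: KN log-spaced over [0.1, 10], KD linear over [0.1, 2].
DEFAULT_KN_GRID = np.logspace(-1, 1, 21)
DEFAULT_KD_GRID = np.linspace(0.1, 2.0, 20)


def phase_map(
    kn_values: np.ndarray | None = None,
    kd_values: np.ndarray | None = None,
    metric: str = "steady_state_delta",
    base_params: CircuitParams | None = None,
    **solver_options,
) -> PhaseMap:
    """Evaluate a scalar circuit metric over a (kn, kd) grid."""
    if metric not in _METRICS:
        raise ParameterError(f"metric must be one of {sorted(_METRICS)}, got {metric!r}")
    kn_values = DEFAULT_KN_GRID if kn_values is None else np.asarray(kn_values, dtype=float)
    kd_values = DEFAULT_KD_GRID if kd_values is None else np.asarray(kd_values, dtype=float)
    if kn_values.size == 0 or kd_values.size == 0 or np.any(kn_values <= 0) or np.any(kd_values <= 0):
        raise ParameterError("kn and kd grids must be non-empty and strictly positive")
    fn = _METRICS[metric]
    values = np.empty((kn_values.size, kd_values.size))
    for i, kn in enumerate(kn_values):
        for j, kd in enumerate(kd_values):
            if base_params is None:
                p = CircuitParams(kn=kn, kd=kd)
            else:
                p = CircuitParams(
                    kn=kn, kd=kd, v=base_params.v, r=base_params.r, h=base_params.h,
                    beta=base_params.beta, alpha=base_params.alpha,
                )
            try:
                values[i, j] = fn(p, **solver_options)
            except SolverError as exc:  # pragma: no cover - defensive
                raise SolverError(f"phase map failed at kn={kn}, kd={kd}") from exc
    if not np.all(np.isfinite(values)):
        raise SolverError("phase map produced non-finite entries")
    return PhaseMap(kn_values, kd_values, values, metric)
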