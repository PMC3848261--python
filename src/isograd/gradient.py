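"""Piecewise-linear gradient programs and the gradient elution integral.

A gradient program is a piecewise-linear eluent concentration profile c(t)
over a fixed time horizon (30 min by default) followed by an indefinite
isocratic hold at the terminal concentration.  The gradient retention time
of an analyte follows from the integral elution equation

    t0 = integral_0^(tR - t0) dt / k[c(t)],

solved by marching in small time steps: within each step k is taken
constant at the average of its values at the step boundaries, and the sum
S = sum(dt / k_bar) is accumulated until it reaches the void time t0.  The
crossing is located by linear interpolation inside the final step, and the
retention time is t0 plus the crossing time.  Because the post-horizon
eluent is constant, any analyte still on the column at the horizon is
finished in closed form (remaining time = (t0 - S_horizon) * k_hold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InconsistentModelError, NoElutionError
from .retention import CalibrationSet, IsocraticRetentionModel

DEFAULT_BOUNDS = (5.0, 95.0)
DEFAULT_HORIZON = 30.0
DEFAULT_DT = 0.01
DEFAULT_CAP_FACTOR = 10.0

_BOUND_EPS = 1e-9


# ---------------------------------------------------------------------------
# gradient profiles
# ---------------------------------------------------------------------------

@dataclass
class GradientProfile:
    """Piecewise-linear eluent program with terminal isocratic hold.

    ``node_times`` start at 0 and increase strictly; the last node defines
    the horizon.  Concentrations must stay within ``bounds`` (mM); pass
    wider bounds explicitly for out-of-domain work such as 2 mM isocratic
    back-prediction.
    """

    node_times: np.ndarray
    node_concentrations: np.ndarray
    bounds: tuple[float, float] = DEFAULT_BOUNDS

    def __post_init__(self):
        self.node_times = np.asarray(self.node_times, dtype=float)
        self.node_concentrations = np.asarray(self.node_concentrations, dtype=float)
        if self.node_times.ndim != 1 or self.node_times.size < 2:
            raise DomainError("a profile needs at least two nodes")
        if self.node_times.size != self.node_concentrations.size:
            raise DomainError("node_times and node_concentrations differ in length")
        if self.node_times[0] != 0.0:
            raise DomainError("the first node must be at t = 0")
        if not np.all(np.diff(self.node_times) > 0):
            raise DomainError("node times must be strictly increasing")
        lo, hi = self.bounds
        if np.any(self.node_concentrations < lo - _BOUND_EPS) or np.any(
            self.node_concentrations > hi + _BOUND_EPS
        ):
            raise DomainError(
                f"node concentrations must lie within bounds [{lo}, {hi}] mM"
            )

    @property
    def horizon(self) -> float:
        return float(self.node_times[-1])

    @property
    def hold_concentration(self) -> float:
        return float(self.node_concentrations[-1])

    @classmethod
    def constant(
        cls,
        concentration: float,
        horizon: float = DEFAULT_HORIZON,
        bounds: tuple[float, float] = DEFAULT_BOUNDS,
    ) -> "GradientProfile":
        """Isocratic program: constant concentration over the horizon."""
        return cls(
            np.array([0.0, horizon]),
            np.array([concentration, concentration], dtype=float),
            bounds,
        )


def concentration_at(profile: GradientProfile, t):
    """Eluent concentration (mM) at time ``t`` (min) from injection.

    Linear interpolation between nodes; the hold concentration after the
    horizon.  Accepts scalars or arrays.
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise DomainError("time must be non-negative")
    out = np.interp(arr, profile.node_times, profile.node_concentrations)
    return float(out) if arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# the stepwise integral solver
# ---------------------------------------------------------------------------

def _time_grid(horizon: float, dt: float) -> tuple[np.ndarray, float]:
    """Uniform grid on [0, horizon] with step as close to dt as divides evenly."""
    if not dt > 0:
        raise DomainError("dt must be positive")
    n_steps = max(1, int(math.ceil(horizon / dt - 1e-9)))
    return np.linspace(0.0, horizon, n_steps + 1), horizon / n_steps


def march_retention_times(
    k_grid: np.ndarray,
    void_time: float,
    dt: float,
    cap_time: float,
) -> np.ndarray:
    """Vectorized stepwise solution of the elution integral.

    Parameters
    ----------
    k_grid
        (Q, N) retention factors sampled on the uniform time grid
        0, dt, ..., (N-1)*dt covering the gradient horizon; row ``q`` is one
        (analyte-marker, profile) combination.  The final column doubles as
        the hold-phase retention factor.
    void_time, dt
        Column hold-up time and integration step, minutes.
    cap_time
        Crossings later than this (minutes after injection, measured on the
        c(t) clock) are reported as ``inf`` (no elution).

    Returns
    -------
    (Q,) retention times in minutes (``inf`` where the analyte does not
    elute before ``cap_time``).
    """
    k = np.atleast_2d(np.asarray(k_grid, dtype=float))
    q, n = k.shape
    incr = (2.0 * dt) / (k[:, :-1] + k[:, 1:])  # dt / k_bar per step
    s = np.cumsum(incr, axis=1)
    horizon = (n - 1) * dt
    reached = s[:, -1] >= void_time
    idx = np.argmax(s >= void_time, axis=1)
    rows = np.arange(q)
    s_prev = np.where(idx > 0, s[rows, np.maximum(idx - 1, 0)], 0.0)
    frac = (void_time - s_prev) / incr[rows, idx]
    t_cross = (idx + frac) * dt
    # isocratic hold beyond the horizon: exact closed form
    t_hold = horizon + (void_time - s[:, -1]) * k[:, -1]
    t_cross = np.where(reached, t_cross, t_hold)
    times = void_time + t_cross
    return np.where(t_cross > cap_time, np.inf, times)


def gradient_retention_time(
    model: IsocraticRetentionModel,
    profile: GradientProfile,
    void_time: float,
    dt: float = DEFAULT_DT,
    cap_factor: float = DEFAULT_CAP_FACTOR,
) -> float:
    """Retention time (min) of one marker model under a gradient program."""
    if not void_time > 0:
        raise DomainError("void_time must be positive")
    t_grid, dt_eff = _time_grid(profile.horizon, dt)
    c_grid = concentration_at(profile, t_grid)
    L = np.log10(c_grid)
    k = 10.0 ** (model.a0 + model.a1 * L + model.a2 * L * L)
    time = march_retention_times(
        k[None, :], void_time, dt_eff, cap_factor * profile.horizon
    )[0]
    if not np.isfinite(time):
        raise NoElutionError(
            f"no elution within {cap_factor:g}x the {profile.horizon:g}-min horizon"
        )
    return float(time)


def batch_marker_times(
    calibration: CalibrationSet,
    profile: GradientProfile,
    dt: float = DEFAULT_DT,
    cap_factor: float = DEFAULT_CAP_FACTOR,
) -> np.ndarray:
    """(n_analytes, 3) fronting/apex/tailing retention times for one profile."""
    t_grid, dt_eff = _time_grid(profile.horizon, dt)
    c_grid = concentration_at(profile, t_grid)
    coefs = calibration.coefficient_matrix()
    L = np.log10(c_grid)
    K = coefs[:, [0]] + coefs[:, [1]] * L + coefs[:, [2]] * (L * L)
    times = march_retention_times(
        10.0 ** K, calibration.void_time, dt_eff, cap_factor * profile.horizon
    )
    return times.reshape(len(calibration.analytes), 3)


# ---------------------------------------------------------------------------
# peak prediction
# ---------------------------------------------------------------------------

@dataclass
class PeakPrediction:
    """Predicted marker times and width for one analyte under one profile."""

    analyte: str
    t_front: float
    t_apex: float
    t_tail: float
    width_half: float = field(init=False)
    stretching_factor: float = math.nan

    def __post_init__(self):
        self.width_half = self.t_tail - self.t_front


def predict_peaks(
    calibration: CalibrationSet,
    profile: GradientProfile,
    dt: float = DEFAULT_DT,
    cap_factor: float = DEFAULT_CAP_FACTOR,
) -> list[PeakPrediction]:
    """Predict all analyte peaks under a gradient program.

    Runs the elution integral for the fronting, apex, and tailing models of
    every analyte, attaches the stretching factor (peak area interpolated
    from the analyte's area table at the eluent concentration present when
    the apex elutes), and returns the peaks sorted by apex time.
    """
    from .peakshape import area_at_concentration

    times = batch_marker_times(calibration, profile, dt, cap_factor)
    peaks = []
    for analyte, (tf, ta, tt) in zip(calibration.analytes, times):
        if not np.all(np.isfinite([tf, ta, tt])):
            raise NoElutionError(
                f"{analyte.name}: no elution within {cap_factor:g}x horizon"
            )
        if not (tf < ta < tt):
            raise InconsistentModelError(
                f"{analyte.name}: predicted marker times violate "
                f"fronting < apex < tailing ({tf:.4f}, {ta:.4f}, {tt:.4f})"
            )
        if analyte.area_table and len(analyte.area_table) >= 2:
            c_elution = concentration_at(profile, min(ta, profile.horizon))
            sf = area_at_concentration(analyte.area_table, c_elution)
        else:
            sf = math.nan
        peaks.append(PeakPrediction(analyte.name, tf, ta, tt, stretching_factor=sf))
    peaks.sort(key=lambda p: p.t_apex)
    return peaks
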