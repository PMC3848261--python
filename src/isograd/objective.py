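"""Scoring of gradient programs: resolutions, criterion function, feasibility.

The separation quality of two adjacent peaks is the half-height resolution

    Rs = 1.18 * (t_apex2 - t_apex1) / (w_half1 + w_half2),

and a whole gradient program is condensed into the criterion function

    CF = (1 / sum(Rs))**alpha * t_A**beta,

which both optimizers minimize: larger total resolution and a shorter
analysis time t_A (the apex time of the last-eluting analyte) both lower
CF.  Programs whose last analyte elutes after the acceptance horizon — or, when
the scorer carries an overlap threshold, whose adjacent-pair resolutions
fall below it — are infeasible and carry an infinite CF sentinel so
population and simplex bookkeeping stay fixed-size.  For optimizer use the
batch scorer additionally reports a graded penalty value (any feasible
candidate beats every infeasible one; infeasible candidates rank by the
size of their constraint violation) so a search can climb out of an
infeasible region instead of stalling on a flat infinite plateau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InvalidPeakError
from .gradient import (
    DEFAULT_CAP_FACTOR,
    DEFAULT_DT,
    DEFAULT_HORIZON,
    GradientProfile,
    PeakPrediction,
    _time_grid,
    concentration_at,
    march_retention_times,
    predict_peaks,
)
from .retention import CalibrationSet

RS_THRESHOLD = 3.0


@dataclass
class CFWeights:
    """Integer exponents of the criterion function (alpha on 1/sum(Rs),
    beta on the analysis time)."""

    alpha: int = 1
    beta: int = 2

    def __post_init__(self):
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise DomainError(f"{name} must be a positive integer")
            setattr(self, name, int(v))


@dataclass
class ScoredProfile:
    """Full valuation of one gradient program."""

    profile: GradientProfile
    peaks: list[PeakPrediction]
    resolutions: list[float]
    sum_rs: float
    t_analysis: float
    cf: float
    feasible: bool


@dataclass
class OptimizationResult:
    """Outcome of one optimizer run."""

    profile: GradientProfile
    cf: float
    scored: ScoredProfile | None
    history: list[float] = field(default_factory=list)
    n_iterations: int = 0


# ---------------------------------------------------------------------------
# elementary scores
# ---------------------------------------------------------------------------

def resolution(peak1: PeakPrediction, peak2: PeakPrediction) -> float:
    """Half-height resolution of two peaks (operands auto-ordered by apex)."""
    if peak2.t_apex < peak1.t_apex:
        peak1, peak2 = peak2, peak1
    if peak1.width_half <= 0 or peak2.width_half <= 0:
        raise InvalidPeakError("peak half-height widths must be positive")
    return 1.18 * (peak2.t_apex - peak1.t_apex) / (
        peak1.width_half + peak2.width_half
    )


def criterion_value(sum_rs: float, t_analysis: float, weights: CFWeights) -> float:
    """CF = (1/sum_rs)**alpha * t_analysis**beta; +inf when sum_rs <= 0."""
    if not t_analysis > 0:
        raise DomainError("t_analysis must be positive")
    if sum_rs <= 0:
        return math.inf
    return (1.0 / sum_rs) ** weights.alpha * t_analysis ** weights.beta


def is_well_separated(scored: ScoredProfile, rs_threshold: float = RS_THRESHOLD) -> bool:
    """True when every adjacent-pair resolution meets the overlap threshold."""
    return all(rs >= rs_threshold for rs in scored.resolutions)


# ---------------------------------------------------------------------------
# batched scorer (used by both optimizers)
# ---------------------------------------------------------------------------

@dataclass
class BatchScores:
    """Vectorized valuation of many candidate programs sharing node times."""

    cf: np.ndarray             # (P,) criterion value; +inf where infeasible
    t_last: np.ndarray         # (P,) apex of last-eluting analyte
    sum_rs: np.ndarray         # (P,)
    resolutions: np.ndarray    # (P, n_analytes - 1), elution order
    order: np.ndarray          # (P, n_analytes) analyte indices by elution
    feasible: np.ndarray       # (P,) bool
    penalized: np.ndarray = None  # (P,) cf where feasible, graded penalty else


# any feasible candidate outranks every infeasible one under the penalty
_PENALTY_BASE = 1e9
_PENALTY_INVALID = 1e12


class GradientScorer:
    """Evaluates the criterion function for batches of gradient programs.

    All candidates in a batch share their node times (the optimizers vary
    only the node concentrations), so the retention models of every analyte
    and marker are integrated together in one vectorized march.

    ``rs_threshold`` enables the peak-overlap acceptability rule: candidates
    with any adjacent-pair resolution below the threshold are excluded
    (infeasible) just like candidates eluting past the horizon.  The
    optimizers use threshold 3 by default; plain scoring leaves it off.
    """

    def __init__(
        self,
        calibration: CalibrationSet,
        weights: CFWeights | None = None,
        horizon: float = DEFAULT_HORIZON,
        dt: float = DEFAULT_DT,
        cap_factor: float = DEFAULT_CAP_FACTOR,
        bounds: tuple[float, float] = (5.0, 95.0),
        rs_threshold: float | None = None,
    ):
        self.calibration = calibration
        self.weights = weights or CFWeights()
        self.horizon = float(horizon)
        self.cap_time = cap_factor * self.horizon
        self.bounds = bounds
        self.rs_threshold = rs_threshold
        self.t_grid, self.dt = _time_grid(self.horizon, dt)
        coefs = calibration.coefficient_matrix()  # (3A, 3)
        self._a0 = coefs[:, 0][None, :, None]
        self._a1 = coefs[:, 1][None, :, None]
        self._a2 = coefs[:, 2][None, :, None]
        self.n_analytes = len(calibration.analytes)

    def marker_times(self, node_times: np.ndarray, conc_matrix: np.ndarray) -> np.ndarray:
        """(P, n_analytes, 3) marker retention times for P candidates."""
        conc = np.atleast_2d(np.asarray(conc_matrix, dtype=float))
        p = conc.shape[0]
        c_grids = np.empty((p, self.t_grid.size))
        for i in range(p):
            c_grids[i] = np.interp(self.t_grid, node_times, conc[i])
        L = np.log10(c_grids)[:, None, :]
        K = self._a0 + self._a1 * L + self._a2 * (L * L)
        k = 10.0 ** K
        times = march_retention_times(
            k.reshape(-1, self.t_grid.size),
            self.calibration.void_time,
            self.dt,
            self.cap_time,
        )
        return times.reshape(p, self.n_analytes, 3)

    def score_batch(self, node_times: np.ndarray, conc_matrix: np.ndarray) -> BatchScores:
        times = self.marker_times(node_times, conc_matrix)
        front, apex, tail = times[..., 0], times[..., 1], times[..., 2]
        with np.errstate(invalid="ignore"):
            ok = (
                np.all(np.isfinite(times), axis=(1, 2))
                & np.all(front < apex, axis=1)
                & np.all(apex < tail, axis=1)
            )
        width = tail - front
        order = np.argsort(apex, axis=1, kind="stable")
        apex_s = np.take_along_axis(apex, order, axis=1)
        width_s = np.take_along_axis(width, order, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            res = 1.18 * np.diff(apex_s, axis=1) / (width_s[:, 1:] + width_s[:, :-1])
        sum_rs = np.where(ok, np.nansum(np.where(ok[:, None], res, 0.0), axis=1), 0.0)
        t_last = np.where(ok, apex_s[:, -1], np.inf)
        feasible = ok & (t_last <= self.horizon) & (sum_rs > 0)
        if self.rs_threshold is not None:
            with np.errstate(invalid="ignore"):
                separated = np.all(
                    np.where(ok[:, None], res, -np.inf) >= self.rs_threshold, axis=1
                )
            feasible &= separated
        alpha, beta = self.weights.alpha, self.weights.beta
        with np.errstate(invalid="ignore", divide="ignore"):
            cf = np.where(
                feasible,
                (1.0 / np.where(sum_rs > 0, sum_rs, 1.0)) ** alpha
                * np.where(np.isfinite(t_last), t_last, 1.0) ** beta,
                np.inf,
            )
        # graded penalty: feasible candidates keep their CF; infeasible ones
        # rank by violation size, always behind every feasible one
        violation = np.zeros(len(feasible))
        if self.rs_threshold is not None:
            with np.errstate(invalid="ignore"):
                shortfall = np.clip(self.rs_threshold - res, 0.0, None)
            violation += np.nansum(np.where(ok[:, None], shortfall, 0.0), axis=1)
        with np.errstate(invalid="ignore"):
            violation += np.clip(
                np.where(ok, t_last, 0.0) - self.horizon, 0.0, None
            )
        penalized = np.where(feasible, cf, _PENALTY_BASE + violation)
        penalized = np.where(ok, penalized, _PENALTY_INVALID)
        return BatchScores(cf, t_last, sum_rs, res, order, feasible, penalized)

    def score(self, profile: GradientProfile) -> ScoredProfile:
        """Full single-profile valuation with peak objects attached."""
        peaks = predict_peaks(
            self.calibration, profile, self.dt, self.cap_time / self.horizon
        )
        resolutions = [
            resolution(peaks[i], peaks[i + 1]) for i in range(len(peaks) - 1)
        ]
        sum_rs = float(sum(resolutions))
        t_analysis = peaks[-1].t_apex
        feasible = t_analysis <= self.horizon
        if self.rs_threshold is not None:
            feasible = feasible and all(
                rs >= self.rs_threshold for rs in resolutions
            )
        cf = (
            criterion_value(sum_rs, t_analysis, self.weights)
            if feasible
            else math.inf
        )
        return ScoredProfile(
            profile, peaks, resolutions, sum_rs, t_analysis, cf, feasible
        )


def score_profile(
    calibration: CalibrationSet,
    profile: GradientProfile,
    weights: CFWeights | None = None,
    horizon: float = DEFAULT_HORIZON,
    dt: float = DEFAULT_DT,
) -> ScoredProfile:
    """Score one gradient program (convenience wrapper over GradientScorer)."""
    scorer = GradientScorer(calibration, weights, horizon=horizon, dt=dt)
    return scorer.score(profile)
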