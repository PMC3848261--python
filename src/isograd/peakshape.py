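"""Peak-shape description with the generalized logistic distribution.

Predicted peaks are drawn as scaled generalized logistic densities

    f(t) = (C / B) * exp((A - t) / B) / (1 + exp((A - t) / B))**(C + 1),

where A locates the peak, B > 0 sets its width and C > 0 its skewness
(C = 1 recovers the symmetric logistic).  The density is unimodal with mode
at A + B*ln C and integrates to one, so a detector trace is h(t) = SF*f(t)
with the stretching factor SF equal to the peak area.

Three predicted times per peak (50%-height fronting, apex, 50%-height
tailing) determine (A, B, C):

* the asymmetry ratio (t_tail - t_apex)/(t_apex - t_front) depends on C
  alone and is solved by root bracketing on log C;
* B scales the solved unit-width half-height span onto the requested one;
* A follows from the mode condition t_apex = A + B*ln C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, InsufficientDataError, NoSolutionError

if TYPE_CHECKING:  # pragma: no cover
    from .gradient import PeakPrediction

_LOG_C_BRACKET = (math.log(1e-3), math.log(1e3))


@dataclass
class GLDParams:
    """Location (A, min), width (B, min) and skewness (C) of one peak."""

    A: float
    B: float
    C: float

    def __post_init__(self):
        if not self.B > 0:
            raise DomainError("B must be positive")
        if not self.C > 0:
            raise DomainError("C must be positive")

    @property
    def mode(self) -> float:
        return self.A + self.B * math.log(self.C)


@dataclass
class ChromatogramTrace:
    """Summed detector trace of all predicted peaks on a uniform time grid."""

    times: np.ndarray
    intensities: np.ndarray

    def integral(self) -> float:
        return float(np.trapezoid(self.intensities, self.times))


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------

def gld_density(params: GLDParams, t):
    """Generalized logistic density at time ``t`` (1/min).

    Evaluated in log space so far tails (|A - t|/B of several hundred)
    underflow gracefully to zero instead of overflowing.
    """
    z = (params.A - np.asarray(t, dtype=float)) / params.B
    logf = (
        math.log(params.C / params.B)
        + z
        - (params.C + 1.0) * np.logaddexp(0.0, z)
    )
    out = np.exp(logf)
    return float(out) if out.ndim == 0 else out


def _log_density_unit(t, C: float):
    """log f(t) for A = 0, B = 1."""
    z = -np.asarray(t, dtype=float)
    return math.log(C) + z - (C + 1.0) * np.logaddexp(0.0, z)


def _half_height_offsets(C: float) -> tuple[float, float]:
    """Distances from the mode to the 50%-height crossings, for A=0, B=1.

    Returns (mode - t_front, t_tail - mode); both positive.
    """
    mode = math.log(C)
    log_half = float(_log_density_unit(mode, C)) - math.log(2.0)

    def g(t):
        return float(_log_density_unit(t, C)) - log_half

    # g(mode) = ln 2 > 0; g -> -inf on both sides: expand until bracketed
    step = 1.0
    while g(mode - step) > 0:
        step *= 2.0
    t_front = brentq(g, mode - step, mode, xtol=1e-13)
    step = 1.0
    while g(mode + step) > 0:
        step *= 2.0
    t_tail = brentq(g, mode, mode + step, xtol=1e-13)
    return mode - t_front, t_tail - mode


def solve_gld_params(t_front: float, t_apex: float, t_tail: float) -> GLDParams:
    """Recover (A, B, C) from the apex and the two 50%-height times.

    The solved density has its mode at ``t_apex`` and equals half the modal
    height at ``t_front`` and ``t_tail``.
    """
    if not (t_front < t_apex < t_tail):
        raise DomainError("times must satisfy t_front < t_apex < t_tail")
    ratio = (t_tail - t_apex) / (t_apex - t_front)

    def h(x):
        d_front, d_tail = _half_height_offsets(math.exp(x))
        return d_tail / d_front - ratio

    lo, hi = _LOG_C_BRACKET
    h_lo, h_hi = h(lo), h(hi)
    if h_lo == 0.0:
        x = lo
    elif h_hi == 0.0:
        x = hi
    elif h_lo * h_hi > 0:
        raise NoSolutionError(
            f"asymmetry ratio {ratio:.4g} outside the solvable skewness range"
        )
    else:
        x = brentq(h, lo, hi, xtol=1e-13)
    C = math.exp(x)
    d_front, d_tail = _half_height_offsets(C)
    B = (t_tail - t_front) / (d_front + d_tail)
    A = t_apex - B * math.log(C)
    return GLDParams(A, B, C)


# ---------------------------------------------------------------------------
# stretching factor (peak area) lookup
# ---------------------------------------------------------------------------

def area_at_concentration(
    area_table: Sequence[tuple[float, float]], c_at_elution: float
) -> float:
    """Peak area at the eluent concentration present when the peak elutes.

    Linear interpolation between the bracketing rows of the isocratic
    area-vs-concentration table; clamped to the endpoint values outside the
    tabulated range.
    """
    table = np.asarray(area_table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2:
        raise InsufficientDataError(
            "area table needs at least two (concentration, area) rows"
        )
    if not np.all(np.diff(table[:, 0]) > 0):
        raise DomainError("area table concentrations must be strictly increasing")
    return float(np.interp(c_at_elution, table[:, 0], table[:, 1]))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

# half-height offset of the symmetric (C=1) logistic with B=1
_LOGISTIC_HALF_OFFSET = math.log(3.0 + 2.0 * math.sqrt(2.0))


def _symmetric_fallback(t_front: float, t_apex: float, t_tail: float) -> GLDParams:
    """Symmetric logistic matched to the apex and the total half-height width.

    Used for peaks whose tailing asymmetry exceeds what the generalized
    logistic can represent (the half-width ratio saturates near 1.48 as the
    skewness parameter grows)."""
    B = (t_tail - t_front) / (2.0 * _LOGISTIC_HALF_OFFSET)
    return GLDParams(t_apex, B, 1.0)


def render_chromatogram(
    peaks: "Sequence[PeakPrediction]",
    grid_step: float = 0.01,
    horizon: float = 35.0,
    skew_fallback: bool = False,
) -> ChromatogramTrace:
    """Sum the scaled peak densities of all predicted peaks on a uniform grid.

    Peaks without a finite stretching factor are drawn with unit area.  With
    ``skew_fallback`` peaks too asymmetric for the generalized logistic are
    drawn as width-matched symmetric logistics instead of raising.
    """
    if not peaks:
        raise DomainError("no peaks to render")
    if not grid_step > 0:
        raise DomainError("grid_step must be positive")
    times = np.arange(0.0, horizon + grid_step / 2, grid_step)
    intensities = np.zeros_like(times)
    for peak in peaks:
        try:
            params = solve_gld_params(peak.t_front, peak.t_apex, peak.t_tail)
        except NoSolutionError:
            if not skew_fallback:
                raise NoSolutionError(
                    f"{peak.analyte}: asymmetry outside the representable "
                    "skewness range (pass skew_fallback=True to draw it "
                    "as a symmetric logistic)"
                ) from None
            params = _symmetric_fallback(peak.t_front, peak.t_apex, peak.t_tail)
        except DomainError as exc:
            raise type(exc)(f"{peak.analyte}: {exc}") from exc
        sf = peak.stretching_factor
        if not math.isfinite(sf):
            sf = 1.0
        intensities += sf * gld_density(params, times)
    return ChromatogramTrace(times, intensities)
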