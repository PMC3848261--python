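"""Nelder-Mead simplex search over gradient node concentrations.

The search space is the vector of eluent concentrations at NF equidistant
time nodes spanning the 30-min horizon (a single factor means isocratic
elution).  The initial simplex is the regular-simplex subset of a Doehlert
lattice: NF+1 mutually equidistant points with edge length equal to the
characteristic concentration interval, centered on an all-equal
(isocratic) central point.  Standard Nelder-Mead moves follow — reflection
(1.0), expansion (2.0), contraction (0.5), with a shrink toward the best
vertex when contraction fails — minimizing the criterion function.  The
search stops when the total absolute vertex movement between consecutive
iterations falls below the tolerance (1e-15 by default) or the iteration
cap is hit.  Reflected and expanded points are clamped coordinate-wise to
the concentration bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import null_space

from .errors import (
    ConfigError,
    DegenerateStartError,
    DomainError,
    InfeasibleInitializationError,
)
from .gradient import DEFAULT_BOUNDS, DEFAULT_DT, DEFAULT_HORIZON, GradientProfile
from .objective import CFWeights, GradientScorer, OptimizationResult
from .retention import CalibrationSet


@dataclass
class SimplexConfig:
    """Configuration of one Nelder-Mead run."""

    n_factors: int
    conc_interval: float
    center_conc: float = 50.0
    reflect: float = 1.0
    expand: float = 2.0
    contract: float = 0.5
    shrink: float = 0.5
    tol: float = 1e-15
    horizon: float = DEFAULT_HORIZON
    bounds: tuple[float, float] = DEFAULT_BOUNDS
    max_iters: int = 5000
    dt: float = DEFAULT_DT
    rs_threshold: float | None = 3.0  # overlap acceptability rule

    def __post_init__(self):
        if self.n_factors < 1:
            raise ConfigError("n_factors must be >= 1")
        if not self.conc_interval > 0:
            raise ConfigError("conc_interval must be positive")
        lo, hi = self.bounds
        if not (lo <= self.center_conc <= hi):
            raise ConfigError("center_conc must lie within bounds")


@dataclass
class SimplexState:
    """Vertices and bookkeeping of a simplex run."""

    vertices: np.ndarray               # (NF+1, NF)
    cf_values: np.ndarray | None = None
    iteration: int = 0
    history: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _regular_simplex(n: int, edge: float) -> np.ndarray:
    """n+1 points in R^n, pairwise distance ``edge``, centroid at the origin.

    Constructed by centering the n+1 standard basis vectors of R^(n+1)
    (pairwise distance sqrt(2)) and projecting onto the zero-sum hyperplane.
    """
    pts = np.eye(n + 1)
    pts -= pts.mean(axis=0)
    basis = null_space(np.ones((1, n + 1)))  # (n+1, n), orthonormal
    return (pts @ basis) * (edge / math.sqrt(2.0))


def initial_simplex(config: SimplexConfig) -> SimplexState:
    """Regular simplex of edge ``conc_interval`` around the isocratic center.

    Coordinates are clamped to the concentration bounds; if clamping
    collapses the simplex to zero volume the initialization is infeasible.
    """
    n = config.n_factors
    verts = config.center_conc + _regular_simplex(n, config.conc_interval)
    verts = np.clip(verts, *config.bounds)
    if np.linalg.matrix_rank(verts[1:] - verts[0], tol=1e-12) < n:
        raise InfeasibleInitializationError(
            "initial simplex degenerates to zero volume after clamping to bounds"
        )
    return SimplexState(vertices=verts)


def factors_to_profile(
    factors: Sequence[float],
    horizon: float = DEFAULT_HORIZON,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> GradientProfile:
    """Gradient program with the factor concentrations at equidistant nodes.

    A single factor yields an isocratic (constant) program.
    """
    factors = np.asarray(factors, dtype=float)
    if factors.ndim != 1 or factors.size < 1:
        raise DomainError("at least one factor is required")
    if factors.size == 1:
        return GradientProfile.constant(float(factors[0]), horizon, bounds)
    node_times = np.linspace(0.0, horizon, factors.size)
    return GradientProfile(node_times, factors, bounds)


# ---------------------------------------------------------------------------
# the search
# ---------------------------------------------------------------------------

def nelder_mead(
    calibration: CalibrationSet,
    config: SimplexConfig,
    weights: CFWeights | None = None,
    objective: Callable[[np.ndarray], float] | None = None,
) -> OptimizationResult:
    """Minimize the criterion function over node concentrations.

    ``objective`` may replace the chromatographic criterion with an
    arbitrary function of the factor vector (used for convergence checks
    against known test functions); the chromatographic scorer is the
    default.
    """
    weights = weights or CFWeights()
    scorer = None
    if objective is None:
        scorer = GradientScorer(
            calibration,
            weights,
            horizon=config.horizon,
            dt=config.dt,
            bounds=config.bounds,
            rs_threshold=config.rs_threshold,
        )
        node_times = (
            np.linspace(0.0, config.horizon, config.n_factors)
            if config.n_factors > 1
            else np.array([0.0, config.horizon])
        )

        def objective_fn(x: np.ndarray) -> float:
            conc = x if config.n_factors > 1 else np.repeat(x, 2)
            return float(scorer.score_batch(node_times, conc[None, :]).penalized[0])

    else:
        objective_fn = objective

    lo, hi = config.bounds

    def clamp(x: np.ndarray) -> np.ndarray:
        return np.clip(x, lo, hi)

    state = initial_simplex(config)
    verts = state.vertices
    fvals = np.array([objective_fn(v) for v in verts])
    if not np.any(np.isfinite(fvals)):
        raise DegenerateStartError("all initial simplex vertices are infeasible")

    history: list[float] = []
    prev_sorted = None
    n_iter = 0
    for n_iter in range(1, config.max_iters + 1):
        order = np.argsort(fvals, kind="stable")
        verts, fvals = verts[order], fvals[order]
        history.append(float(fvals[0]))

        if prev_sorted is not None:
            movement = float(np.abs(verts - prev_sorted).sum())
            if movement < config.tol:
                break
        prev_sorted = verts.copy()

        centroid = verts[:-1].mean(axis=0)
        xr = clamp(centroid + config.reflect * (centroid - verts[-1]))
        fr = objective_fn(xr)
        if fr < fvals[0]:
            xe = clamp(centroid + config.expand * (xr - centroid))
            fe = objective_fn(xe)
            if fe < fr:
                verts[-1], fvals[-1] = xe, fe
            else:
                verts[-1], fvals[-1] = xr, fr
        elif fr < fvals[-2]:
            verts[-1], fvals[-1] = xr, fr
        else:
            if fr < fvals[-1]:  # outside contraction
                xc = clamp(centroid + config.contract * (xr - centroid))
            else:  # inside contraction
                xc = clamp(centroid + config.contract * (verts[-1] - centroid))
            fc = objective_fn(xc)
            if fc < min(fr, fvals[-1]):
                verts[-1], fvals[-1] = xc, fc
            else:  # shrink toward the best vertex
                verts[1:] = clamp(
                    verts[0] + config.shrink * (verts[1:] - verts[0])
                )
                fvals[1:] = [objective_fn(v) for v in verts[1:]]

    order = np.argsort(fvals, kind="stable")
    verts, fvals = verts[order], fvals[order]
    best = verts[0]
    best_val = float(fvals[0])
    profile = factors_to_profile(clamp(best), config.horizon, config.bounds)
    scored = scorer.score(profile) if scorer is not None and math.isfinite(best_val) else None
    best_cf = scored.cf if scored is not None else best_val
    return OptimizationResult(profile, best_cf, scored, history, n_iter)
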