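"""Packaged calibration data for the 8-sugar system and synthetic generators.

The packaged fixture carries the published isocratic retention coefficients
(fronting / apex / tailing quadratic models) for the eight sugars separated
on a CarboPac PA20 column with KOH eluent — arabitol, cellobiose, fructose,
fucose, lactulose, melibiose, N-acetyl-D-glucosamine, and raffinose — plus
the column void time (0.93 min), the study's criterion weights (alpha=1,
beta=2), concentration bounds (5-95 mM), 30-min horizon, and the Rs >= 3
overlap threshold.

Peak areas were published only graphically, so the fixture attaches
synthetic monotone-decreasing area-vs-concentration tables reproducing the
reported qualitative trend (peak area falls as eluent concentration rises
under amperometric detection).  The synthetic-system generator emits whole
calibration sets with known ground-truth coefficients for round-trip and
noise-recovery testing.

Note on one coefficient: the published fucose fronting a2 appears with a
positive sign although every other a2 in the table (including fucose apex
and tailing) is negative of nearly equal magnitude; the fixture stores
-0.234, treating the positive sign as a typographical slip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .objective import CFWeights
from .retention import (
    MARKERS,
    AnalyteModel,
    CalibrationSet,
    IsocraticRetentionModel,
    isocratic_retention_time,
)

VOID_TIME = 0.93           # min
BOUNDS = (5.0, 95.0)       # mM KOH gradient domain
HORIZON = 30.0             # min acceptable analysis window
RS_THRESHOLD = 3.0
STUDY_WEIGHTS = CFWeights(alpha=1, beta=2)
CALIBRATION_CONCENTRATIONS = (2.0, 26.0, 50.0, 74.0, 98.0)  # mM, 5 isocratic runs

# published 2 mM isocratic apex retention times (min); approximate checks only
# (back-prediction from the rounded coefficients deviates by up to ~10%)
RETENTION_2MM = {
    "arabitol": 1.53,
    "fucose": 3.85,
    "N-acetyl-D-glucosamine": 15.83,
    "fructose": 18.87,
    "melibiose": 23.98,
    "raffinose": 27.92,
    "lactulose": 40.12,
    "cellobiose": 61.28,
}
ELUTION_ORDER_2MM = tuple(RETENTION_2MM)

# analyte -> marker -> (a0, a1, a2, R^2)
SUGAR_COEFFICIENTS = {
    "arabitol": {
        "fronting": (-0.201, -0.009, -0.031, 0.9580),
        "apex": (-0.188, -0.007, -0.030, 0.9723),
        "tailing": (-0.153, -0.020, -0.027, 0.9689),
    },
    "cellobiose": {
        "fronting": (1.808, 0.127, -0.286, 0.9999),
        "apex": (1.814, 0.125, -0.285, 0.9999),
        "tailing": (1.820, 0.126, -0.285, 0.9999),
    },
    "fructose": {
        "fronting": (1.224, 0.128, -0.261, 0.9999),
        "apex": (1.230, 0.128, -0.261, 0.9999),
        "tailing": (1.237, 0.124, -0.259, 1.0000),
    },
    "fucose": {
        "fronting": (0.353, 0.282, -0.234, 1.0000),  # a2 sign corrected
        "apex": (0.363, 0.278, -0.231, 1.0000),
        "tailing": (0.374, 0.274, -0.228, 1.0000),
    },
    "lactulose": {
        "fronting": (1.552, 0.152, -0.291, 1.0000),
        "apex": (1.558, 0.152, -0.291, 1.0000),
        "tailing": (1.566, 0.149, -0.289, 1.0000),
    },
    "melibiose": {
        "fronting": (1.298, 0.205, -0.288, 1.0000),
        "apex": (1.304, 0.204, -0.288, 1.0000),
        "tailing": (1.311, 0.201, -0.286, 1.0000),
    },
    "N-acetyl-D-glucosamine": {
        "fronting": (1.168, 0.036, -0.243, 0.9998),
        "apex": (1.177, 0.028, -0.239, 0.9998),
        "tailing": (1.185, 0.028, -0.238, 0.9998),
    },
    "raffinose": {
        "fronting": (1.327, 0.346, -0.262, 0.9989),
        "apex": (1.335, 0.345, -0.261, 0.9989),
        "tailing": (1.343, 0.341, -0.260, 0.9989),
    },
}

# per-analyte 2 mM area scale (detector units) for the synthetic area tables;
# arbitrary but fixed, spanning a realistic order-of-magnitude range
_AREA_SCALE = {name: 60.0 + 15.0 * i for i, name in enumerate(sorted(SUGAR_COEFFICIENTS))}


def synthetic_area_table(
    a_max: float,
    concentrations=CALIBRATION_CONCENTRATIONS,
) -> list[tuple[float, float]]:
    """Monotone-decreasing area table: area falls 60% across the range."""
    c = np.asarray(concentrations, dtype=float)
    frac = (c - c[0]) / (c[-1] - c[0])
    return [(float(ci), float(a_max * (1.0 - 0.6 * f))) for ci, f in zip(c, frac)]


def load_sugar_fixture() -> CalibrationSet:
    """The packaged 8-sugar calibration set (24 marker models + void time)."""
    analytes = []
    for name in sorted(SUGAR_COEFFICIENTS):
        models = {
            marker: IsocraticRetentionModel(a0, a1, a2, r2)
            for marker, (a0, a1, a2, r2) in SUGAR_COEFFICIENTS[name].items()
        }
        analytes.append(
            AnalyteModel(
                name,
                *[models[m] for m in MARKERS],
                synthetic_area_table(_AREA_SCALE[name]),
            )
        )
    return CalibrationSet(VOID_TIME, analytes)


# ---------------------------------------------------------------------------
# synthetic systems
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSystem:
    """A generated calibration set plus the raw isocratic tables it implies."""

    calibration: CalibrationSet
    isocratic_tables: pd.DataFrame  # long format: analyte, marker, c, tR
    true_coefficients: dict[str, dict[str, tuple[float, float, float]]]
    noise_sigma: float
    seed: int


def generate_synthetic_system(
    n_analytes: int,
    noise_sigma: float = 0.0,
    seed: int = 0,
    void_time: float = VOID_TIME,
    concentrations=CALIBRATION_CONCENTRATIONS,
) -> SyntheticSystem:
    """Draw a plausible multi-analyte system and its raw isocratic datasets.

    Apex coefficients are drawn from ranges covering the packaged system
    (a0 in [-0.3, 2.0], a1 in [-0.05, 0.4], a2 in [-0.35, -0.02]); fronting
    and tailing models shift a0 down/up by a small offset, which preserves
    the marker ordering at every concentration.  The emitted isocratic
    tables carry Gaussian noise of ``noise_sigma`` on log10 k.
    """
    if n_analytes < 1:
        raise DomainError("n_analytes must be >= 1")
    rng = np.random.default_rng(seed)
    analytes = []
    truth: dict[str, dict[str, tuple[float, float, float]]] = {}
    rows = []
    for i in range(n_analytes):
        name = f"analyte_{i:02d}"
        a0 = rng.uniform(-0.3, 2.0)
        a1 = rng.uniform(-0.05, 0.4)
        a2 = rng.uniform(-0.35, -0.02)
        d_front = rng.uniform(0.005, 0.03)
        d_tail = rng.uniform(0.005, 0.03)
        coefs = {
            "fronting": (a0 - d_front, a1, a2),
            "apex": (a0, a1, a2),
            "tailing": (a0 + d_tail, a1, a2),
        }
        truth[name] = coefs
        models = {m: IsocraticRetentionModel(*coefs[m]) for m in MARKERS}
        a_max = rng.uniform(50.0, 200.0)
        analytes.append(
            AnalyteModel(
                name,
                *[models[m] for m in MARKERS],
                synthetic_area_table(a_max, concentrations),
            )
        )
        for marker in MARKERS:
            model = models[marker]
            for c in concentrations:
                logk = model.log_k(c) + (
                    rng.normal(0.0, noise_sigma) if noise_sigma > 0 else 0.0
                )
                rows.append(
                    {
                        "analyte": name,
                        "marker": marker,
                        "concentration_mM": float(c),
                        "retention_min": void_time * (1.0 + 10.0**logk),
                    }
                )
    calibration = CalibrationSet(void_time, analytes)
    return SyntheticSystem(
        calibration, pd.DataFrame(rows), truth, noise_sigma, seed
    )


def sugar_calibration_table(concentrations=CALIBRATION_CONCENTRATIONS) -> pd.DataFrame:
    """Noiseless calibration table back-predicted from the packaged models."""
    fixture = load_sugar_fixture()
    rows = []
    for analyte in fixture.analytes:
        for marker, model in zip(MARKERS, analyte.markers):
            for c in concentrations:
                rows.append(
                    {
                        "analyte": analyte.name,
                        "marker": marker,
                        "concentration_mM": float(c),
                        "retention_min": isocratic_retention_time(
                            model, c, fixture.void_time
                        ),
                    }
                )
    return pd.DataFrame(rows)
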