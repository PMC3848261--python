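"""Isocratic retention models for single-eluent ion chromatography.

Retention of an analyte eluted isocratically at competing-ion (eluent)
concentration ``c`` is described by a quadratic polynomial on log-log scale,

    log10 k = a0 + a1 * log10(c) + a2 * log10(c)**2,

where the retention factor ``k`` relates to the retention time ``tR`` and
the column void (hold-up) time ``t0`` through ``k = (tR - t0) / t0``.  The
quadratic term is an empirical correction to the linear solvent-strength
model; three isocratic experiments at distinct concentrations determine the
coefficients, more over-determine them (ordinary least squares).

Each chromatographic peak carries three such models: one for the peak
apex and one each for the 50%-height points on the fronting and tailing
sides.  Those three predicted times give the half-height peak width needed
for resolution calculations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDesignError,
    DomainError,
    InvalidRetentionError,
)

MARKERS = ("fronting", "apex", "tailing")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class IsocraticRetentionModel:
    """Quadratic log10 k(c) model for one peak marker.

    Parameters
    ----------
    a0, a1, a2
        Polynomial coefficients of log10 k in log10 c (dimensionless).
    r_squared
        Coefficient of determination of the fit on the log10 k scale;
        ``None`` for models constructed directly from coefficients.
    """

    a0: float
    a1: float
    a2: float
    r_squared: float | None = None

    def log_k(self, c):
        return log_k(self, c)

    def retention_time(self, c, void_time):
        return isocratic_retention_time(self, c, void_time)


@dataclass
class AnalyteModel:
    """Three marker models plus an area-vs-concentration table for one analyte.

    ``area_table`` rows are (eluent concentration in mM, peak area in
    detector units) with strictly increasing concentrations; it feeds the
    stretching-factor estimate when rendering chromatograms.
    """

    name: str
    fronting: IsocraticRetentionModel
    apex: IsocraticRetentionModel
    tailing: IsocraticRetentionModel
    area_table: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        concs = np.asarray([row[0] for row in self.area_table], dtype=float)
        if concs.size >= 2 and not np.all(np.diff(concs) > 0):
            raise DomainError(
                f"{self.name}: area_table concentrations must be strictly increasing"
            )

    @property
    def markers(self) -> tuple[IsocraticRetentionModel, ...]:
        return (self.fronting, self.apex, self.tailing)

    def check_marker_ordering(self, concentrations, void_time: float) -> None:
        """Raise if fronting <= apex <= tailing is violated at any given c."""
        for c in np.atleast_1d(concentrations):
            tf = isocratic_retention_time(self.fronting, c, void_time)
            ta = isocratic_retention_time(self.apex, c, void_time)
            tt = isocratic_retention_time(self.tailing, c, void_time)
            if not (tf <= ta <= tt):
                from .errors import InconsistentModelError

                raise InconsistentModelError(
                    f"{self.name}: marker ordering violated at c={c} mM "
                    f"(front={tf:.4f}, apex={ta:.4f}, tail={tt:.4f})"
                )


@dataclass
class CalibrationSet:
    """A column void time plus the fitted models of every analyte."""

    void_time: float
    analytes: list[AnalyteModel]

    def __post_init__(self):
        if not self.void_time > 0:
            raise DomainError("void_time must be positive")
        names = [a.name for a in self.analytes]
        if len(set(names)) != len(names):
            raise DomainError("analyte names must be unique")

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.analytes]

    def coefficient_matrix(self) -> np.ndarray:
        """(3*n_analytes, 3) coefficient array, analyte-major in the marker
        order fronting, apex, tailing.  Used by the batched gradient solver."""
        rows = []
        for analyte in self.analytes:
            for model in analyte.markers:
                rows.append((model.a0, model.a1, model.a2))
        return np.asarray(rows, dtype=float)


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def log_k(model: IsocraticRetentionModel, c):
    """log10 of the retention factor at eluent concentration ``c`` (mM).

    Accepts scalars or arrays; every concentration must be positive.
    """
    arr = np.asarray(c, dtype=float)
    if np.any(arr <= 0):
        raise DomainError("eluent concentration must be positive")
    L = np.log10(arr)
    out = model.a0 + model.a1 * L + model.a2 * L * L
    return float(out) if np.isscalar(c) or arr.ndim == 0 else out


def retention_factor(model: IsocraticRetentionModel, c):
    """Retention factor k = 10**log_k at concentration ``c``."""
    out = 10.0 ** np.asarray(log_k(model, c))
    return float(out) if out.ndim == 0 else out


def isocratic_retention_time(model: IsocraticRetentionModel, c, void_time: float):
    """Isocratic retention time tR = t0 * (1 + k(c)) in minutes."""
    if not void_time > 0:
        raise DomainError("void_time must be positive")
    out = void_time * (1.0 + 10.0 ** np.asarray(log_k(model, c)))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_isocratic_model(
    points: Sequence[tuple[float, float]], void_time: float
) -> IsocraticRetentionModel:
    """Least-squares fit of the quadratic log10 k model to isocratic data.

    Parameters
    ----------
    points
        (concentration in mM, retention time in min) pairs; at least three
        distinct positive concentrations, all retention times above the
        void time.
    void_time
        Column hold-up time t0 in minutes.
    """
    if not void_time > 0:
        raise DomainError("void_time must be positive")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DomainError("points must be (c, tR) pairs")
    c, tr = pts[:, 0], pts[:, 1]
    if np.any(c <= 0):
        raise DomainError("calibration concentrations must be positive")
    if np.unique(c).size < 3:
        raise DegenerateDesignError(
            "at least 3 distinct concentrations are required to fit the "
            "quadratic retention model"
        )
    if np.any(tr <= void_time):
        raise InvalidRetentionError(
            "every retention time must exceed the void time"
        )
    y = np.log10((tr - void_time) / void_time)
    L = np.log10(c)
    X = np.column_stack([np.ones_like(L), L, L * L])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res < 1e-20 else 0.0
    # an exactly-determined or perfect fit should report exactly 1
    if ss_res <= 1e-20 * max(1.0, ss_tot):
        r2 = 1.0
    return IsocraticRetentionModel(*map(float, coef), r_squared=r2)


# ---------------------------------------------------------------------------
# calibration I/O
# ---------------------------------------------------------------------------
# CSV layout: analyte, marker (fronting|apex|tailing), concentration_mM,
# retention_min.  Fitted models serialize to JSON as
# {analyte: {marker: {a0, a1, a2, r_squared}}} plus the void time.

def fit_calibration_table(
    table: pd.DataFrame,
    void_time: float,
    area_tables: dict[str, list[tuple[float, float]]] | None = None,
) -> CalibrationSet:
    """Fit a full :class:`CalibrationSet` from a long-format calibration table."""
    required = {"analyte", "marker", "concentration_mM", "retention_min"}
    missing = required - set(table.columns)
    if missing:
        raise DomainError(f"calibration table missing columns: {sorted(missing)}")
    analytes = []
    for name, group in table.groupby("analyte", sort=True):
        models = {}
        for marker in MARKERS:
            rows = group[group["marker"] == marker]
            if rows.empty:
                raise DomainError(
                    f"analyte {name!r}: no rows for marker {marker!r}"
                )
            pts = rows[["concentration_mM", "retention_min"]].to_numpy()
            models[marker] = fit_isocratic_model(pts, void_time)
        area = (area_tables or {}).get(str(name), [])
        analytes.append(AnalyteModel(str(name), *[models[m] for m in MARKERS], area))
    return CalibrationSet(void_time, analytes)


def read_calibration_csv(path, void_time: float) -> CalibrationSet:
    return fit_calibration_table(pd.read_csv(path), void_time)


def calibration_to_table(
    calibration: CalibrationSet, concentrations: Iterable[float]
) -> pd.DataFrame:
    """Noiseless long-format calibration table predicted by a calibration set."""
    rows = []
    for analyte in calibration.analytes:
        for marker, model in zip(MARKERS, analyte.markers):
            for c in concentrations:
                rows.append(
                    {
                        "analyte": analyte.name,
                        "marker": marker,
                        "concentration_mM": float(c),
                        "retention_min": isocratic_retention_time(
                            model, c, calibration.void_time
                        ),
                    }
                )
    return pd.DataFrame(rows)


def models_to_dict(calibration: CalibrationSet) -> dict:
    out: dict = {"void_time": calibration.void_time, "analytes": {}}
    for analyte in calibration.analytes:
        entry: dict = {}
        for marker, model in zip(MARKERS, analyte.markers):
            entry[marker] = {
                "a0": model.a0,
                "a1": model.a1,
                "a2": model.a2,
                "r_squared": model.r_squared,
            }
        if analyte.area_table:
            entry["area_table"] = [list(map(float, row)) for row in analyte.area_table]
        out["analytes"][analyte.name] = entry
    return out


def models_from_dict(payload: dict) -> CalibrationSet:
    analytes = []
    for name, entry in payload["analytes"].items():
        models = {
            marker: IsocraticRetentionModel(
                entry[marker]["a0"],
                entry[marker]["a1"],
                entry[marker]["a2"],
                entry[marker].get("r_squared"),
            )
            for marker in MARKERS
        }
        area = [tuple(row) for row in entry.get("area_table", [])]
        analytes.append(AnalyteModel(name, *[models[m] for m in MARKERS], area))
    return CalibrationSet(payload["void_time"], analytes)


def save_models(calibration: CalibrationSet, path) -> None:
    Path(path).write_text(json.dumps(models_to_dict(calibration), indent=2))


def load_models(path) -> CalibrationSet:
    return models_from_dict(json.loads(Path(path).read_text()))
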