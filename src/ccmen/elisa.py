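"""ELISA standard-curve arithmetic for model validation.

Particle concentrations are read off a direct-binding ELISA via a
logarithmic standard curve,

    absorbance = slope * ln(concentration) + intercept,

fitted by ordinary least squares on ln-transformed concentration.  The
fraction of particles bound to cells is the relative depletion of the
supernatant:

    % bound = 100 * (exposed - supernatant) / exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError


@dataclass(frozen=True)
class StandardCurve:
    """Fitted log-linear calibration curve.

    ``slope`` is absorbance per ln(concentration in ug/mL); ``intercept``
    the absorbance at 1 ug/mL; ``r_squared`` the coefficient of
    determination on the absorbance scale.
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def predict(self, concentration: float) -> float:
        return predict_absorbance(self, concentration)

    def invert(self, absorbance: float) -> float:
        return invert_concentration(self, absorbance)


def average_replicates(
    points: Iterable[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Average replicate absorbances measured at the same concentration."""
    df = pd.DataFrame(points, columns=["concentration", "absorbance"])
    grouped = df.groupby("concentration", as_index=False)["absorbance"].mean()
    return list(grouped.itertuples(index=False, name=None))


def fit_log_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares fit of absorbance against ln(concentration).

    Replicates (repeated concentrations) are averaged before fitting.
    Requires at least three calibration points with at least two distinct,
    strictly positive concentrations.
    """
    pts = list(points)
    if len(pts) < 3:
        raise FitError(f"need at least 3 calibration points, got {len(pts)}")
    if any(c <= 0 for c, _ in pts):
        raise ValueError("concentrations must be strictly positive for a log fit")
    pts = average_replicates(pts)
    conc = np.array([c for c, _ in pts], dtype=float)
    absorb = np.array([a for _, a in pts], dtype=float)
    if np.unique(conc).size < 2:
        raise FitError("calibration concentrations are all equal; cannot fit a slope")
    result = stats.linregress(np.log(conc), absorb)
    return StandardCurve(
        slope=float(result.slope),
        intercept=float(result.intercept),
        r_squared=float(result.rvalue**2),
        n_points=len(pts),
    )


def predict_absorbance(curve: StandardCurve, concentration: float) -> float:
    """Absorbance the curve predicts at a concentration (ug/mL, > 0)."""
    if concentration <= 0:
        raise ValueError(f"concentration must be > 0, got {concentration}")
    return curve.slope * math.log(concentration) + curve.intercept


def invert_concentration(curve: StandardCurve, absorbance: float) -> float:
    """Concentration (ug/mL) producing a given absorbance; inverse of predict."""
    if curve.slope == 0:
        raise ZeroDivisionError("curve slope is zero; inversion undefined")
    return math.exp((absorbance - curve.intercept) / curve.slope)


def percent_bound(conc_exposed: float, conc_supernatant: float) -> float:
    """Percentage of exposed particles depleted from the supernatant."""
    if conc_exposed <= 0:
        raise ValueError(f"exposed concentration must be > 0, got {conc_exposed}")
    if conc_supernatant < 0:
        raise ValueError("supernatant concentration cannot be negative")
    if conc_supernatant > conc_exposed:
        raise ValueError(
            "supernatant concentration exceeds the exposed concentration; "
            "measurements are inconsistent"
        )
    return 100.0 * (conc_exposed - conc_supernatant) / conc_exposed


def load_calibration(path: str | Path) -> list[tuple[float, float]]:
    """Read a two-column (concentration, absorbance) calibration CSV."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FitError(f"calibration file {path} needs two columns")
    return list(
        df.iloc[:, :2].astype(float).itertuples(index=False, name=None)
    )
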