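"""Two-parameter logistic psychometric observers.

A participant's detection behaviour is modelled as

    p(x) = 1 / (1 + exp(-4 * slope * (x - t50)))

where ``x`` is stimulus intensity in mA, ``t50`` is the 50% detection
threshold (mA) and ``slope`` is the derivative dp/dx evaluated at ``t50``
(units 1/mA).  The factor 4 makes the slope parameter literally the slope of
the curve at threshold: dp/dx|_{t50} = 4*s/4 = s.

From a fitted observer the module derives the 10-level experimental intensity
grid (anchored so level 2 sits at the 1% point T01 and level 9 at the 99%
point T99), and implements the participant-exclusion rule based on fitted
detection probabilities at the extreme grid levels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "PsychometricFit",
    "IntensityGrid",
    "fit_logistic",
    "detection_probability",
    "uncertainty_value",
    "average_fits",
    "derive_intensity_grid",
    "exclusion_check",
    "read_calibration",
    "write_calibration",
]

#: Upper bound on the fitted slope (1/mA).  Perfectly separated outcome data
#: drive the maximum-likelihood slope to infinity; the cap keeps the optimum
#: finite and well inside float range.
SLOPE_CAP = 50.0

# logit(0.99) = -logit(0.01); used to place T01/T99 on the intensity axis.
_LOGIT99 = math.log(0.99 / 0.01)


class NonIdentifiableFitError(ValueError):
    """Raised when the outcome data cannot identify both logistic parameters."""


class DegenerateDesignError(ValueError):
    """Raised when the calibration design has fewer than two distinct intensities."""


@dataclass(frozen=True)
class PsychometricFit:
    """Maximum-likelihood two-parameter logistic observer.

    Attributes
    ----------
    t50 : float
        Intensity (mA) with 50% detection probability.
    slope : float
        dp/dx at ``t50`` (1/mA); strictly positive.
    n_trials : int
        Number of trials the fit was computed from (0 for synthetic fits).
    log_likelihood : float
        Bernoulli log-likelihood at the optimum (``nan`` for synthetic fits).
    """

    t50: float
    slope: float
    n_trials: int = 0
    log_likelihood: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if not (self.slope > 0 and math.isfinite(self.slope)):
            raise ValueError(f"slope must be finite and positive, got {self.slope}")
        if not math.isfinite(self.t50):
            raise ValueError(f"t50 must be finite, got {self.t50}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "t50": self.t50,
            "slope": self.slope,
            "n_trials": self.n_trials,
            "log_likelihood": self.log_likelihood,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PsychometricFit":
        d = json.loads(Path(path).read_text())
        return cls(d["t50"], d["slope"], d.get("n_trials", 0),
                   d.get("log_likelihood", math.nan))


@dataclass(frozen=True)
class IntensityGrid:
    """Equidistant 10-level stimulus grid anchored at T01 (level 2) and T99 (level 9)."""

    levels: tuple[float, ...]
    step: float

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        if lv.size != 10:
            raise ValueError("grid must have exactly 10 levels")
        d = np.diff(lv)
        if not np.all(d > 0):
            raise ValueError("grid levels must be strictly increasing")
        if np.max(np.abs(d - self.step)) >= 1e-9:
            raise ValueError("grid levels must be equidistant")

    def level(self, i: int) -> float:
        """Intensity (mA) at 1-based level index ``i``."""
        if not 1 <= i <= 10:
            raise IndexError(f"level index must be in 1..10, got {i}")
        return self.levels[i - 1]


def detection_probability(fit: PsychometricFit, x) -> float | np.ndarray:
    """Detection probability at intensity ``x`` (mA) under the fitted observer."""
    x = np.asarray(x, dtype=float)
    out = 1.0 / (1.0 + np.exp(-4.0 * fit.slope * (x - fit.t50)))
    return float(out) if out.ndim == 0 else out


def uncertainty_value(fit: PsychometricFit, x) -> float | np.ndarray:
    """Slope of the psychometric function at ``x`` (1/mA).

    Maximal at threshold and symmetric about it — an inverse-U over intensity —
    this is the "expected uncertainty" covariate: how steeply detection
    probability is changing at the presented intensity, i.e. how susceptible
    the percept is to trial-by-trial fluctuation.
    """
    p = detection_probability(fit, x)
    return 4.0 * fit.slope * p * (1.0 - p)


def _negloglik(params: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    t50, slope = params
    z = 4.0 * slope * (x - t50)
    # log p = -log1p(exp(-z)); log(1-p) = -z - log1p(exp(-z))
    log1pexp = np.logaddexp(0.0, -z)
    ll = -(y * log1pexp + (1.0 - y) * (z + log1pexp)).sum()
    return -ll


def fit_logistic(intensities: Sequence[float], detected: Sequence[int],
                 slope_cap: float = SLOPE_CAP) -> PsychometricFit:
    """Maximum-likelihood logistic fit to binary detection data.

    Bounded L-BFGS-B from multiple starts; ``t50`` is box-constrained to the
    tested intensity range and the slope to ``(0, slope_cap]``, which guards
    against divergence on perfectly separated data.  Ties between equally
    likely optima are broken towards the smaller slope.
    """
    x = np.asarray(intensities, dtype=float)
    y = np.asarray(detected, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("intensities and detected must be 1-D and equal length")
    if np.unique(x).size < 2:
        raise DegenerateDesignError("need at least 2 distinct intensities")
    if not (np.any(y == 0) and np.any(y == 1)):
        raise NonIdentifiableFitError(
            "all outcomes identical: logistic parameters are not identifiable")

    lo, hi = float(x.min()), float(x.max())
    span = hi - lo
    bounds = [(lo, hi), (1e-3, slope_cap)]
    starts = [
        (0.5 * (lo + hi), 2.0 / span),
        (float(np.median(x)), 1.0 / span),
        (0.5 * (lo + hi), 10.0 / span),
        (lo + 0.25 * span, 4.0 / span),
        (lo + 0.75 * span, 4.0 / span),
    ]
    best = None
    for s in starts:
        res = minimize(_negloglik, np.asarray(s, dtype=float), args=(x, y),
                       method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun - 1e-10 or (
                abs(res.fun - best.fun) <= 1e-10 and res.x[1] < best.x[1]):
            best = res
    t50, slope = best.x
    return PsychometricFit(float(t50), float(slope), n_trials=int(x.size),
                           log_likelihood=float(-best.fun))


def average_fits(fits: Sequence[PsychometricFit]) -> PsychometricFit:
    """Participant-level observer: unweighted mean of per-run thresholds and slopes."""
    if len(fits) == 0:
        raise ValueError("cannot average an empty list of fits")
    t50 = float(np.mean([f.t50 for f in fits]))
    slope = float(np.mean([f.slope for f in fits]))
    return PsychometricFit(t50, slope, n_trials=int(sum(f.n_trials for f in fits)))


def derive_intensity_grid(fit: PsychometricFit) -> IntensityGrid:
    """10-level equidistant grid with T01 at level 2 and T99 at level 9.

    T01/T99 solve p(x) = .01/.99 under the fit; the common step is
    (T99 - T01)/7 and levels 1..10 are T01 + (i - 2) * step.
    """
    if fit.slope <= 0:
        raise ValueError("slope must be positive")
    half_range = _LOGIT99 / (4.0 * fit.slope)  # t50 -> T99 distance
    t01 = fit.t50 - half_range
    t99 = fit.t50 + half_range
    step = (t99 - t01) / 7.0
    levels = tuple(t01 + (i - 2) * step for i in range(1, 11))
    return IntensityGrid(levels=levels, step=step)


def exclusion_check(avg_fit: PsychometricFit, grid: IntensityGrid) -> bool:
    """True (exclude) iff p(level 1) > .10 or p(level 10) < .90.

    Applied to the run-averaged observer against the grid fixed before the
    main experiment; it fires when the calibration failed to pin down the
    dynamic range (threshold drift, criterion shifts).  Inequalities are
    strict, so a participant sitting exactly on a bound is kept.
    """
    p1 = detection_probability(avg_fit, grid.level(1))
    p10 = detection_probability(avg_fit, grid.level(10))
    return bool(p1 > 0.10 or p10 < 0.90)


def write_calibration(path: str | Path, intensities: Sequence[float],
                      detected: Sequence[int]) -> None:
    """Write a calibration session as a tab-separated (trial, intensity_mA, detected) table."""
    df = pd.DataFrame({
        "trial": np.arange(1, len(list(intensities)) + 1),
        "intensity_mA": np.asarray(intensities, dtype=float),
        "detected": np.asarray(detected, dtype=int),
    })
    df.to_csv(path, sep="\t", index=False)


def read_calibration(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return df["intensity_mA"].to_numpy(float), df["detected"].to_numpy(int)
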