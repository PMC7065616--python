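"""Pressure-sensor to force calibration.

A noncontact tonometry air-puff chamber reports an internal pressure
reading (kPa) while the quantity acting on the cornea is a force (N).
The two are linked by a static calibration: a strain gauge, itself
precalibrated with reference weights, records the force exerted by the
air puff while the internal pressure sensor is read out simultaneously.
This module fits that relationship as an affine model by ordinary least
squares and applies it to convert pressure traces into force traces.

The affine form is a modelling choice: the weight calibration of the
gauge (1-10 g, i.e. ~10-100 mN) spans a linear regime, and the fit R^2
is reported so any nonlinearity is visible to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateDesignError, InvalidTraceError

__all__ = [
    "GRAVITY",
    "CalibrationModel",
    "ForceTrace",
    "fit_calibration",
    "pressure_to_force",
    "weights_to_forces",
]

#: Standard gravity used to convert calibration weights (grams) to force (N).
GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class ForceTrace:
    """Applied-force time series.

    Attributes
    ----------
    time : ndarray
        Sample times in seconds, strictly increasing.
    force : ndarray
        Force in newtons, same length as ``time``, finite.
    """

    time: np.ndarray
    force: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if t.ndim != 1 or f.ndim != 1 or len(t) != len(f):
            raise InvalidTraceError("time and force must be 1-D arrays of equal length")
        if not np.all(np.isfinite(f)) or not np.all(np.isfinite(t)):
            raise InvalidTraceError("force trace contains non-finite values")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise InvalidTraceError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "force", f)

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class CalibrationModel:
    """Affine pressure-to-force map ``force = slope * pressure + intercept``.

    Attributes
    ----------
    slope : float
        N per kPa; positive for physical calibrations.
    intercept : float
        N.
    fit_r2 : float
        Coefficient of determination of the fit, in [0, 1].
    n_points : int
        Number of calibration points used.
    """

    slope: float
    intercept: float = 0.0
    fit_r2: float = 1.0
    n_points: int = 2

    def __post_init__(self):
        if self.n_points < 2:
            raise DegenerateDesignError("a calibration needs at least 2 points")
        if not (0.0 <= self.fit_r2 <= 1.0 + 1e-12):
            raise ValueError(f"fit_r2 must lie in [0, 1], got {self.fit_r2}")

    def __call__(self, pressure_kpa):
        return self.slope * np.asarray(pressure_kpa, dtype=float) + self.intercept


def weights_to_forces(grams) -> np.ndarray:
    """Convert reference weights in grams to gauge forces in newtons."""
    return np.asarray(grams, dtype=float) * 1e-3 * GRAVITY


def fit_calibration(pressure_readouts, gauge_forces) -> CalibrationModel:
    """Fit the affine pressure (kPa) -> force (N) calibration by OLS.

    Parameters
    ----------
    pressure_readouts : array-like
        Internal pressure-sensor readouts in kPa; at least two distinct values.
    gauge_forces : array-like
        Simultaneous strain-gauge forces in newtons, same length.

    Returns
    -------
    CalibrationModel
        Slope (N/kPa), intercept (N), fit R^2 and the number of points.

    Raises
    ------
    DegenerateDesignError
        If fewer than two points are given or all pressures coincide.
    """
    p = np.asarray(pressure_readouts, dtype=float)
    f = np.asarray(gauge_forces, dtype=float)
    if p.ndim != 1 or f.ndim != 1 or len(p) != len(f):
        raise InvalidTraceError("pressure and force arrays must be 1-D and equal length")
    if len(p) < 2:
        raise DegenerateDesignError("at least 2 calibration points required")
    if np.ptp(p) == 0.0:
        raise DegenerateDesignError("all pressure readouts identical; slope undefined")

    slope, intercept = np.polyfit(p, f, 1)
    resid = f - (slope * p + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    # Perfect fit on constant forces gives 0/0; by convention R^2 = 1 there.
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return CalibrationModel(slope=float(slope), intercept=float(intercept),
                            fit_r2=r2, n_points=len(p))


def pressure_to_force(time_s, pressure_kpa, model: CalibrationModel) -> ForceTrace:
    """Convert a pressure trace (kPa) into a force trace (N).

    The affine model is applied elementwise; the time base is carried
    through unchanged.
    """
    p = np.asarray(pressure_kpa, dtype=float)
    return ForceTrace(time=np.asarray(time_s, dtype=float), force=model(p))
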