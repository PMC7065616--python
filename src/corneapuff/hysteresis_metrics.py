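"""Dynamic corneal hysteresis loop construction and descriptors.

Combining the apex displacement x(t) and the applied force F(t) of one
air-puff stimulation yields a force-displacement loop F(x): the loading
branch runs from rest to the maximum apex displacement (MAD) and the
unloading branch back.  Because the cornea dissipates energy viscously,
the two branches do not coincide; the enclosed area is the dissipated
energy.

Descriptors
-----------
MAD
    Maximum apex displacement, microns.
HA (hysteresis area)
    Enclosed loop energy,

        HA = int_0^MAD F_loading dx  -  int_MAD^0 F_unloading dx,

    reported in joules.  It is computed as the time-parameterised line
    integral oint F dx around the closed loop (shoelace / trapezoidal
    rule, loop closed from the last point back to the first), which
    equals the two-integral form whenever each branch is monotone in x
    but also handles non-monotone segments and post-recovery ringing
    (x < 0) without re-sorting.
HR (hysteresis ratio)
    HR = 100 * HA / int_0^MAD F_loading dx, the percentage of loading
    energy that is dissipated over one deformation-recovery cycle.
S_sec
    Secant slope of the loading branch between the 10%-of-MAD point and
    the MAD point, N/m.
S_low / S_high
    Least-squares slopes of the loading branch over the first 120 um
    from the 10%-MAD point (low strain) and over the last 120 um before
    MAD (high strain), N/m.  On the J-shaped corneal loading curve
    S_high exceeds S_low.

Displacements are carried in microns throughout and converted to metres
inside the energy and slope computations, so HA is in joules and slopes
in N/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    AlignmentError,
    InsufficientDataError,
    InsufficientWindowError,
    InvalidTraceError,
    NoDeformationError,
    SlopeUndefinedError,
    UndefinedRatioError,
    CorneaPuffError,
)
from .force_calibration import ForceTrace
from .mscan_segmentation import CCTTriplet, DisplacementTrace

__all__ = [
    "HysteresisCurve",
    "HysteresisMetrics",
    "build_hysteresis",
    "hysteresis_area",
    "loading_energy",
    "hysteresis_ratio",
    "secant_slope",
    "low_strain_slope",
    "high_strain_slope",
    "compute_all_metrics",
    "curve_to_csv",
    "metrics_to_csv",
]

#: Width of the low/high-strain linear-fit windows on the loading curve.
STRAIN_WINDOW_UM = 120.0

#: Fraction of MAD defining the start of the secant / low-strain window.
SECANT_START_FRACTION = 0.10


@dataclass(frozen=True)
class HysteresisCurve:
    """Time-ordered force-displacement loop of one stimulation.

    Attributes
    ----------
    x : ndarray
        Apex displacement, microns, in acquisition order.
    F : ndarray
        Force, newtons, resampled onto the displacement timestamps.
    split_index : int
        Index of the maximum displacement (first occurrence on ties).
        Samples [0..split_index] form the loading branch,
        [split_index..end] the unloading branch.
    mad : float
        Maximum apex displacement ``x[split_index]``, microns.
    """

    x: np.ndarray
    F: np.ndarray
    split_index: int
    mad: float

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        F = np.asarray(self.F, dtype=float)
        if len(x) != len(F) or len(x) < 4:
            raise InvalidTraceError("hysteresis curve needs >= 4 paired samples")
        if not (0 <= self.split_index < len(x)):
            raise InvalidTraceError("split_index out of range")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "F", F)

    @property
    def loading(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, F) of the loading branch, rest to MAD inclusive."""
        s = self.split_index + 1
        return self.x[:s], self.F[:s]

    @property
    def unloading(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, F) of the unloading branch, MAD to end inclusive."""
        return self.x[self.split_index:], self.F[self.split_index:]

    def __len__(self) -> int:
        return len(self.x)


def build_hysteresis(x: DisplacementTrace, f: ForceTrace) -> HysteresisCurve:
    """Pair displacement and force into a time-ordered hysteresis loop.

    Force samples are linearly resampled onto the displacement
    timestamps (kept as-is when the clocks already coincide).  The loop
    is split at the first occurrence of the maximum displacement.

    Raises
    ------
    AlignmentError
        If the two traces share no time support.
    NoDeformationError
        If the maximum displacement is not positive.
    """
    tx, tf = x.time, f.time
    if tx[0] > tf[-1] or tx[-1] < tf[0]:
        raise AlignmentError("displacement and force traces do not overlap in time")

    if len(tx) == len(tf) and np.allclose(tx, tf, rtol=0.0, atol=1e-12):
        xs, Fs = x.x, f.force
    else:
        keep = (tx >= tf[0]) & (tx <= tf[-1])
        if keep.sum() < 4:
            raise AlignmentError("fewer than 4 displacement samples overlap the force trace")
        xs = x.x[keep]
        Fs = np.interp(tx[keep], tf, f.force)

    split = int(np.argmax(xs))
    mad = float(xs[split])
    if mad <= 0:
        raise NoDeformationError("maximum apex displacement is not positive")
    return HysteresisCurve(x=xs.copy(), F=np.asarray(Fs, float).copy(),
                           split_index=split, mad=mad)


def hysteresis_area(h: HysteresisCurve) -> float:
    """Enclosed loop energy oint F dx in joules.

    Trapezoidal (shoelace) line integral around the time-ordered loop,
    closed from the last point back to the first.  Positive for passive
    dissipative loops traversed loading-then-unloading; zero when the
    two branches coincide.
    """
    if len(h) < 4:
        raise InsufficientDataError("hysteresis area needs >= 4 points")
    x_m = h.x * 1e-6
    F = h.F
    dx = np.roll(x_m, -1) - x_m
    return float(np.sum(0.5 * (F + np.roll(F, -1)) * dx))


def loading_energy(h: HysteresisCurve) -> float:
    """Energy delivered on the loading branch, int_0^MAD F dx, joules."""
    xl, Fl = h.loading
    return float(np.trapezoid(Fl, xl * 1e-6))


def hysteresis_ratio(h: HysteresisCurve) -> float:
    """Dissipated percentage of the loading energy, HR = 100 * HA / E_load."""
    e_load = loading_energy(h)
    if e_load <= 0:
        raise UndefinedRatioError("loading energy is not positive; HR undefined")
    return 100.0 * hysteresis_area(h) / e_load


def _x10_point(h: HysteresisCurve) -> tuple[float, float]:
    """Locate the 10%-of-MAD point on the loading branch.

    Returns the (x, F) pair at exactly ``SECANT_START_FRACTION * mad``,
    obtained by linear interpolation at the first crossing.  When the
    very first loading sample already exceeds the threshold, that sample
    is used as-is (nothing earlier exists to interpolate against).
    """
    xl, Fl = h.loading
    x_thr = SECANT_START_FRACTION * h.mad
    above = np.nonzero(xl >= x_thr)[0]
    if len(above) == 0:
        raise SlopeUndefinedError("loading branch never reaches 10% of MAD")
    i = int(above[0])
    if i == 0:
        return float(xl[0]), float(Fl[0])
    # linear interpolation between samples i-1 and i to exactly x_thr
    x0, x1 = xl[i - 1], xl[i]
    f0, f1 = Fl[i - 1], Fl[i]
    w = (x_thr - x0) / (x1 - x0)
    return float(x_thr), float(f0 + w * (f1 - f0))


def secant_slope(h: HysteresisCurve) -> float:
    """Secant slope between the 10%-MAD point and the MAD point, N/m."""
    x10, f10 = _x10_point(h)
    x_end, f_end = h.mad, float(h.F[h.split_index])
    if x_end <= x10:
        raise SlopeUndefinedError("degenerate loading branch: MAD at or below the 10% point")
    return (f_end - f10) / ((x_end - x10) * 1e-6)


def _window_fit(h: HysteresisCurve, lo_um: float, hi_um: float) -> float:
    """Least-squares slope of F vs x over loading samples with x in [lo, hi]."""
    xl, Fl = h.loading
    mask = (xl >= lo_um) & (xl <= hi_um)
    if mask.sum() < 3:
        raise InsufficientWindowError(
            f"only {int(mask.sum())} loading samples in [{lo_um:.1f}, {hi_um:.1f}] um; need >= 3"
        )
    slope = np.polyfit(xl[mask] * 1e-6, Fl[mask], 1)[0]
    return float(slope)


def low_strain_slope(h: HysteresisCurve) -> float:
    """Slope of the linear fit over the first 120 um from the 10%-MAD point, N/m."""
    x10, _ = _x10_point(h)
    if x10 + STRAIN_WINDOW_UM > h.mad:
        raise InsufficientWindowError(
            f"low-strain window [{x10:.1f}, {x10 + STRAIN_WINDOW_UM:.1f}] um "
            f"extends beyond MAD = {h.mad:.1f} um"
        )
    return _window_fit(h, x10, x10 + STRAIN_WINDOW_UM)


def high_strain_slope(h: HysteresisCurve) -> float:
    """Slope of the linear fit over the last 120 um of the loading curve, N/m."""
    if h.mad < STRAIN_WINDOW_UM:
        raise InsufficientWindowError(
            f"loading span {h.mad:.1f} um is shorter than the {STRAIN_WINDOW_UM:.0f} um window"
        )
    return _window_fit(h, h.mad - STRAIN_WINDOW_UM, h.mad)


@dataclass(frozen=True)
class HysteresisMetrics:
    """The full descriptor set of one stimulation.

    Metrics that could not be computed are NaN, with the reason recorded
    in ``failures`` under the metric name — a partial record is reported
    honestly rather than dropped.
    """

    mad: float = np.nan          # um
    ha: float = np.nan           # J
    hr: float = np.nan           # %
    s_sec: float = np.nan        # N/m
    s_low: float = np.nan        # N/m
    s_high: float = np.nan       # N/m
    cct_bef: float = np.nan      # um
    cct_max: float = np.nan      # um
    cct_aft: float = np.nan      # um
    loading_energy: float = np.nan  # J
    failures: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mad_um": self.mad,
            "ha_J": self.ha,
            "hr_pct": self.hr,
            "s_sec_N_per_m": self.s_sec,
            "s_low_N_per_m": self.s_low,
            "s_high_N_per_m": self.s_high,
            "cct_bef_um": self.cct_bef,
            "cct_max_um": self.cct_max,
            "cct_aft_um": self.cct_aft,
            "loading_energy_J": self.loading_energy,
        }


def compute_all_metrics(
    x: DisplacementTrace, f: ForceTrace, cct: CCTTriplet | None = None
) -> HysteresisMetrics:
    """Build the loop and evaluate every descriptor, tolerating partial failures.

    Each descriptor is attempted independently; a failing one is set to
    NaN with its error message stored in ``failures`` instead of
    aborting the record.
    """
    failures: dict[str, str] = {}
    values: dict[str, float] = {}

    try:
        h = build_hysteresis(x, f)
    except CorneaPuffError as e:
        failures["curve"] = str(e)
        h = None

    if h is not None:
        values["mad"] = h.mad
        for name, fn in (
            ("ha", hysteresis_area),
            ("hr", hysteresis_ratio),
            ("s_sec", secant_slope),
            ("s_low", low_strain_slope),
            ("s_high", high_strain_slope),
            ("loading_energy", loading_energy),
        ):
            try:
                values[name] = fn(h)
            except CorneaPuffError as e:
                failures[name] = str(e)

    if cct is not None:
        values["cct_bef"] = cct.cct_bef
        values["cct_max"] = cct.cct_max
        values["cct_aft"] = cct.cct_aft
    else:
        failures.setdefault("cct", "no thickness data supplied")

    return HysteresisMetrics(failures=failures, **values)


def curve_to_csv(h: HysteresisCurve, path) -> None:
    """Export a loop as CSV with columns ``x_um,F_N`` for plotting."""
    import pandas as pd

    pd.DataFrame({"x_um": h.x, "F_N": h.F}).to_csv(path, index=False)


def metrics_to_csv(metrics_list, path, extra_columns=None) -> None:
    """Write one row per stimulation with the documented column schema.

    Columns: mad_um, ha_J, hr_pct, s_sec_N_per_m, s_low_N_per_m,
    s_high_N_per_m, cct_bef_um, cct_max_um, cct_aft_um,
    loading_energy_J, plus any ``extra_columns`` (a list of dicts,
    one per row, e.g. identifiers).
    """
    import pandas as pd

    rows = []
    for i, m in enumerate(metrics_list):
        row = m.to_dict()
        if extra_columns is not None:
            row.update(extra_columns[i])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
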