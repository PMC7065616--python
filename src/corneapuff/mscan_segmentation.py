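"""Corneal surface segmentation of OCT M-scans.

An M-scan is a depth-vs-time image: each column is one A-scan (a depth
reflectivity profile) acquired at the corneal apex, and successive
columns sample the deformation at the A-scan rate.  During an air-puff
stimulation the anterior corneal interface moves inward (down the image)
and back; the posterior interface follows it at roughly one corneal
thickness below.

This module extracts both interfaces per column with subpixel precision,
converts the anterior trace into apex displacement x(t) relative to a
pre-stimulus baseline, and evaluates central corneal thickness (CCT) at
the three canonical instants: before the puff, at maximum displacement,
and after recovery.

Conventions
-----------
* Depth coordinates are 0-based from the top of the image; a pixel's
  centre sits at integer row index; subpixel positions are continuous.
* Depth increases downward, so inward corneal motion increases the
  anterior coordinate and displacement is inward-positive.
* Surface positions are optical path length in air-equivalent microns
  (pixels x axial pitch).  Physical thickness divides the optical
  thickness by the corneal group index (1.376 at 1310 nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .errors import (
    InvalidTraceError,
    InvalidWindowError,
    NoRecoveryError,
    NoSurfaceError,
    SegmentationFailureError,
)

__all__ = [
    "CORNEAL_GROUP_INDEX",
    "MScan",
    "SurfacePair",
    "DisplacementTrace",
    "CCTTriplet",
    "SegmentationParams",
    "segment_surfaces",
    "displacement_from_surfaces",
    "cct_at_instants",
]

#: Corneal group refractive index at 1310 nm, used to convert optical
#: thickness (air-equivalent path) to physical thickness.
CORNEAL_GROUP_INDEX = 1.376


@dataclass(frozen=True)
class MScan:
    """Depth x time OCT intensity image with acquisition metadata.

    Attributes
    ----------
    intensity : ndarray, shape (depth_px, n_ascan)
        Non-negative finite intensities; rows are depth, columns time.
    axial_pitch : float
        Depth sampling, microns in air per pixel.
    ascan_rate : float
        A-scan acquisition rate in Hz.
    t0 : float
        Acquisition trigger time of the first column, seconds.
    """

    intensity: np.ndarray
    axial_pitch: float
    ascan_rate: float
    t0: float = 0.0

    def __post_init__(self):
        img = np.asarray(self.intensity)
        if img.ndim != 2 or img.shape[1] < 2:
            raise InvalidTraceError("M-scan must be 2-D with at least 2 A-scans")
        if not np.all(np.isfinite(img)) or np.any(img < 0):
            raise InvalidTraceError("M-scan intensities must be finite and >= 0")
        if self.axial_pitch <= 0 or self.ascan_rate <= 0:
            raise InvalidTraceError("axial_pitch and ascan_rate must be positive")
        object.__setattr__(self, "intensity", img)

    @property
    def n_ascan(self) -> int:
        return self.intensity.shape[1]

    @property
    def depth_px(self) -> int:
        return self.intensity.shape[0]

    @property
    def time(self) -> np.ndarray:
        """Column acquisition times in seconds."""
        return self.t0 + np.arange(self.n_ascan) / self.ascan_rate


@dataclass(frozen=True)
class SurfacePair:
    """Per-A-scan anterior/posterior surface positions (optical microns).

    Positions are NaN where ``valid_mask`` is False; invalid columns are
    flagged, never silently interpolated, so quality control stays
    auditable.  Interpolation happens only downstream, in the derived
    displacement trace.
    """

    anterior: np.ndarray
    posterior: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.anterior, dtype=float)
        p = np.asarray(self.posterior, dtype=float)
        v = np.asarray(self.valid_mask, dtype=bool)
        if not (len(a) == len(p) == len(v)):
            raise InvalidTraceError("surface arrays must share length")
        if np.any(p[v] <= a[v]):
            raise InvalidTraceError("posterior must lie below anterior where valid")
        object.__setattr__(self, "anterior", a)
        object.__setattr__(self, "posterior", p)
        object.__setattr__(self, "valid_mask", v)

    def __len__(self) -> int:
        return len(self.anterior)


@dataclass(frozen=True)
class DisplacementTrace:
    """Apex displacement time series, microns, inward-positive.

    ``baseline_window`` is the (start, stop) half-open sample range used
    to zero the trace; it is None for model-generated traces that start
    at rest by construction.  ``interpolated`` flags samples that were
    filled in from neighbouring valid columns.
    """

    time: np.ndarray
    x: np.ndarray
    baseline_window: tuple[int, int] | None = None
    interpolated: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        x = np.asarray(self.x, dtype=float)
        if t.ndim != 1 or x.ndim != 1 or len(t) != len(x):
            raise InvalidTraceError("time and x must be 1-D arrays of equal length")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "x", x)
        if self.interpolated is not None:
            object.__setattr__(
                self, "interpolated", np.asarray(self.interpolated, dtype=bool)
            )

    def __len__(self) -> int:
        return len(self.x)

    @property
    def mad(self) -> float:
        """Maximum apex displacement in microns."""
        return float(np.max(self.x))


@dataclass(frozen=True)
class CCTTriplet:
    """Physical central corneal thickness before / at peak / after recovery.

    All values in microns.  ``group_index`` is stored so the optical
    (air-equivalent) thickness is recoverable as ``cct * group_index``.
    """

    cct_bef: float
    cct_max: float
    cct_aft: float
    group_index: float = CORNEAL_GROUP_INDEX

    def __post_init__(self):
        for name in ("cct_bef", "cct_max", "cct_aft"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidTraceError(f"{name} must be positive and finite, got {v}")


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables for peak-based surface detection.

    Attributes
    ----------
    smooth_px : float
        Gaussian depth-smoothing sigma (pixels) applied per column before
        peak finding; suppresses speckle without displacing band centres.
    min_prominence : float
        Peak prominence threshold as a fraction of the column dynamic
        range.  Relative (not absolute) so segmentation is invariant to
        rescaling the image intensity.
    median_width : int
        Temporal median filter width (columns, odd) applied to the raw
        surface traces; removes single-column speckle outliers.
    min_thickness_um : float
        Minimum optical anterior-posterior separation; the posterior
        search starts this far below the detected anterior peak so the
        tail of the anterior band is never picked up.
    """

    smooth_px: float = 2.0
    min_prominence: float = 0.2
    median_width: int = 9
    min_thickness_um: float = 300.0

    def __post_init__(self):
        if self.smooth_px <= 0 or self.min_prominence <= 0 or self.min_thickness_um <= 0:
            raise InvalidTraceError("segmentation parameters must be positive")
        if self.median_width < 1 or self.median_width % 2 == 0:
            raise InvalidTraceError("median_width must be a positive odd integer")


def _parabolic_refine(col: np.ndarray, idx: int) -> float:
    """Subpixel peak position by parabola through the peak and neighbours."""
    if idx <= 0 or idx >= len(col) - 1:
        return float(idx)
    y0, y1, y2 = col[idx - 1], col[idx], col[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not a local max of the parabola; keep integer position
        return float(idx)
    return float(idx + 0.5 * (y0 - y2) / denom)


def _median_filter_masked(values: np.ndarray, valid: np.ndarray, width: int) -> np.ndarray:
    """Temporal median filter that ignores invalid columns.

    Invalid entries are bridged by nearest-valid interpolation before
    filtering so they cannot contaminate the medians; the caller resets
    them to NaN afterwards.
    """
    if width <= 1 or valid.sum() == 0:
        return values.copy()
    idx = np.arange(len(values))
    filled = np.interp(idx, idx[valid], values[valid])
    return signal.medfilt(filled, kernel_size=width)


def segment_surfaces(m: MScan, params: SegmentationParams | None = None) -> SurfacePair:
    """Detect anterior and posterior corneal interfaces in every A-scan.

    Per column, intensities are Gaussian-smoothed along depth and peaks
    exceeding ``min_prominence`` (relative to the column's dynamic range)
    are located scanning from the top of the image.  The first such peak
    is the anterior interface; the posterior interface is the next peak
    at least ``min_thickness_um`` of optical path below it.  Peak
    positions are refined to subpixel precision by parabolic
    interpolation, then median-filtered along time.

    Parameters
    ----------
    m : MScan
    params : SegmentationParams, optional

    Returns
    -------
    SurfacePair
        Surface positions in optical microns; columns without a
        detection are flagged invalid (NaN position).

    Raises
    ------
    NoSurfaceError
        If the image is uniform or no column yields any peak.
    SegmentationFailureError
        If more than 20% of columns have no valid detection.
    """
    params = params or SegmentationParams()
    img = m.intensity.astype(float)
    if np.ptp(img) == 0.0:
        raise NoSurfaceError("image has no intensity structure (uniform background)")

    # Depth smoothing for the whole image at once (axis 0 = depth).
    sm = ndimage.gaussian_filter1d(img, sigma=params.smooth_px, axis=0, mode="nearest")

    n = m.n_ascan
    min_sep_px = max(1, int(round(params.min_thickness_um / m.axial_pitch)))
    ant_px = np.full(n, np.nan)
    post_px = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)

    for j in range(n):
        col = sm[:, j]
        rng = np.ptp(col)
        if rng == 0.0:
            continue
        peaks, _ = signal.find_peaks(col, prominence=params.min_prominence * rng)
        if len(peaks) == 0:
            continue
        a = peaks[0]
        below = peaks[peaks >= a + min_sep_px]
        if len(below) == 0:
            continue
        p = below[0]
        ant_px[j] = _parabolic_refine(col, a)
        post_px[j] = _parabolic_refine(col, p)
        valid[j] = True

    if valid.sum() == 0:
        raise NoSurfaceError("no corneal interfaces detected in any A-scan")
    invalid_frac = 1.0 - valid.sum() / n
    if invalid_frac > 0.20:
        raise SegmentationFailureError(
            f"{invalid_frac:.0%} of A-scan columns have no valid surface detection"
        )

    ant_px = _median_filter_masked(ant_px, valid, params.median_width)
    post_px = _median_filter_masked(post_px, valid, params.median_width)
    ant_px[~valid] = np.nan
    post_px[~valid] = np.nan

    return SurfacePair(
        anterior=ant_px * m.axial_pitch,
        posterior=post_px * m.axial_pitch,
        valid_mask=valid,
    )


def displacement_from_surfaces(
    s: SurfacePair, m: MScan, baseline_window: tuple[int, int]
) -> DisplacementTrace:
    """Convert the anterior surface trace into apex displacement x(t).

    x(t) is the anterior position minus its mean over the pre-stimulus
    baseline window, in microns, inward-positive.  Invalid columns are
    linearly interpolated in the output trace only (and flagged), never
    in the SurfacePair itself.

    Parameters
    ----------
    baseline_window : (start, stop)
        Half-open sample range lying before stimulus onset; must contain
        at least 10 valid columns.
    """
    start, stop = baseline_window
    n = len(s)
    if not (0 <= start < stop <= n):
        raise InvalidWindowError(f"baseline window {baseline_window} invalid for {n} samples")
    win_valid = s.valid_mask[start:stop]
    if win_valid.sum() < 10:
        raise InvalidWindowError(
            f"baseline window has {int(win_valid.sum())} valid samples; need >= 10"
        )

    idx = np.arange(n)
    anterior = np.interp(idx, idx[s.valid_mask], s.anterior[s.valid_mask])
    baseline = float(np.mean(anterior[start:stop][win_valid]))
    time = m.t0 + idx / m.ascan_rate
    return DisplacementTrace(
        time=time,
        x=anterior - baseline,
        baseline_window=(start, stop),
        interpolated=~s.valid_mask,
    )


def cct_at_instants(
    s: SurfacePair,
    x: DisplacementTrace,
    group_index: float = CORNEAL_GROUP_INDEX,
) -> CCTTriplet:
    """Central corneal thickness before the puff, at peak, and after recovery.

    Optical thickness is posterior minus anterior; physical thickness
    divides by ``group_index``.  The three instants are:

    * ``cct_bef`` — mean over the displacement trace's baseline window;
    * ``cct_max`` — median over +/-2 samples around the displacement
      maximum (robust to a single noisy column at the peak);
    * ``cct_aft`` — mean over post-peak samples that satisfy the recovery
      criterion |x| < 5% of the maximum apex displacement.

    Raises
    ------
    NoRecoveryError
        If no post-peak sample satisfies the recovery criterion.
    InvalidWindowError
        If the trace carries no baseline window.
    """
    if len(s) != len(x):
        raise InvalidTraceError("surfaces and displacement trace must share columns")
    if x.baseline_window is None:
        raise InvalidWindowError("displacement trace has no baseline window")
    if group_index <= 0:
        raise InvalidTraceError("group_index must be positive")

    n = len(s)
    idx = np.arange(n)
    opt = s.posterior - s.anterior  # optical microns; NaN at invalid columns
    valid = s.valid_mask
    opt_filled = np.interp(idx, idx[valid], opt[valid])

    start, stop = x.baseline_window
    cct_bef_opt = float(np.mean(opt_filled[start:stop]))

    imax = int(np.argmax(x.x))
    mad = float(x.x[imax])
    lo, hi = max(0, imax - 2), min(n, imax + 3)
    cct_max_opt = float(np.median(opt_filled[lo:hi]))

    rec = (idx > imax) & (np.abs(x.x) < 0.05 * mad) if mad > 0 else np.zeros(n, bool)
    if not rec.any():
        raise NoRecoveryError(
            "no post-peak samples with |x| < 5% MAD; cornea did not recover in-record"
        )
    cct_aft_opt = float(np.mean(opt_filled[rec]))

    return CCTTriplet(
        cct_bef=cct_bef_opt / group_index,
        cct_max=cct_max_opt / group_index,
        cct_aft=cct_aft_opt / group_index,
        group_index=group_index,
    )
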