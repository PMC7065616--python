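"""Synthetic air-puff OCT data generation.

No public repository of air-puff M-scans with synchronized pressure
traces exists, so every downstream stage is exercised on synthetic data
with known ground truth.  The generator chain is:

1.  :func:`generate_force_pulse` — a smooth, zero-ended air-puff force
    pulse.  The default emulates the study conditions: 120.8 mN peak
    over a 1600-sample record at 50 kHz (32 ms).
2.  :func:`simulate_eye_response` — the Kelvin-Voigt apex displacement
    driven by that pulse (delegates to :mod:`corneapuff.kv_simulator`).
3.  :func:`render_mscan` — a speckled depth-vs-time image with a bright
    anterior and posterior corneal interface following the displacement,
    including a slight thickness compression at maximum deformation.
4.  :func:`generate_cohort` — eyes x conditions x repetitions record
    collections for the two synthetic experiment designs (cyclic
    intraocular-pressure inflation, and corneal cross-linking stages),
    each record carrying its ground truth.

Every generator is a pure function of (spec, seed): identical inputs
reproduce bitwise-identical outputs.

The rendering model is deliberately simple — two Gaussian bands per
A-scan with fully-developed-speckle-style multiplicative noise and an
additive Gaussian floor; it emulates interface brightness and speckle
statistics, not diffraction, shadowing, or full-field corneal shape.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidSpecError, OutOfRangeError
from .force_calibration import CalibrationModel, ForceTrace
from .kv_simulator import KVParams, kv_response
from .mscan_segmentation import CORNEAL_GROUP_INDEX, DisplacementTrace, MScan

__all__ = [
    "PulseSpec",
    "EyePhantomSpec",
    "CohortSpec",
    "CohortRecord",
    "AffineMap",
    "CXL_STAGES",
    "DEFAULT_CALIBRATION",
    "generate_force_pulse",
    "simulate_eye_response",
    "render_mscan",
    "generate_cohort",
    "write_mscan",
    "read_mscan",
    "write_trace_csv",
    "read_trace_csv",
    "save_record",
]

#: Cross-linking protocol stages: epithelium removed, riboflavin-saturated,
#: and riboflavin + UV-A irradiated (complete treatment).
CXL_STAGES = ("EPI_OFF", "RS", "RS_UV")

#: Pressure-sensor to force slope reproducing the instrument calibration
#: pair 18.18 kPa -> 120.8 mN.
DEFAULT_CALIBRATION = CalibrationModel(slope=0.006645, intercept=0.0,
                                       fit_r2=1.0, n_points=2)


# ---------------------------------------------------------------------------
# Force pulse
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseSpec:
    """Air-puff force pulse specification.

    Attributes
    ----------
    peak_force : float
        Pulse maximum in newtons; default 0.1208 N.
    rise_time : float
        Seconds from pulse onset to the peak.
    total_duration : float
        Record length in seconds; default 32 ms (1600 samples at 50 kHz).
    shape : {"raised_cosine", "gamma"}
        Raised cosine: half-cosine rise over ``rise_time``, half-cosine
        fall filling the remaining support — smooth and exactly
        zero-ended.  Gamma: a skewed gamma-like bump peaking at
        ``rise_time`` with a cosine taper pinning the tail to zero.
    sample_rate : float
        Hz; default 50 kHz, the A-scan rate, so force and image columns
        share a clock.
    onset_delay : float
        Quiet zero-force margin at the start of the record (mirrored at
        the end), seconds.  A non-zero delay provides the pre-stimulus
        baseline and post-recovery windows the analysis needs.
    """

    peak_force: float = 0.1208
    rise_time: float = 0.016
    total_duration: float = 0.032
    shape: str = "raised_cosine"
    sample_rate: float = 50_000.0
    onset_delay: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.peak_force) or self.peak_force <= 0:
            raise InvalidSpecError(f"peak_force must be > 0, got {self.peak_force}")
        if self.total_duration <= 0 or self.sample_rate <= 0:
            raise InvalidSpecError("total_duration and sample_rate must be positive")
        if not (0 < self.rise_time < self.total_duration):
            raise InvalidSpecError("rise_time must lie in (0, total_duration)")
        if self.onset_delay < 0:
            raise InvalidSpecError("onset_delay must be >= 0")
        if self.onset_delay + self.rise_time >= self.total_duration - self.onset_delay:
            raise InvalidSpecError("onset_delay + rise_time must leave room for the fall")
        if self.shape not in ("raised_cosine", "gamma"):
            raise InvalidSpecError(f"unknown pulse shape {self.shape!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration * self.sample_rate))

    @property
    def peak_time(self) -> float:
        """Nominal time of the pulse maximum."""
        return self.onset_delay + self.rise_time


def generate_force_pulse(spec: PulseSpec) -> ForceTrace:
    """Generate the air-puff force pulse described by ``spec``.

    The trace has ``round(total_duration * sample_rate)`` samples,
    starts and ends at exactly 0 N, is non-negative throughout, and
    attains ``peak_force`` within one sample of the nominal peak time.
    """
    n = spec.n_samples
    if n < 4:
        raise InvalidSpecError("pulse must contain at least 4 samples")
    t = np.arange(n) / spec.sample_rate
    t_last = t[-1]
    t_on = spec.onset_delay
    t_peak = spec.peak_time
    t_off = t_last - spec.onset_delay  # support end; symmetric quiet margin
    fall = t_off - t_peak
    if fall <= 0:
        raise InvalidSpecError("pulse support leaves no room for the falling flank")

    F = np.zeros(n)
    if spec.shape == "raised_cosine":
        rising = (t >= t_on) & (t <= t_peak)
        falling = (t > t_peak) & (t <= t_off)
        F[rising] = 0.5 * spec.peak_force * (1 - np.cos(np.pi * (t[rising] - t_on) / spec.rise_time))
        F[falling] = 0.5 * spec.peak_force * (1 + np.cos(np.pi * (t[falling] - t_peak) / fall))
    else:  # gamma-like skewed bump, peak at t_peak, tapered to zero at t_off
        alpha = 3.0
        tau = (t - t_on) / spec.rise_time
        active = (t >= t_on) & (t <= t_off)
        with np.errstate(invalid="ignore"):
            bump = np.where(tau > 0, np.power(np.clip(tau, 0, None), alpha)
                            * np.exp(alpha * (1 - tau)), 0.0)
        taper = np.ones(n)
        tail = (t > t_off - 0.1 * (t_off - t_on)) & (t <= t_off)
        s = (t[tail] - (t_off - 0.1 * (t_off - t_on))) / (0.1 * (t_off - t_on))
        taper[tail] = 0.5 * (1 + np.cos(np.pi * s))
        F[active] = spec.peak_force * (bump * taper)[active]
        F[F < 0] = 0.0
        # renormalise so the grid maximum equals peak_force exactly
        F *= spec.peak_force / F.max()

    return ForceTrace(time=t, force=F)


# ---------------------------------------------------------------------------
# Eye phantom and M-scan rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EyePhantomSpec:
    """A synthetic eye standing in for an ex vivo globe.

    Attributes
    ----------
    kv : KVParams
        Effective apex stiffness and damping of the phantom.
    baseline_cct : float
        Resting physical central corneal thickness, microns.
    compression_fraction : float
        Relative thickness reduction at maximum deformation, in [0, 1).
        Thickness shrinks linearly with x(t)/max(x) up to this fraction
        and returns to baseline with recovery.
    anterior_depth : float
        Resting anterior surface position below the image top, microns.
    group_index : float
        Corneal group refractive index; rendered optical thickness is
        physical thickness x group_index.
    speckle_contrast : float
        0 = noiseless; 1 = fully developed speckle (exponential
        intensity statistics); intermediate values interpolate.
    background_level : float
        Additive intensity floor (arbitrary units of the 16-bit image).
    peak_intensity : float
        Interface band amplitude above background.
    band_sigma_px : float
        Gaussian half-width of each interface band, pixels.
    seed : int
        Default speckle seed for :func:`render_mscan`.
    """

    kv: KVParams = field(default_factory=lambda: KVParams(k=120.0, c=0.15))
    baseline_cct: float = 1000.0
    compression_fraction: float = 0.03
    anterior_depth: float = 300.0
    group_index: float = CORNEAL_GROUP_INDEX
    speckle_contrast: float = 0.5
    background_level: float = 500.0
    peak_intensity: float = 20_000.0
    band_sigma_px: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.baseline_cct <= 0:
            raise InvalidSpecError("baseline_cct must be positive")
        if not (0 <= self.compression_fraction < 1):
            raise InvalidSpecError("compression_fraction must lie in [0, 1)")
        if self.anterior_depth < 0:
            raise InvalidSpecError("anterior_depth must be >= 0")
        if self.group_index <= 0 or self.speckle_contrast < 0:
            raise InvalidSpecError("group_index must be > 0 and speckle_contrast >= 0")

    @property
    def optical_cct(self) -> float:
        """Resting optical (air-equivalent) thickness, microns."""
        return self.baseline_cct * self.group_index


def simulate_eye_response(force: ForceTrace, phantom: EyePhantomSpec) -> DisplacementTrace:
    """Apex displacement of the phantom under the given force pulse.

    Delegates to the Kelvin-Voigt solver; displacement is inward-positive
    microns starting from rest.
    """
    return kv_response(force, phantom.kv)


def render_mscan(
    x: DisplacementTrace,
    phantom: EyePhantomSpec,
    axial_pitch: float = 8.0,
    depth_px: int = 420,
    seed: int | None = None,
) -> MScan:
    """Render a speckled M-scan of the phantom following displacement x(t).

    Each A-scan column contains two Gaussian interface bands: the
    anterior at ``anterior_depth + x(t)`` and the posterior one optical
    thickness below it, with thickness compressed linearly in
    ``x(t)/max(x)`` up to ``compression_fraction`` at the peak.
    Multiplicative exponential speckle and an additive Gaussian floor
    are applied, and the image is quantised to 16-bit.

    Parameters
    ----------
    axial_pitch : float
        Microns in air per depth pixel.
    depth_px : int
        Number of depth rows; must accommodate both surfaces at all times.
    seed : int, optional
        Speckle seed; defaults to ``phantom.seed``.  Identical seeds
        yield bitwise-identical images.

    Raises
    ------
    OutOfRangeError
        If either surface leaves the imaged depth range, naming the
        first offending A-scan column.
    """
    if axial_pitch <= 0 or depth_px < 4:
        raise InvalidSpecError("axial_pitch must be > 0 and depth_px >= 4")
    xs = x.x
    n = len(xs)
    xmax = float(np.max(xs))
    rel = xs / xmax if xmax > 0 else np.zeros(n)

    thickness_opt = phantom.optical_cct * (1.0 - phantom.compression_fraction * rel)
    ant_um = phantom.anterior_depth + xs
    post_um = ant_um + thickness_opt

    ant_px = ant_um / axial_pitch
    post_px = post_um / axial_pitch
    margin = 3.0 * phantom.band_sigma_px
    bad = np.nonzero((ant_px < margin) | (post_px > depth_px - 1 - margin))[0]
    if len(bad) > 0:
        raise OutOfRangeError(
            f"surface leaves depth range at A-scan column {int(bad[0])} "
            f"(anterior {ant_um[bad[0]]:.0f} um, posterior {post_um[bad[0]]:.0f} um)"
        )

    rows = np.arange(depth_px, dtype=float)[:, None]
    sig2 = 2.0 * phantom.band_sigma_px**2
    clean = phantom.background_level + phantom.peak_intensity * (
        np.exp(-((rows - ant_px[None, :]) ** 2) / sig2)
        + np.exp(-((rows - post_px[None, :]) ** 2) / sig2)
    )

    rng = np.random.default_rng(phantom.seed if seed is None else seed)
    if phantom.speckle_contrast > 0:
        factor = 1.0 + phantom.speckle_contrast * (rng.exponential(1.0, clean.shape) - 1.0)
        factor = np.clip(factor, 0.0, None)
        img = clean * factor
        img += rng.normal(0.0, 0.1 * phantom.background_level, clean.shape)
    else:
        img = clean

    img = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    return MScan(intensity=img, axial_pitch=axial_pitch,
                 ascan_rate=1.0 / (x.time[1] - x.time[0]), t0=float(x.time[0]))


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AffineMap:
    """Affine map value -> slope * value + intercept (e.g. mm Hg -> N/m)."""

    slope: float
    intercept: float

    def __call__(self, v: float) -> float:
        return self.slope * float(v) + self.intercept


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort for either experiment.

    Inflation design: ``iop_levels`` are visited in ascending then
    descending order (the top level not duplicated) and the phantom
    stiffness follows ``k_of_iop``.  Cross-linking (CXL) design: every
    ``stage`` x ``iop_level`` combination is measured ``repetitions``
    times per eye, with damping and thickness per stage.

    Attributes
    ----------
    iop_levels : tuple of float
        Intraocular pressure levels, mm Hg, within [5, 35].
    k_of_iop : AffineMap
        Strictly increasing mm Hg -> N/m map for the phantom stiffness.
        Default 80 + 4*IOP, which spans maximum displacements of roughly
        0.5-1.2 mm under the default 120.8 mN pulse.
    base_c : float
        Damping (N*s/m) used in the inflation design.
    stages : tuple of str or None
        CXL stages; None selects the inflation design.
    c_of_stage, cct_of_stage, k_scale_of_stage : mappings
        Per-stage damping (N*s/m), baseline thickness (um) and stiffness
        multiplier for the CXL design.  Defaults emulate the reported
        qualitative picture: thickness shrinking ~36% over the protocol
        (dehydration) and a viscosity-dominated stiffening.
    eyes_per_condition : int
        Number of eyes, each measured under every condition.
    repetitions : int
        Consecutive measurements per eye and condition.
    eye_k_sigma : float
        Relative between-eye stiffness variability (lognormal-free
        Gaussian multiplier), 0 for noiseless phantoms.
    pulse : PulseSpec
        Shared stimulus; default 120.8 mN raised cosine, 32 ms record at
        50 kHz with a 4 ms quiet margin for baseline and recovery.
    phantom : EyePhantomSpec
        Template phantom; its ``kv`` and ``seed`` are overridden per
        record.
    axial_pitch, depth_px : rendering geometry.
    calibration : CalibrationModel
        Used to express the stimulus as the pressure trace an internal
        sensor would record.
    seed : int
        Master seed; all per-record seeds derive from it.
    """

    iop_levels: tuple = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0)
    k_of_iop: AffineMap = field(default_factory=lambda: AffineMap(slope=4.0, intercept=80.0))
    base_c: float = 0.15
    stages: tuple | None = None
    c_of_stage: dict = field(default_factory=lambda: {"EPI_OFF": 0.12, "RS": 0.18, "RS_UV": 0.24})
    cct_of_stage: dict = field(default_factory=lambda: {"EPI_OFF": 1000.0, "RS": 850.0, "RS_UV": 640.0})
    k_scale_of_stage: dict = field(default_factory=lambda: {"EPI_OFF": 1.0, "RS": 0.9, "RS_UV": 1.05})
    eyes_per_condition: int = 5
    repetitions: int = 1
    eye_k_sigma: float = 0.05
    pulse: PulseSpec = field(default_factory=lambda: PulseSpec(
        peak_force=0.1208, rise_time=0.012, total_duration=0.032,
        shape="raised_cosine", sample_rate=50_000.0, onset_delay=0.004))
    phantom: EyePhantomSpec = field(default_factory=EyePhantomSpec)
    axial_pitch: float = 8.0
    depth_px: int = 420
    calibration: CalibrationModel = DEFAULT_CALIBRATION
    seed: int = 0

    def __post_init__(self):
        if self.eyes_per_condition < 1 or self.repetitions < 1:
            raise InvalidSpecError("eyes_per_condition and repetitions must be >= 1")
        if len(self.iop_levels) == 0:
            raise InvalidSpecError("iop_levels must be non-empty")
        if any(not (5.0 <= v <= 35.0) for v in self.iop_levels):
            raise InvalidSpecError("iop_levels must lie within [5, 35] mm Hg")
        if self.k_of_iop.slope <= 0:
            raise InvalidSpecError("k_of_iop must be strictly increasing (slope > 0)")
        if self.stages is not None:
            for st in self.stages:
                if st not in self.c_of_stage or st not in self.cct_of_stage:
                    raise InvalidSpecError(f"stage {st!r} missing from stage maps")
        if self.eye_k_sigma < 0:
            raise InvalidSpecError("eye_k_sigma must be >= 0")
        object.__setattr__(self, "iop_levels", tuple(float(v) for v in self.iop_levels))

    @classmethod
    def inflation(cls, **kw) -> "CohortSpec":
        """Cyclic inflation design: IOP 5 -> 35 -> 5 mm Hg in 5 mm Hg steps."""
        kw.setdefault("stages", None)
        return cls(**kw)

    @classmethod
    def cxl(cls, **kw) -> "CohortSpec":
        """Cross-linking design: 3 stages x 2 IOP levels, repeated measurements."""
        kw.setdefault("stages", CXL_STAGES)
        kw.setdefault("iop_levels", (15.0, 25.0))
        kw.setdefault("eyes_per_condition", 13)
        kw.setdefault("repetitions", 5)
        return cls(**kw)


@dataclass(frozen=True)
class CohortRecord:
    """One simulated stimulation with its full ground truth.

    The M-scan is rendered on demand via :meth:`render` so that
    truth-level analyses and record counting do not pay the imaging
    cost; rendering with the stored seed is deterministic.
    """

    eye_id: int
    condition: str
    phase: str          # "ascending" / "descending" / "NA"
    iop: float
    stage: str          # CXL stage or "NA"
    repetition: int
    seed: int
    phantom: EyePhantomSpec
    force: ForceTrace
    pressure_kpa: np.ndarray
    x_true: DisplacementTrace
    axial_pitch: float
    depth_px: int
    truth: dict
    calibration: CalibrationModel = DEFAULT_CALIBRATION

    def render(self) -> MScan:
        """Render the speckled M-scan for this record (deterministic in seed)."""
        return render_mscan(self.x_true, self.phantom,
                            axial_pitch=self.axial_pitch,
                            depth_px=self.depth_px, seed=self.seed)

    @property
    def baseline_window(self) -> tuple[int, int]:
        """Pre-onset sample range usable as the displacement baseline."""
        spec_onset = self.truth["onset_delay_s"]
        stop = max(12, int(spec_onset * self.truth["sample_rate_hz"]) - 5)
        return (0, stop)


def _record_truth(phantom: EyePhantomSpec, x: DisplacementTrace, pulse: PulseSpec) -> dict:
    mad = float(np.max(x.x))
    return {
        "k_N_per_m": phantom.kv.k,
        "c_Ns_per_m": phantom.kv.c,
        "mad_um": mad,
        "cct_bef_um": phantom.baseline_cct,
        "cct_max_um": phantom.baseline_cct * (1.0 - phantom.compression_fraction),
        "cct_aft_um": phantom.baseline_cct,
        "compression_fraction": phantom.compression_fraction,
        "group_index": phantom.group_index,
        "onset_delay_s": pulse.onset_delay,
        "sample_rate_hz": pulse.sample_rate,
        "peak_force_N": pulse.peak_force,
    }


def generate_cohort(spec: CohortSpec) -> list[CohortRecord]:
    """Generate the full record collection for a cohort design.

    One record per eye x condition x repetition.  For the inflation
    design the condition sequence is the ascending IOP levels followed
    by the descending ones with the top level not repeated (a cycle of
    ``2 * len(levels) - 1`` conditions).  Ground truth (k, c, true MAD
    and CCT triplet) is stored on every record so recovery tests never
    re-derive it from images.
    """
    master = np.random.SeedSequence(spec.seed)
    eye_rng = np.random.default_rng(master.spawn(1)[0])
    # per-eye stiffness multipliers, shared across all conditions of an eye
    eye_scale = 1.0 + spec.eye_k_sigma * eye_rng.standard_normal(spec.eyes_per_condition)
    eye_scale = np.clip(eye_scale, 0.5, 1.5)

    if spec.stages is None:
        asc = sorted(spec.iop_levels)
        desc = asc[-2::-1]
        conditions = [("ascending", iop, "NA") for iop in asc] + \
                     [("descending", iop, "NA") for iop in desc]
    else:
        conditions = [("NA", iop, st) for st in spec.stages for iop in spec.iop_levels]

    force = generate_force_pulse(spec.pulse)
    pressure = (force.force - spec.calibration.intercept) / spec.calibration.slope

    records: list[CohortRecord] = []
    counter = 0
    for eye in range(spec.eyes_per_condition):
        for phase, iop, stage in conditions:
            k = spec.k_of_iop(iop) * eye_scale[eye]
            if stage != "NA":
                k *= spec.k_scale_of_stage[stage]
                c = spec.c_of_stage[stage]
                cct = spec.cct_of_stage[stage]
            else:
                c = spec.base_c
                cct = spec.phantom.baseline_cct
            for rep in range(spec.repetitions):
                counter += 1
                rec_seed = int(np.random.SeedSequence(
                    entropy=spec.seed, spawn_key=(counter,)).generate_state(1)[0] % (2**31))
                phantom = dataclasses.replace(spec.phantom, kv=KVParams(k=k, c=c),
                                              baseline_cct=cct, seed=rec_seed)
                x_true = kv_response(force, phantom.kv)
                cond = f"{stage}@{iop:g}mmHg" if stage != "NA" else f"{iop:g}mmHg"
                records.append(CohortRecord(
                    eye_id=eye, condition=cond, phase=phase, iop=iop, stage=stage,
                    repetition=rep, seed=rec_seed, phantom=phantom, force=force,
                    pressure_kpa=pressure, x_true=x_true,
                    axial_pitch=spec.axial_pitch, depth_px=spec.depth_px,
                    truth=_record_truth(phantom, x_true, spec.pulse),
                    calibration=spec.calibration))
    return records


# ---------------------------------------------------------------------------
# File I/O: TIFF + JSON sidecar, CSV traces, ground-truth JSON
# ---------------------------------------------------------------------------

def write_mscan(m: MScan, tiff_path) -> None:
    """Write an M-scan as 16-bit grayscale TIFF plus a JSON metadata sidecar."""
    import tifffile

    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, np.asarray(m.intensity, dtype=np.uint16))
    sidecar = {"axial_pitch_um": m.axial_pitch, "ascan_rate_hz": m.ascan_rate,
               "t0_s": m.t0}
    tiff_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_mscan(tiff_path) -> MScan:
    """Read an M-scan written by :func:`write_mscan`."""
    import tifffile

    tiff_path = Path(tiff_path)
    img = tifffile.imread(tiff_path)
    meta = json.loads(tiff_path.with_suffix(".json").read_text())
    return MScan(intensity=img, axial_pitch=meta["axial_pitch_um"],
                 ascan_rate=meta["ascan_rate_hz"], t0=meta.get("t0_s", 0.0))


def write_trace_csv(time_s, values, path) -> None:
    """Write a time series as CSV with header ``time_s,value``."""
    import pandas as pd

    pd.DataFrame({"time_s": np.asarray(time_s, float),
                  "value": np.asarray(values, float)}).to_csv(path, index=False)


def read_trace_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a ``time_s,value`` CSV back into arrays."""
    import pandas as pd

    df = pd.read_csv(path)
    return df["time_s"].to_numpy(), df["value"].to_numpy()


def save_record(rec: CohortRecord, out_dir, render: bool = True) -> Path:
    """Persist one cohort record: M-scan TIFF+sidecar, traces, truth JSON.

    Returns the record directory.
    """
    out = Path(out_dir) / f"eye{rec.eye_id:02d}_{rec.condition}_{rec.phase}_rep{rec.repetition}"
    out.mkdir(parents=True, exist_ok=True)
    if render:
        write_mscan(rec.render(), out / "mscan.tiff")
    write_trace_csv(rec.force.time, rec.pressure_kpa, out / "pressure_kpa.csv")
    write_trace_csv(rec.force.time, rec.force.force, out / "force_n.csv")
    write_trace_csv(rec.x_true.time, rec.x_true.x, out / "displacement_true_um.csv")
    truth = dict(rec.truth)
    truth.update({"eye_id": rec.eye_id, "condition": rec.condition,
                  "phase": rec.phase, "repetition": rec.repetition,
                  "seed": rec.seed})
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return out
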