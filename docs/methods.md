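# Methods

This note documents the models, parameter choices and numerical
decisions behind `corneapuff`, in the spirit of a methods appendix: what
is being computed, under which assumptions, and what the synthetic
validation does and does not demonstrate.

## The measurement model

One stimulation produces two synchronized observables on a shared
50 kHz clock: an OCT M-scan (depth × time intensity image of the
corneal apex, 1600 A-scan columns over 32 ms) and the tonometer's
internal pressure reading. The analysis chain is

1. **Force calibration.** The pressure sensor does not measure the
   force on the cornea directly; a static calibration against a
   strain gauge (itself calibrated with 1–10 g reference weights,
   g = 9.81 m/s²) links the two. We model the relation as affine,
   fitted by ordinary least squares, and report R² so any
   nonlinearity is visible. The default slope 0.006645 N/kPa
   reproduces the instrument-scale pair 18.18 kPa ↔ 120.8 mN. The
   sensor-voltage→pressure stage is treated as upstream: inputs are
   already in kPa, and a second affine stage can be composed if raw
   voltages are supplied.
2. **Surface segmentation.** Per A-scan column, intensities are
   Gaussian-smoothed along depth (σ = 2 px) and peaks with prominence
   above 20 % of the column's dynamic range are located from the top
   of the image. The first peak is the anterior interface; the next
   peak at least 300 µm of optical path deeper is the posterior one.
   Peak positions are refined by parabolic interpolation through the
   peak and its two neighbours, then median-filtered along time
   (width 9 columns) to remove speckle outliers. Prominence is
   *relative*, so segmentation is invariant to rescaling the image;
   positions are continuous µm with a 0-based, top-of-image origin.
   Columns without a detection are flagged invalid — never silently
   interpolated in the surface data; more than 20 % invalid columns
   is a hard failure.
3. **Displacement and thickness.** Apex displacement is the anterior
   position minus its mean over a pre-stimulus baseline window
   (≥ 10 valid samples), inward-positive; invalid columns are
   linearly interpolated in the derived trace only, and flagged.
   Optical thickness (posterior − anterior) is converted to physical
   thickness with the corneal group index 1.376 (1310 nm); the index
   is stored with the result so optical values remain recoverable.
   The three thickness instants are: mean over the baseline window
   (before), median over ±2 samples around the displacement maximum
   (at peak — robust to one noisy column), and mean over post-peak
   samples with |x| < 5 % of the maximum displacement (after
   recovery). The 5 % recovery criterion is our own operational
   definition, chosen because it is robust and testable.
4. **Hysteresis loop and descriptors.** Force is linearly resampled
   onto the displacement timestamps; the loop splits at the first
   occurrence of the maximum displacement. The hysteresis area is
   computed as the time-parameterised line integral ∮F dx
   (trapezoidal shoelace, loop closed last→first) rather than as two
   x-parameterised integrals: the two agree to numerical precision
   whenever each branch is monotone in x (property-tested over random
   monotone loops), but the line integral also handles non-monotone
   segments and post-recovery ringing (x < 0) without re-sorting.
   Displacements are carried in µm and converted to metres inside the
   energy and slope computations, so HA is in joules (≈ 1e-5–1e-4 J
   at the default force/displacement scale) and slopes in N/m. The
   10 %-MAD point is located on the loading branch only, first
   crossing, linearly interpolated; window membership for the 120 µm
   low/high-strain fits uses closed intervals in x and requires ≥ 3
   samples; the low-strain window must fit inside the loading span
   (10 % MAD + 120 µm ≤ MAD) or the slope is reported undefined.
   Descriptors that cannot be computed are returned as NaN with an
   explicit reason, never silently dropped.

## The Kelvin–Voigt phantom

The synthetic cornea is a massless spring–dashpot pair in parallel:

    c·x′(t) + k·x(t) = F(t),   x(0) = 0,

with k the effective apex stiffness (N/m) and c the damping (N·s/m).
An inertial term (m·x″) is deliberately out of scope: over the 10-ms
pulse time scale the first-order element already reproduces the
qualitative phenomenology (finite deformation, lagged recovery, open
loop whose area grows with c and vanishes as c → 0). Integration is an
exact per-step exponential update assuming F is piecewise linear
between samples — unconditionally stable, tolerance-free, and verified
against the closed-form step and sinusoidal responses (relative error
< 1e-6, loop area within 1 % of πcωX²) and a dt/100 dense-step solver.
For c = 0 the equation is algebraic and x = F/k exactly.

## The synthetic data generator

Defaults encode the study conditions of the instrument the package
models:

| parameter | default | rationale |
| --- | --- | --- |
| peak force | 120.8 mN | instrument calibration peak (18.18 kPa sensor reading) |
| record | 1600 samples at 50 kHz (32 ms) | one M-scan of 1600 A-scans |
| pulse shape | raised cosine, peak mid-record | smooth, zero-ended; the true pneumatic profile is not parameterised anywhere, so this is a stand-in, not a claim about the device |
| onset margin | 4 ms (cohort pipeline) | provides the pre-stimulus baseline and post-recovery windows; the bare pulse defaults to no margin with the peak at mid-record |
| k(IOP) | 80 + 4·IOP N/m | spans MAD ≈ 0.5–1.2 mm over IOP 5–35 mm Hg under the default pulse, the magnitude range of ex vivo porcine corneas |
| c | 0.15 N·s/m (inflation) | time constant c/k ≈ 1 ms ≪ pulse width: moderately open loops (HR ≈ 30–40 %) with in-record recovery |
| baseline CCT | 1000 µm | porcine central corneal thickness scale |
| compression fraction | 0.03 | slight thickness dip at peak deformation, returning to baseline on recovery |
| group index | 1.376 | corneal refractive index at 1310 nm |
| speckle contrast | 0.5 | partially developed speckle; contrast 1 = fully developed (exponential intensity) |
| axial pitch / depth | 8 µm/px × 420 px | accommodates both interfaces at maximum deflection with margin |
| eye-to-eye variability | 5 % σ on k | between-animal stiffness spread |

Rendering places two Gaussian bands (σ = 2 px) per column at the
anterior position (resting depth + x(t)) and one optical thickness
below, with thickness shrinking linearly in x(t)/max(x) up to the
compression fraction; multiplicative exponential speckle
(factor 1 + contrast·(E−1), E ~ Exp(1)) and an additive Gaussian floor
are applied and the image is quantised to 16 bits. Every generator is
a pure function of (spec, seed); per-record seeds derive from the
cohort master seed via `numpy` seed sequences, so cohorts are
reproducible bitwise.

**What the phantom does not emulate.** Only apex-column dynamics are
modelled — no full-field corneal shape, air-jet fluid dynamics,
whole-globe retraction, scleral or anterior-chamber contributions, or
the inflation-cycle tissue memory of real corneas (the phantom is
memoryless by construction, so ascending and descending pressure
sweeps must coincide — a deliberate null). The linear Kelvin–Voigt
element has no strain stiffening, so synthetic loading curves are not
J-shaped and the high-strain slope does not exceed the low-strain
slope as it does on tissue; J-curve behaviour is exercised with
analytic loading curves instead. Passing synthetic tests therefore
demonstrates the correctness of the *analysis* (segmentation accuracy,
integral and slope definitions, units, statistics, reproducibility),
not the biological fidelity of the phantom.

## Experiment designs

The cyclic inflation design visits IOP levels 5→35→5 mm Hg in
5 mm Hg steps (13 conditions, top level not duplicated) with phantom
stiffness following k(IOP). The cross-linking design measures three
treatment stages (epithelium off; riboflavin-saturated; riboflavin +
UV) at 15 and 25 mm Hg with five repetitions per eye; per-stage
defaults thin the cornea by 36 % over the protocol (dehydration) and
raise damping, with a mild stiffness dip after saturation — the
qualitative pattern reported for the procedure. Group comparisons use
the classical pooled-variance two-sample Student's t test (α = 0.05)
— the unpaired form is used for stage comparisons as in the original
analysis convention, with eye identity preserved in the output tables
so a paired reanalysis remains possible — and associations use
Pearson's R. The thickness-corrected displacement MAD/CCT_bef is
included in the metric set.

## Verification problem sizes

The test-suite and acceptance-script computations use: 1000 random
monotone loops for the area-oracle identity; 10⁴-sample analytic loops
for the worked-example descriptors; 50 rendered speckled phantoms
(speckle contrast 0.5, 8 µm/px) spanning MAD ≈ 220–1170 µm for
segmentation recovery; and a rendered inflation cohort of 2 eyes × 13
conditions for the trend checks. These sizes give stable statistics
(recovery bias ≈ 0.5 %, RMSE ≈ 2 µm, trend correlations insensitive to
the seed) while keeping a full run in the tens of seconds.

## Known limitations

- The hysteresis area at the default force/displacement scale is
  bounded near 0.1 mJ (peak force ~0.12 N over ~1 mm); values are
  reported in SI joules without rescaling.
- A fixed latency between the pressure-sensor and OCT streams is not
  modelled; alignment assumes a shared trigger. A constant offset
  would bias HA and the slopes.
- Segmentation assumes exactly two dominant interfaces per column;
  multi-layer media or strong shadowing are out of scope.
- The affine calibration is a modelling choice; strongly nonlinear
  sensors would need a higher-order stage composed upstream.
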