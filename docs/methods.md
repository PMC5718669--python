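# Methods

## Problem and scope

Wide-beam (cone-beam) CT deposits an axial dose profile D(z) whose scatter
tails extend far beyond the 100 mm pencil ionization chamber that defines the
conventional CTDI100, so the classical index truncates a substantial part of
the profile integral. `cbctdose` implements the dosimetric statistics that
remain well defined for a single-rotation cone beam:

* the dose profile integral DPI_l = ∫_{−l/2}^{l/2} D(z) dz over a stated
  longitudinal range l,
* the aperture-normalized index CTDI_a,l = DPI_l / T, where T is the
  **actual** beam width at isocenter (the physical collimation, 1–3 cm wider
  than the console's nominal reconstruction width),
* the weighted index CTDIw,l = ½·CTDI_a,l(center) + ½·mean CTDI_a,l(four
  peripheral points 10 mm below the phantom surface, 90° apart),
* the scan-level mean CTDIw,l over the ten nominal collimations (1–10 cm) and
  the dose–length product DLP = mean CTDIw,l × T,
* the truncated pencil-chamber variants CTDI100, D̄100 = DPI(100 mm)/100 and
  CTDI300, and the central ray dose f(0) = D(0).

The ½/½ center/periphery weights follow the "plausible relative function
variation" argument for wide beams; the conventional ⅓/⅔ weighting is
available through `CtdiConfig(weights=(1/3, 2/3))` but is never the default.

Out of scope: photon transport (the profiles are either synthetic or read
from files), image reconstruction, and effective-dose conversion factors.

## The synthetic profile model

Since a cone-beam profile can be built as a superposition of narrow-beam
responses, the generator convolves the aperture rectangle of width T with a
unit-area narrow-beam line spread function

    lsf(z) = (1 − η)·g(z; σ) + (η / 2d)·exp(−|z| / d),

where g is a unit-area Gaussian (a Dirac impulse for σ = 0). This is the
simplest kernel reproducing the three behaviours phantom dosimetry of wide
beams exhibits: long exponential scatter tails, a central dose that
saturates with collimation, and an exactly aperture-constant full integral.
For σ = 0 the convolution has the closed form used as an oracle throughout
the tests:

* f(0) = h·(1 − η·e^(−T/2d)),
* ∫ D dz = h·T (unit-area kernel preserves the rectangle's area),
* inside the beam D(z) = h[(1−η) + η(1 − ½(e^(−(T/2−z)/d) + e^(−(T/2+z)/d)))],
  with the matching piecewise-exponential expression outside.

Parameters, with units and defaults (a 125 kVp head/body technique,
**illustrative, not fitted** — no quantitative claim depends on them):

| parameter | meaning | head ctr / per | body ctr / per |
|---|---|---|---|
| h (cGy) | equilibrium (infinite-beam) dose | 8.8 / 8.8 | 3.1 / 5.5 |
| η (–) | scatter fraction of the kernel area | 0.60 / 0.45 | 0.75 / 0.50 |
| d (mm) | scatter tail decay length | 60 / 40 | 90 / 60 |
| σ (mm) | Gaussian penumbra of the aperture edge | 0 | 0 |
| noise CV | multiplicative Gaussian noise per sample | 0.01 | 0.01 |

Center kernels must be at least as broad as peripheral ones (η and d), the
behaviour seen in phantom measurements. Profiles are symmetric in z: gantry
rotation smears out the anode heel effect. Noise is multiplicative Gaussian
at 1% CV by default — the statistical-uncertainty regime of a well-converged
Monte Carlo profile — clipped at zero; one integer seed drives one
position-major stream (center, then 12/3/6/9 o'clock), so profile sets are
bit-reproducible.

What the generator does **not** emulate: bowtie-filter fluence shaping,
beam-hardening along the tails, phantom-end scatter deficits, or any 2D/3D
dose structure. Passing tests therefore demonstrate the correctness of the
integration/weighting pipeline and its invariants, not agreement of absolute
cGy values with any physical system — absolute values require a transport
calculation or measurement, which this package deliberately takes as input.

## Numerical choices

* Default grid: 0.5 mm spacing, ±450 mm span (covers the 900 mm body
  integration range). The generator refuses grids with half-length below
  3d + T ("truncation" error) rather than silently clipping tails.
* Integrals: trapezoid rule with linear interpolation of the endpoint values
  when ±l/2 falls between samples. At 0.5 mm spacing Simpson's rule offers
  no measurable benefit and complicates even sample counts.
* Aperture-edge sampling: when a sharp edge lands exactly on a grid point it
  is assigned half the plateau value, which keeps the trapezoid integral of
  the step exact.
* Constancy/oracle verifications use grids with half-length T/2 + 12d so
  that residual tail truncation (< e^(−12)) is far below the 0.1% assertion
  bands; the default ±450 mm span already keeps it below ~0.1% for the
  default parameter sets.
* Reports: full internal precision; tabulated output rounded to 2 decimals
  (cGy). DLP is computed from the **rounded** scan mean — reproducing how
  such tables are conventionally printed; the full-precision mean remains on
  the results object. The per-width "DPI" column of the report is the
  weighted quantity CTDIw,l × T; per-position integrals stay available in
  `results.per_position`.
* Mean CTDIw dispersion is the sample (n−1) standard deviation.

## Film dosimetry

The film chain is PV → exposure → dose with the roentgen-to-rad factor
0.869 and a dose-to-film factor of 1.00 (1 rad = 1 cGy). Choices where the
procedure is genuinely open:

* The PV→exposure interpolant is a shape-preserving monotone piecewise cubic
  (PCHIP): a dosimetric calibration must be monotone, and a generic cubic
  through noisy points can oscillate. Extrapolation outside the calibrated
  PV range is refused, not clamped — clamping silently biases profile tails.
* Net optical density uses the reflective convention
  NOD = log10(PV_unexposed / PV).
* Only the red channel is used (maximum film sensitivity); the channel index
  is a fixed convention in `roi_mean_red`/`extract_normalized_profile`.
* Beam width is measured as FWHM with linear sub-sample crossing
  interpolation.
* Profile extraction centers z at the dose-weighted centroid of the samples
  at or above half maximum, then normalizes to the interpolated z = 0 dose.

The synthetic calibration used in tests follows an exposure-linear NOD
response PV(E) = PV₀·10^(−kE) over 0–16.07 R, sampled at 17 points (~1 R
spacing). The density matters: the render and extract directions use
independent PCHIP fits, and with a much sparser ladder (e.g. 12 points over
16 R) their mutual interpolation error alone approaches ~2% at the low-dose
end, while ~1 R spacing keeps the full round trip comfortably inside a 1%
budget. Round-trip comparisons use a profile with a 2 mm Gaussian penumbra,
because a pointwise relative comparison across a perfectly discontinuous
edge sampled at the 0.35 mm film pitch is ill-posed (any sub-pixel shift
produces an O(1) pointwise error that says nothing about dosimetry).

## Reference-table regression

The package ships a transcription of a published per-beam-width dose-index
table for one commercial cone-beam system (head: T = 20–136 mm with
CTDIw,600; body: T = 22–154 mm with CTDIw,900; plus a wide-beam point-dose
block), guarded by a SHA-256 transcription checksum. Two arithmetic
identities are exercised against it: the scan means (8.74 and 4.26 cGy) with
every DLP cell at 2-decimal rounding, and the ½/½ point-dose combinations
(8.50/8.77 and 4.21/4.26 cGy, method differences 3.2% and 1.2%). One known
internal inconsistency of the printed source — the head T = 136 mm row,
where DPI/T = 8.741 but the printed CTDIw is 8.72 — is left as printed and
no assertion is placed on that cell's DPI/CTDIw consistency.

## Known limitations

* The scatter kernel is phenomenological; its parameters are configuration,
  and absolute doses from the generator are only illustrative.
* The "±0.01" dispersion printed with published scan means is not defined
  (sd vs standard error); the report emits the sample sd and asserts nothing
  against ±0.01.
* Film modelling excludes darkening kinetics, scanner flat-field response
  and multi-channel dosimetry; 8-bit scans are accepted with a warning but
  quantization then limits accuracy.
* Peripheral angular positions are fixed at 12/3/6/9 o'clock by CTDI-phantom
  convention; the angles do not enter the arithmetic (only the
  center/periphery split does).
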