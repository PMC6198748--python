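# Methods

Models, numerical choices, and limitations of each analysis stage, and the
scope of the synthetic-data generator. All empirical numbers quoted here are
computed by the test suite (`tests/`) or by `scripts/acceptance.py`.

## Cantilever lateral calibration (`fibrilmech.cantilever`)

The lateral force on the tip twists the cantilever; the lateral spring
constant and photodiode sensitivity follow from the vertical calibration and
the lever geometry:

- K_L = 2L²·K_z / (3(1 + ν)H²)  [N/m]
- S_L = 3H·S_z / (2L)           [nm/V]
- F_lateral = K_L · S_L · signal, converted to µN

with `L` the lever length, `H` the tip height, `K_z` the vertical spring
constant, `S_z` the vertical sensitivity, and ν the Poisson ratio of the
lever material (0.27 for silicon ⟨111⟩, the package default). For a typical
stiff lever (L = 225 µm, H = 17.5 µm, K_z = 40 N/m, S_z = 100 nm/V) this
gives K_L ≈ 3471 N/m and S_L ≈ 11.67 nm/V. K_L depends on L and H only
through their ratio (a tested invariance).

Assumptions: rectangular lever, tip at the free end, small torsion angles,
and a vertical calibration performed on the same lever.

## Bowstring mechanics (`fibrilmech.mechanics`)

**Geometry.** The glued segment of rest length `L0` is pulled laterally at
its midpoint by `d`; both arms stay straight, so the fibril length is
2·√((L0/2)² + d²). Strain is the relative elongation of that length; the
lateral probe force `F` balances the two tension projections,
T = F·√((L0/2)² + d²)/(2d). Stress is tension over the dry cross-sectional
area (µN/µm² = MPa). Slack (initial non-zero deflection before the fibril
is taut) shifts the reference length.

**Trace processing order.**

1. *Rupture detection*: the largest single-sample force drop, accepted when
   it exceeds 5× the standard deviation of the post-drop trace.
2. *Background subtraction*: the post-rupture mean force (tip–surface
   friction) is subtracted from the whole trace.
3. *Smoothing*: 5-point adjacent averaging applied to the pre-rupture
   segment only, so the rupture edge is not smeared. Windows shrink
   symmetrically at the segment ends (window 1 reproduces the sample
   exactly).
4. *Synchronization*: the video time axis is shifted so the identified
   rupture frame coincides with the force-trace rupture instant; deflection
   is interpolated onto force timestamps over the overlap.
5. *Full-tension onset*: a two-segment piecewise-linear fit over the
   deflection–force relation; the breakpoint marks where both arms carry
   tension, and the stress–strain curve is built from there to rupture.

**Summary parameters.** Rupture strain/stress are the last curve point.
Toughness integrates stress over fractional strain by the trapezoid rule
plus a linear extrapolation from the first retained point down to 0% strain
(slope fit over the first 2% strain; area clamped if the extrapolation
crosses zero). The high-strain modulus is the least-squares slope over the
final 10% of strain, reported with its standard error.

**Accuracy (tested).** On noiseless synthetic pulls (500 Hz force, 20 fps
video, 1 µm/s): rupture strain within one video-frame step (~0.11% strain at
the study geometry), stress/toughness/modulus within 1% relative. With the
default 0.05 µN friction noise, single-pull rupture stress scatters with
sd ≈ 2.5 MPa around the 100 MPa truth.

**Bending bound.** The worked upper bound on the bending contribution models
the fibril as a clamped–clamped beam centrally loaded: F = 192·E·I·d/L³ with
I = πr⁴/4. At E = 0.17 GPa, r = 100 nm, L = 50 µm, d = 5 µm this is
0.1 nN to one significant figure — negligible against µN-scale tensile
forces, justifying the string (tension-only) model.

**Hydration rescale.** Fibril radius roughly doubles on rehydration, so
stresses computed on the dry area can be rescaled by 1/factor² (default
factor 2 → ÷4) to a hydrated-area basis.

## AFM morphometry (`fibrilmech.afm`)

The fibril is assumed to run roughly along the raster's x axis. The fibril
mask thresholds heights at median + 5 × (1.4826·MAD) — the raster median
sits at the substrate level because the fibril occupies a minority of
pixels. A least-squares background plane fit to off-mask pixels is
subtracted before any profile work (note: this also removes any uniform
height offset between two rasters; height change is therefore measured
relative to the local substrate, not absolute z).

- **Centerline**: per-column height-weighted centroid of masked pixels,
  moving-average smoothed (5 px).
- **Cross-sectional area**: centerline-aligned cross-profiles over a 500 nm
  axial segment (≥ 62 scanlines at 8 nm pixels) are averaged and integrated
  by the trapezoid rule. Tested to converge to the half-cylinder πr²/2 as
  pixel size decreases (16 → 4 nm) and to recover it within 2% at 8 nm.
- **D-band period**: the centerline height signal, resampled uniformly in
  arc length, is detrended, Hann-windowed, zero-padded (×8) and Fourier
  transformed; the strongest peak in the 30–150 nm period band is refined by
  parabolic interpolation of log-power. Two gates reject non-banded
  fibrils: the peak must exceed 5× the median in-band power, and at least
  20% of the in-band power must lie within the peak's natural linewidth
  (a coherent sinusoid concentrates its power; noise does not). Across 20
  seeds at 8 nm pixels and SNR 5 the mean estimate is 67.0 nm for a 67 nm
  generator period.
- **Kinks**: the tangent direction difference across ±200 nm windows;
  positions where it changes by more than 20° are kinks,
  non-maximum-suppressed within one window. There is no standard numeric
  criterion for a "sharp bend"; both the 20° threshold and the 200 nm
  window are stand-ins, exposed as parameters.
- **Height loss**: difference of mean centerline heights before/after
  rupture, also as a percentage of the before height.

## SHG anisotropy (`fibrilmech.shg`)

Under cylindrical and Kleinman symmetry the polarization-resolved SHG
intensity of a fibril at angle φ probed at polarization α is

I(α) ∝ [ρ·cos²(φ−α) + sin²(φ−α)]² + sin²(2(φ−α)),

with ρ = χ⁽²⁾xxx/χ⁽²⁾xyy. Expanding in harmonics of 2(φ−α) gives, for unit
amplitude, a0 = (ρ+1)²/4 + (ρ−1)²/8 + 1/2, a2 = (ρ²−1)/2,
a4 = (ρ−1)²/8 − 1/2, hence the closures a0 − a2 + a4 = 1,
a0 + a2 + a4 = ρ², and the inversion ρ = √((a0+a2+a4)/(a0−a2+a4)).

A pol-stack holds 25 images at α = 0°–240° in 10° steps; exactly the first
18 span one 180° period and are used for both the max-intensity map and the
per-pixel decomposition (perturbing images 19–25 does not change results —
a tested invariance). Per pixel, a DFT of the 18-point trace yields the
first and second harmonic amplitudes and the angle φ (mod 180°). The
inherent φ vs φ+90° ambiguity (which swaps ρ ↔ 1/ρ) is resolved by choosing
the candidate whose a4 best satisfies the model's amplitude-locked relation.
Noiseless recovery is exact to < 1e−10 per pixel for ρ ∈ {0.5, 1, 1.5, 2.5}
and φ ∈ {0°, 30°, 77°}; the coefficients agree with an independent
least-squares cosine fit to < 1e−10 on random traces.

The ρ distribution over masked pixels is summarized by its histogram peak
(0.05 bins, parabolic refinement) and FWHM (half-maximum crossing
interpolation); for a Gaussian ρ field (µ = 1.5, σ = 0.1, 10⁴ px) this
recovers 1.5 and 2√(2 ln 2)·σ ≈ 0.236 within 0.02. The ruptured/control
intensity ratio compares masked means of the max-intensity maps; note it
depends on both amplitude and ρ, since the intensity law's maximum grows
with ρ. The fibril mask thresholds the max-intensity map at
median + 5 × (1.4826·MAD).

## CHP fluorescence (`fibrilmech.fluorescence`)

The brightfield channel (fibril dark against the substrate, thresholded at
the channel's range midpoint) yields the fibril mask and — after a 2 px
guard dilation — the background mask. The fibril is called positive when
its mean fluorescence exceeds the background mean by more than 3 background
standard deviations; the margin is reported in background-sd units. "Above
background" is not by itself a statistical criterion; the k·sd rule is a
documented stand-in. Laser power is carried as metadata only.

## Synthetic generator (`fibrilmech.synth`)

Scope: the generator stands in for the deposited raw recordings. It
produces, from one `FibrilGroundTruth` (defaults: 100 nm dry radius, 50 µm
segment, 67 nm D-band with 4 nm peak-to-peak modulation, ρ = 1.5, linear
500 MPa law rupturing at 20% strain):

- **Pol-stacks**: the exact intensity law times an amplitude, plus optional
  Poisson shot noise.
- **Height maps**: a half-cylinder along a polyline that bends at each kink
  position, D-band as a sinusoid tapered by the local profile (so the
  footprint edge stays clean), plus Gaussian surface noise. SNR is the
  modulation amplitude over the surface-noise sd (2 nm / 0.4 nm = 5 at the
  defaults used in validation).
- **Pull experiments**: constant-velocity deflection at video rate; lateral
  force at the force rate as Gaussian friction background plus the
  bowstring-projected tension of the fibril's stress law, vanishing within
  one force sample at the rupture strain.
- **Fluorescence**: two-level images with Gaussian noise clipped at zero
  counts, and a deterministic dark-silhouette brightfield.

All draws flow from one `numpy.random.default_rng(seed)` per call;
identical seeds give bit-identical outputs (tested). Parameters are the
study conditions, not tuned values.

Limitations: rupture is instantaneous and complete (no partial unloading or
plasticity before rupture); arms are perfectly straight and inextensible
glue anchors are assumed; the AFM tip has zero width (no tip-convolution
broadening, so real-area estimates would be biased high in ways the
generator does not model); SHG ignores birefringence, depolarization and
focal-volume averaging beyond the single-ρ-per-pixel model; fluorescence
noise is Gaussian rather than Poisson. Per-fibril biological values for
real tendon fibrils are not reproducible from this package — they require
the deposited instrument recordings; what is validated here is the full
computational path on data with known ground truth.
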