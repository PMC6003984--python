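# Methods

This note records the models implemented in `ringpact`, the assumptions
behind them, the defaults that matter, and the choices made where the
design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Forward model

Absorbers are point-like or finite spheres. A uniform sphere of radius
*a* emits the analytic bipolar N-wave p(d,t) = A(d − ct)/(2d) on
|d − ct| ≤ a; spheres at or below 0.06 mm use the small-sphere limit, in
which the received waveform is proportional to the derivative of the
element impulse response.

Two element effects are applied per channel:

* **Impulse response** — Gaussian-envelope band-pass at f₀ = 2.25 MHz
  with −6 dB one-way fractional bandwidth 0.95. The measured element
  spectrum is not published; the Gaussian band-pass is a modelling
  stand-in consistent with the stated ">95% one-way bandwidth".
* **Elevational reception** — the exact far-field response of a uniform
  5-mm line aperture: a temporal boxcar smear of width T = L·sinθ/c,
  evaluated in closed form through the impulse-response antiderivative.
  This is frequency-dependent directivity; its narrow-band limit is the
  sinc pattern whose FWHM for the defaults is 9.23°. Scalar "sinc" and
  "Gaussian (9° FWHM)" directivities remain available as configuration
  options, but the boxcar model is the default: the coherent elevational
  focusing of 3D reconstruction depends on the *waveform* received at
  large angles, not only on an amplitude weight, and the scalar options
  measurably misstate the 3D elevational point-spread function.

Waveforms are accumulated on short windows around each arrival and,
in the point-source fast path, evaluated from a lookup table sampled at
dt/256 — linear-interpolation error is orders of magnitude below the
waveform scale and removes sample-grid phase artifacts that otherwise
alias sub-sample arrival times. Additive white Gaussian noise models the
receive chain; the DAQ's 12-bit quantization is not modelled. The speed
of sound defaults to 1.50 mm/µs (water near 35 °C) and is configurable;
no heterogeneous acoustics, reflections or fluence modelling.

## Reconstruction

2D and 3D universal back-projection with integrand 2p − 2t·dp/dt
(temporal derivative by central differences at the native 40-MHz
sampling; delays by linear interpolation; out-of-record delays contribute
zero). Per-pixel weights are the subtended-angle factors cosα/d,
normalized per pixel — uniform at the ring centre. "Half time" truncates
each record to propagation distances ≤ one ring diameter: the earliest
portion of the data sufficient for the field of view, which suppresses
late-arriving reverberation. Both half-time and full-time modes exist.

3D mode sums all elevational steps; contributions are weighted by a
Gaussian divergence profile (FWHM 9.0° by default, hard cutoff at 2×
FWHM) of the voxel's elevational angle, over 1/d. The measured
elevational PSF is only weakly sensitive to the exact weight profile
(Gaussian, uniform and sinc weightings give closely similar widths on
the default scan). When the
virtual-transducer option is enabled, elevational angles are referenced
to a point L²/(4λ₀) in front of the physical element (the
Fresnel–Fraunhofer transition at the centre frequency; using the centre
wavelength there is this package's convention).

The anti-aliasing bank low-passes the UBP integrand to
f_cut(r) = N·c/(4π·r) in radial zones (raised-cosine roll-off); with 512
elements, c = 1.5 mm/µs and the ~3.3-MHz band edge the unfiltered central
zone is ~37 mm across.

### The 2D-mode elevational sensitivity probe

The 2D mode's elevational figure is *defined by the element divergence*:
the slab thickness from which an element still receives at half its peak
sensitivity. A naive probe — reconstructing an off-plane point at the
ring centre slice-wise and reading the image peak — does not measure
this quantity: for a centred point every back-projection arc acquires the
same excess delay z²/(2Rc), all arcs become tangent to a common caustic,
and the zero-mean band-pass wavelet self-cancels. The probe therefore
reconstructs slice-wise with defocus-compensated (3D) delays, so the
measured amplitude roll-off is the divergence profile as expressed
through the UBP amplitude. The result (~13.3 mm FWHM) is somewhat
narrower than the pure carrier-frequency geometric estimate
(2R·tan(4.5°) ≈ 17 mm) because the UBP derivative term up-weights the
spectrum's high side.

FWHM measurements interpolate linearly between samples; the baseline is
the median of the outer 10% of profile samples, and flat profiles or
boundary peaks raise errors.

## Synthetic data

* **Vessel trees** — seeded binary trees; at each bifurcation daughters
  solve D_p^X = D_a^X + D_b^X exactly for the planted exponent with a
  fixed asymmetry ratio (defaults: X = 2.63, γ = 0.8, matching the scale
  of adult vascular measurements). Segment lengths scale with diameter;
  centrelines receive small seeded heading perturbations.
* **Phantoms** — trees rasterized at 0.1 mm in-plane; tumors are discs
  with reduced relative compliance (default 0.5, the stiff-inclusion
  analog) and extra short vessel segments. Planting is calibrated on the
  *measured* metric — the rasterized-and-skeletonized sliding-window
  density — rather than on raw segment counts, because rasterization
  merges crowded vessels and raw counts overstate the achieved contrast.
  Extra segments are kept individually resolvable (0.3-mm diameter,
  ≥ 0.7-mm mutual spacing, 1.4–2.4 mm length): sub-resolution crowding
  reconstructs as speckle that vesselness filtering cannot segment.
* **Frame sequences** — pulsation mode oscillates masked pixels
  sinusoidally at a cardiac frequency; compression mode warps the frame
  with a displacement field whose local divergence is amplitude ×
  compliance, so a 0.5-compliance inclusion deforms at exactly half the
  background rate by construction. Rigid jitter and additive noise are
  seeded options.

What the generator does *not* emulate: 3D vascular topology (phantoms are
single-slice), flow and oxygenation contrast, heterogeneous acoustics,
skin, and fluence inhomogeneity. Passing tests therefore demonstrate the
correctness and internal consistency of the computational chain under
controlled contrast, not clinical performance.

## Vessel analysis

Frangi scales σ ∈ {1.5, 2.5, 3.5, 4.5, 6} px span vessel diameters of
roughly 3–12 px; β = 0.5; the scale-normalization constant is
scikit-image's half-max-Hessian-norm default. The adaptive threshold is
**local median (51-px window) + 0.25 × global response SD**, with a floor
at 10% of the peak response; isolated single pixels are then removed. A
local-mean + local-SD threshold was evaluated and rejected: both its
terms grow with the local vessel *fraction*, so densely vascularized
regions — precisely the tumor signature — suppress themselves, losing a
large share of in-tumor vessels that the median variant retains. The
floor rejects
faint reconstruction-sidelobe ridges that a purely local rule admits.
All parameters are recorded in the mask provenance.

Skeletons use 8-connectivity throughout: junction pixels have more than
two skeleton neighbours, chains are split there, and chains shorter than
3 px are dropped. Depth encoding takes the per-pixel elevational argmax,
a 3×3 median on the full depth map, then a 6×6 median restricted to
in-mask pixels.

Diameter templates are built from the system's own in-plane PSF
(simulated and reconstructed point) convolved with anti-aliased vessel
bands on a 0.5–2.0 mm grid (0.1-mm steps) over a set of orientations,
normalized to zero mean and unit energy. Matching maximizes normalized
cross-correlation over diameter, orientation and translation — with
translation limited to ±0.5 mm around the patch centre, since an
unrestricted search lets a thin template lock onto a single edge response
of a wide vessel — followed by parabolic refinement on the diameter grid.
Bank-boundary matches warn. The junction exponent is solved by bisection
on [0.5, 10] to |residual| < 1e-9.

## Dynamics

Subdomains: 4×4 grid with 25% linear overlap, triangular blending.
Frames whose global correlation to the first frame falls below 0.85 are
dropped (≥ 10 must survive). Registration is phase-correlation
translation (0.1-px upsampling) plus a small rotation search; estimated
shifts below 0.3 px — the estimator's resolution — are treated as noise
and not applied, since interpolating them measurably smears cardiac-band
power on already-aligned data. Spectra use per-pixel mean removal and a
Hann window after 0.2-mm Gaussian smoothing; band power integrates
spectral magnitude over 1.0–1.6 Hz; arteries exceed 3× the median band
power over vessel pixels; the heart rate is the band-power-weighted
spectral peak. Records shorter than 5 s warn (0.2-Hz resolution).

## Elastography

Demons registration (SimpleITK fast symmetric forces, 60 iterations,
smoothing σ = 1.5 px) maps every frame onto the first; a frame is
excluded with a warning when its residual stays above 20% of the
reference contrast and above half its initial mismatch. Stable pixels
have registered-intensity SD below the 20th percentile ("relatively
small" SD made concrete as a quantile); one seeded-random qualifier
per 2×2 mm square; Delaunay triangulation; triangle vertices are mapped
back to each original frame through the displacement fields and signed
areas tracked. Per triangle, the relative-area series is Hann-windowed
and read at the discrete bin nearest the compression frequency; the final
map averages 100 random stable-pixel re-selections (fewer in tests).
Records shorter than 4 compression periods warn. In patient-mode use the
breathing frequency is estimated from the global mean-area spectrum peak
in 0.1–0.5 Hz; phantom mode uses the configured ~0.25 Hz.

## Tumor detection

Density windows are 2×2 mm (20 px at the 0.1-mm pixel size); a segment
intersecting the window counts once; window offsets follow the
floor-centred convention [i − w//2, i + w − w//2). Whole-breast statistics
are taken inside a 10-cm support circle (the full field when the field is
smaller). The segmentation threshold is mean + k·SD (k = 2.0), regions
are 8-connected, and regions under 1855 px (18.55 mm²) are rejected —
1855 px itself survives. The per-breast ratio divides the high-density
region's mean by the normal region's mean (support minus high-density;
in-tumor pixels are included in the whole-breast statistics). The ROC
sweeps ratio thresholds over [1, 6] in 0.01 steps; the AUC integrates
the step curve with midpoints between distinct ratios added so that
tie-free data reproduce the Mann–Whitney statistic exactly.

### The end-to-end detection study

The study plants a 10-mm tumor at a 3.4× measured density ratio — the
scale of clinically measured tumor-to-normal density ratios — in a
33.6-mm field carrying a jittered-grid bed of fine vessels (1.6-mm
cells), and runs the full chain at the unchanged processing constants
(2-mm window, k = 2.0, 1855-px filter). Three properties of
distinct-segment counting shaped these conditions and are worth
recording:

* counting saturates once vessels crowd within the resolution scale —
  merged vessels stop being distinct — which bounds the background
  density a 3–3.4× tumor can sit on;
* branching-tree-only backgrounds are clumpy (density SD ≈ mean), which
  drives the mean + 2·SD threshold up to the tumor level; the uniform
  bed keeps the relative SD workable;
* the tumor must stay a small fraction of the support area, or its own
  pixels inflate the whole-field SD.

Detection requires a segmented centroid within 3 mm of the planted
centre.

## Problem sizes and budgets

Unit tests run a reduced ring (128 elements, 30-mm radius, 40-µs
records) that preserves the physics; the resolution figures use the full
512-element system on small grids (25-µm PSF grid, ±15-mm elevational
scan). The elastography fixture is a 16-mm field over 20 s at 10 Hz; the
detection study runs ten seeded 33.6-mm fields end to end. These sizes
are the package's desk-scale study conditions; the processing constants
are never scaled with them.

## Known limitations

Single-slice phantoms understate the apparent vessel density of real
maximum-amplitude projections (which stack a thick elevational slab), so
absolute density values are not comparable to clinical maps. The forward
model omits acoustic heterogeneity, attenuation and fluence, so
reconstructed amplitudes carry no quantitative meaning. The 2D-mode
elevational sensitivity is a divergence-limited figure by definition; the
defocused response of a literal off-plane point at the ring centre is
roughly half as wide and oscillatory. Template diameters saturate at the
0.5–2.0 mm bank edges by design.
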