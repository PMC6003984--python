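# ringpact

Ring-array photoacoustic computed tomography (PACT) of the breast, as a
fully simulatable computational stack: a physical forward model of a
512-element full-ring ultrasound array, half-time universal back-projection
(UBP) reconstruction in 2D and 3D, vessel enhancement and bifurcation
morphometry, heartbeat-band artery mapping, breathing-induced elastography,
and automatic tumor segmentation from vessel-density maps. Every analysis
stage can be exercised end-to-end on synthetic phantoms — no patient data
are required.

The intended users are researchers developing or validating PACT image
formation and vascular analysis pipelines who need a tested, seeded
reference implementation of the whole chain.

## The system and its algorithms

The modelled scanner is a full ring of 512 flat-rectangular transducer
elements (220 mm diameter, 1.35 mm pitch, 5 mm elevational height,
2.25 MHz centre frequency, ~95% one-way bandwidth) sampling at 40 MHz for
100 µs after each laser pulse, optionally stepped along the elevational
axis z to scan a volume.

**Forward model.** A uniform sphere absorber of radius *a* at distance *d*
produces the bipolar N-wave p(d,t) = A·(d − ct)/(2d) for |d − ct| ≤ a.
Each element applies (i) a Gaussian-envelope band-pass impulse response
(−6 dB one-way fractional bandwidth 0.95) and (ii) the exact far-field
line-aperture reception: arrivals spread over a temporal boxcar of width
T = L·sin θ/c at elevational angle θ, whose narrow-band limit is the
familiar sinc directivity (FWHM ≈ 9.0–9.2° for the defaults).

**Reconstruction.** Universal back-projection with integrand

    b(t̄) = 2 p(t̄) − 2 t̄ · dp/dt(t̄),   t̄ = |r − r_e| / c,

summed over elements with subtended-angle weights. "Half time" truncates
each record to propagation distances within one ring diameter, suppressing
late reverberation. 3D mode back-projects all elevational steps with a
divergence-angle weight; a radius-dependent anti-aliasing filter bank
low-passes the data to f_cut(r) = N·c/(4πr) outside the fully sampled
~37-mm central zone.

**Vascular analysis.** Frangi vesselness (scales spanning 3–12 px vessel
diameters) → adaptive (local-median) thresholding → single-pixel
elimination → skeletonization split into independent segments at junction
points (chains < 3 px dropped). Diameters are measured by normalized
cross-correlation against a bank of simulated vessel images (0.5–2.0 mm);
at a bifurcation the junction exponent X_B solves

    D_parent^X = D_daughter_a^X + D_daughter_b^X

(bisection), with the cube-ratio R_B = D_p³/(D_a³ + D_b³); X_B = 3 is
Murray's law.

**Dynamics.** Arteries pulse with the heartbeat: after motion screening
and rigid registration in 16 overlapping subdomains, per-pixel Fourier
power inside 1.0–1.6 Hz classifies arteries against veins.

**Elastography.** Slow periodic compression (~0.25 Hz) deforms soft tissue
more than stiff tumors. Frames are demons-registered to the first frame;
stably registered pixels (one per 2×2 mm square) are Delaunay-triangulated
and each triangle's relative area change is Fourier-analysed at the
compression frequency, averaged over 100 random re-selections.

**Tumor segmentation.** Vessel density = distinct skeleton segments
intersecting a sliding 2×2 mm window / window area. Suspicious regions
exceed the whole-breast mean + 2.0·SD; 8-connected regions with fewer than
1855 pixels (18.55 mm²) are rejected. Per-breast density ratios feed a
threshold-sweep ROC over affected vs contralateral breasts.

## Worked example

`examples/01_point_source_resolution.py` simulates a point absorber and
measures the system's resolution figures from the reconstruction:

```
elevational directivity FWHM  : 9.23 deg  (divergence of one element)
in-plane PSF FWHM             : 252 um   (lateral resolution)
3D-mode elevational PSF FWHM  : 5.30 mm  (scanned, weighted UBP)
2D-mode elevational sens FWHM : 13.32 mm  (divergence-limited slab)
```

The element's 9.2° divergence admits a ~13-mm elevational slab into a
single 2D image, while coherent 3D back-projection over a ±15 mm scan
sharpens elevation to 5.3 mm — roughly a three-fold improvement; the
in-plane PSF of ~252 µm is the lateral resolving power. The other
examples exercise bifurcation morphometry (`02`), artery mapping (`03`),
elastography (`04`), full-chain tumor detection (`05`) and the
density-ratio ROC (`06`); each prints the quantities it computes and the
planted ground truth they should match.

A thin CLI mirrors the library (`ringpact simulate|recon2d|recon3d|
vessels|depthmap|diameter|junctions|arteries|elasto|tumor|roc|run`), each
subcommand accepting `--config` (YAML), `--seed` and `--out`.

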