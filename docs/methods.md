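# Methods

## Problem and model

A single in-line (Gabor) hologram records the intensity of the coherent
superposition of the wave scattered by a semi-transparent object and the
unscattered illumination on one sensor:

    I(x, y) = |P_z(u)|^2 ,       u = A(x, y) · exp(i·ψ(x, y)),

where `u` is the complex transmission of the object (amplitude `A ∈ [0, 1]`,
phase `ψ` in radians), `z` the object-to-sensor distance and `P_z` free-space
propagation.  Recovering `u` from `I` alone is the classic phase problem of
in-line holography; a naive back-propagation is contaminated by the twin
image (the defocused conjugate term).  `holomorph` solves it by alternating
projections between the measured sensor modulus and an object-plane support
prior, where the support is re-estimated *every iteration* by morphological
filtering of the current reconstruction — so the support shrinks to fit the
object instead of being guessed in advance.

## Propagation

`P_z` is the band-limited angular spectrum method:

    P_z(u) = F⁻¹{ F{u} · H(f_x, f_y, z) },
    H = exp( i·2π·z·sqrt(1/λ² − f_x² − f_y²) )   for f_x² + f_y² ≤ 1/λ²,
    H = 0                                         otherwise.

Evanescent components are zeroed (hard cutoff), so `|H| = 1` in band,
propagation conserves energy for band-limited fields, and `z → −z` is the
exact inverse.  DFT conventions are numpy's (unnormalized forward, 1/N
inverse) with unshifted frequency grids, which makes the round trip an
exact identity up to FFT rounding.  Fields are padded before propagation
(default 2× per axis, constant fill) because the FFT implements a circular
convolution; the reference reconstruction geometry pads 500×500 holograms
to 1000×1000.  For odd padding differences the extra row/column goes to
the bottom/right and the offset is recorded, making crop∘pad exact.

The propagator is validated two independent ways: a paraxial analytic
Gaussian-beam closed form (1% amplitude tolerance at the beam centre), and
direct Rayleigh–Sommerfeld quadrature of the on-axis field behind an
opaque disk (the Poisson–Arago bright spot), which exercises the full
non-paraxial kernel and is computed by `scipy.integrate.quad`, sharing no
code with the FFT path.

## Morphological support estimation

Binary erosion/dilation follow the set definitions (erosion: the translated
structuring element fits inside the set; dilation: the reflected translate
meets it), with three fixed conventions: outside-image samples are
background for both operations, even-sized SEs anchor at their top-left
cell, and reflection is taken about the origin cell.  The open–closing and
close–opening cascades use G1 = disk of radius 1 (5-cell plus) and
G2 = 2×2 square, the values used in the reference simulation study.

The per-iteration mask pipeline, applied separately to the object-plane
amplitude image and to the phase-deviation image
`|ψ − median(ψ)|` (median-centred so either sign of phase excursion is
foreground and a global phase offset is invisible):

1. **Poisson minimum-error threshold.**  The image is mapped to 256 count
   levels; for every candidate split the two class means are fitted and
   the split minimizing the Poisson-mixture negative log-likelihood is
   chosen.  Parameter-free; a class with zero mean is handled exactly
   (P(0) = 1).  Object polarity is resolved as the minority class
   (`auto`), overridable to `bright`/`dark`.
2. **Cascade average.**  `F̄ = (OC(B) + CO(B))/2` balances the opening
   cascade's shrinkage against the closing cascade's expansion; values in
   {0, ½, 1}.
3. **Gaussian smoothing**, σ = 1 px by default — the same scale as the
   SEs; larger σ would blur single-pixel speckle rejection away.
4. **Sobel-derived re-binarization.**  Edge pixels are those with Sobel
   gradient magnitude above 4× its mean; the binarization threshold is the
   mean smoothed value over the edge pixels, i.e. the half-height of the
   smoothed transition (0.5 fallback when no edges exist).

A degenerate (near-constant) input yields an all-false mask plus a
warning, and the retrieval loop skips the constraint for that iteration
rather than zeroing the field — an early collapse would be unrecoverable.

## Constraint application

Two application modes exist because the physical reading of "mask times
reconstruction" is ambiguous for transmission objects:

* `background_fill` (default): outside the amplitude mask the amplitude is
  set to the estimated background level (median amplitude outside the
  mask); outside the phase mask the phase is set to 0.  This models a
  uniformly transmitting (bright) background, which is what in-line
  holograms of cells and etched targets actually have.
* `hadamard`: amplitude and phase are literally multiplied by their masks
  (outside-support values → 0).  Retained for fidelity experiments; on
  bright-background scenes it injects a large artificial absorber and the
  iteration degrades, which is why it is not the default.

## Retrieval loops

Single-shot loop (per iteration): back-propagate the sensor field by −z;
regenerate and apply the constraint (adaptive masks, a fixed support
aperture, or nothing); forward-propagate by +z; replace the sensor modulus
with √I₀ keeping the phase (the padded margin of I₀ is enforced like
measured data).  The readout after k iterations is the back-propagation of
the k-th sensor field, cropped to the hologram extent.  Initial phase is
zeros by default (seeded uniform random available).  Padding fill is the
mean of the hologram's 5-pixel border ring, matching the unscattered-beam
level.

The multi-distance baseline (MPR) cycles through the measurement planes
nearest-to-farthest each iteration, replacing the modulus with the
measured √I_k at each plane; no object-plane mask is used.  The static
support baseline applies a fixed rectangular/circular aperture in
`background_fill` mode.

## Autofocus

The Tamura coefficient `TC = sqrt(std(I)/mean(I))` of the back-propagated
intensity is scanned over candidate distances.  The hologram is padded
(2×, border-ring fill) before back-propagation: unpadded, the circular
convolution's wraparound varies smoothly with distance and swamps the
focus feature of the curve.  Whether focus is a TC minimum or maximum
depends on the object type, so the polarity is a flag (`min`/`max`/
`auto`); `auto` takes the global extremum farthest from the median TC,
preferring interior extrema because a scan-edge extremum is a truncated
monotone branch, not a focus.  A two-stage scan (0.5 mm coarse, 0.1 mm
fine) recovers the recording distance of a strong amplitude object to
the fine step.  For mixed amplitude+phase objects the extremum is
displaced by a few tenths of a millimetre — the intensity contrast of a
weak phase structure vanishes exactly at focus, so it pulls the
sharpness extremum slightly off — an intrinsic property of
intensity-based focus metrics, not of the implementation.

## Synthetic scenes

The generator emulates plane-wave in-line holography of compact complex
transmission objects in the reference geometry (λ = 500 nm, pitch
5.86 µm, 500×500 sensor window, z = 6 cm, 0.5 mm multi-distance
interval).  Scenes place an amplitude pattern (block letters, three-bar
groups, or cell-like blobs; amplitude 0.3 on a background of 1.0) and a
separate phase pattern (1 rad step, or a smooth interior gradient for
blob scenes) in distinct parts of the field of view, mirroring the
reference figures where amplitude and phase carry different marks.
`boundary="flat"` gives sharp geometric outlines; `boundary="random"`
replaces them with compact blobs whose radius is modulated by random
azimuthal harmonics — irregular, non-geometric outlines at matched fill.
Holograms are formed by the same band-limited propagator on a 2× padded
grid and cropped to the sensor window; the Rayleigh–Sommerfeld quadrature
oracle exists precisely because forward and inverse modelling otherwise
share the propagator (inverse crime).

Noise is additive white Gaussian at a stated SNR with signal power
defined as `mean(I²)` — the SNR convention is not standardized, so one
convention is fixed and the empirical-SNR test uses the same one.  The
noisy intensity is clipped at 0; at SNR ≥ 15 dB clipping touches ≲0.2% of
pixels.

What the generator does *not* model: partial coherence, sensor MTF, shot
noise, quantization beyond optional 16-bit rounding, and amplitude/phase
structures that occupy the *same* pixels.  The last point is a known
limitation of support-based adaptive masking, not of the simulator: where
an absorbing step and a phase step coincide, phase-to-amplitude crosstalk
in the reconstruction can push those pixels above the amplitude threshold,
the background fill then erases them, and the erasure is self-confirming.
Passing tests on the standard scenes therefore demonstrate twin-image
suppression for objects with distinct amplitude and phase structures, and
say nothing about strongly co-located amplitude/phase steps.

## Metrics

Reconstruction error is the reference-normalized MSE
`E = Σ|ρ − ρ₀|² / Σ|ρ₀|²`, applied separately to amplitude and phase
images.  Phase comparisons are made on the wrapped scale after removing
the global piston (circular mean of the wrapped difference over the
reference support): single-intensity retrieval is blind to a global phase
offset, so a raw comparison would penalize an unrecoverable degree of
freedom.  Raw mode is available.  All test objects keep |ψ| < π, so
unwrapping is out of scope.

## Problem sizes and numerical choices

The head-to-head convergence studies run 150 iterations (noise studies
100) in the full reference geometry (1000×1000 padded grids); mask
regeneration is every iteration (`mask_every=1`); traces are recorded
every 5–20 iterations.  The morphology fast path is exact (shift-and-
accumulate), verified bit-identical against a brute-force set-translation
oracle on 200 random masks.  All randomness flows through
`numpy.random.default_rng` with explicit seeds; identical configs and
seeds give bit-identical results, including trace CSVs when the wall-time
column is excluded.

## Known limitations

* Co-located amplitude and phase steps (see above).
* Literal `hadamard` application degrades on bright-background scenes.
* The static-support baseline's divergence under noise is mild at 20 dB
  (the error climbs slowly); the contrast with the adaptive method is
  clearest at 15 dB.
* Phase MSE of the baselines stays large on stepped-phase scenes because
  the twin image dominates the small reference-phase energy; this matches
  the qualitative figure behaviour but makes baseline phase MSEs
  scale-sensitive.
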