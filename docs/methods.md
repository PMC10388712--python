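# Methods

## Forward model

A pollen grain in water is modeled as a pure phase object: the acetocarmine
dye used for conventional staining absorbs negligibly at the 650 nm laser
line, so the object field is `O = a·exp(iφ)` with transmitted amplitude
`a = 1` by default (an absorption factor is configurable). The phase map φ
is the projection of refractive-index contrast along the optical axis. The
detector records image-plane holograms — the microscope images the sample
plane onto the sensor, so no free-space propagation is simulated — formed
as `H = |O + R|²` with a tilted plane reference
`R = A·exp(i2π(f_r·row + f_c·col))`. Detector noise is additive Gaussian on
intensity, clipped at zero; the default carrier is (1/8, 1/8) cycles/px,
which separates the sideband from DC for ROIs ≥ 128 px while staying well
below Nyquist.

Default optics: wavelength 650 nm, 40×/0.75 NA objective, 5.2 µm detector
pitch, giving an object-plane pixel of 0.13 µm.

## Phantoms

* **Viable** grains carry a hemispherical phase dome
  `φ(r) = Φ·√(1 − (r/R)²)`; its analytic mask-mean is (2/3)Φ.
* **Non-viable** (aborted) grains carry a low plateau (85% of the wall
  height) with a raised exine wall cresting at 0.9 R and falling to zero at
  the disk edge — a nearly flat map with a residual wall. The exact wall
  shape is a modeling choice; the abrupt outer falloff reflects the sharp
  exine boundary of real grains and keeps the grain footprint recoverable
  by segmentation.

The population generator draws a viability label (default fraction 0.5, as
in a roughly balanced field sample) and a target mask-mean phase from the
class normal — centers 8.72 rad (viable) and 4.26 rad (non-viable), sd
0.8 rad — then scales the profile so its mask-mean equals the target
(`peak = 1.5 × target` for the hemisphere). A 1-px Gaussian edge softening
is applied (real grains are only *nearly* hemispherical, and an ideal
hemisphere's rim slope is unbounded, i.e. unphysical); the softened map is
truncated to the disk and rescaled so the mask-mean target is preserved
exactly.

Grain radii default to 80–100 px (20.8–26 µm at the default optics), the
scale of real *Lantana* pollen. This is also the regime in which the
assay is physically well-posed: the rim slope of a dome with mean ~9 rad
scales as `1.5·mean·√(2/R)` rad/px, so radii below ~50 px push local fringe
frequencies past Nyquist and no reconstruction can recover the phase. The
synthetic data emulate fringe geometry, phase statistics and detector
noise; they do not emulate exine ornamentation texture, clumped grains,
absorbing debris, or optical aberrations, so passing tests demonstrate the
correctness of the computational chain, not robustness to every real-world
artifact.

## Reconstruction

`fourier_reconstruct` demodulates the hologram by the reference carrier,
keeps a circular baseband region (default radius 1/16 cycles/px) and
inverse-transforms — the conventional single-shot method, band-limited by
construction.

`sparse_reconstruct` minimizes data fidelity `‖H − |O+R|²‖²` plus the
isotropic complex TV penalty with smoothing guard ε (default 1e-9 relative
to the RMS of the initial iterate; ε only prevents zero division).
Gradients are Wirtinger derivatives with respect to O*: the data gradient
is `−2(H − |O+R|²)(O+R)`; the TV gradient is the exact discrete adjoint of
the forward-difference gradient applied to the ε-normalized gradient field
(replicate boundary), which makes the finite-difference oracle test exact
in the discrete sense. Each iteration takes a backtracking (Armijo)
steepest-descent step on the data term, then a TV step whose displacement
equals `balance_ratio` × the data-step displacement. `balance_ratio`
defaults to 1.0 — the data- and TV-induced solution changes are balanced
one-to-one — which empirically also gives the best phase fidelity on
phantoms; no regularization constant is ever tuned. The TV step is halved
(at worst skipped) whenever it would raise the data term above its value
at the start of the iteration, so the per-iteration data-term trace is
non-increasing — the testable form of the monotonicity contract. Iteration
stops when the relative solution change falls below 1e-4 or at `max_iters`
(default 300; the population pipeline uses 120, which changes measured
mean phases by < 0.01 rad at one third the cost).

Initialization uses the Fourier method with a wider filter (0.6 × carrier
frequency by default): the optimizer converges locally, and a
higher-bandwidth start preserves rim detail that the descent would
otherwise trade for amplitude dips (complex TV prefers attenuating |O|
where phase varies quickly).

`estimate_reference` locates the strongest non-DC spectral peak, resolves
the conjugate-sideband ambiguity toward positive row frequency (ties to
positive column frequency) on the integer peak before sub-pixel parabolic
refinement. The reference amplitude is estimated from the carrier-free
fringe modulation on the image border, assuming a transparent background
(`|O| ≈ 1` there): `H = 1 + A² + 2A·cos(carrier)` gives `A = sd/√2`. A
background-median estimate is biased in image-plane holography because the
object beam contributes `|O|²` everywhere; the modulation estimator is
exact on a clear border.

## Phase unwrapping and flattening

Wrapped phase uses the half-open convention (−π, π] (−1 maps to +π);
exactly-zero pixels get phase 0 and a logged warning. Unwrapping follows
the transport-of-intensity / Poisson route: pixel-pair phase differences
computed through the complex exponential (hence insensitive to 2π jumps),
their divergence as the Laplacian estimate, and a DCT-II Poisson solve
with Neumann boundaries — free edges of the field of view; a periodic FFT
solver would alias the carrier tilt. Because the least-squares solution is
not congruent to the data, a final step snaps each pixel to the nearest
2π-multiple of the wrapped input, making round trips on residue-free
surfaces exact up to a global 2π·k. Background flattening fits a plane
over the mask exterior (or a border frame) by least squares and zeroes the
background median; it refuses to fit on fewer than 100 background pixels.

## Morphometry

Segmentation thresholds |φ|, fills holes, drops components below a minimum
area and labels the rest. `segment_pollen` defaults to Otsu for unknown
backgrounds; the simulation pipeline uses a fixed 0.5 rad threshold
(≈ 10× the background phase noise at the default settings) because Otsu on
a single-grain ROI bisects the phase dome itself and clips the low-phase
skirt, biasing mean phase upward. Per grain: area (pixel count; µm² via
pitch/magnification), marching-squares contour perimeter (runs ~6% long on
a binarized circle — the documented estimator, kept for bit-for-bit
reproducibility), mean phase `Σφ/N` in radians, and optical volume
`Σφ × pixel area` in radian·µm². The segmentation-based mean phase of
non-viable phantoms runs ≈ +0.1 rad above the disk-mean ground truth
(the sub-threshold outer skirt is excluded); this is a property of the
measurement definition, shared with any image-based segmentation.

## Classification

A two-component 1D Gaussian mixture (EM, k-means initialization, fixed
seed, 5 restarts) is fitted to the mean-phase values; the decision
threshold is the equal-posterior point between the component means (the
root of the quadratic; midpoint on degeneracy), and the higher-mean class
is labeled viable. Fits degenerate — under 4 points, identical values, or
a component weight below 0.02 — raise an error rather than guessing.
Class statistics come from the hard partition at the threshold. Class
separation uses Welch's unequal-variance two-sample t-test
(Welch–Satterthwaite degrees of freedom, two-sided p), appropriate because
the class spreads need not match. Grains within a band around the
threshold (default half-width: half the pooled within-class sd; the
overlap region where stain-based calls are least reliable) are flagged,
and grains whose stain label contradicts their phase label are flagged as
discordant. Histogram binning (Freedman–Diaconis) is display-only and
never affects classification.

## Pipeline and reproducibility

One master seed fans out to per-stage seeds via
`numpy.random.SeedSequence(master, spawn_key=(stage_index,))`, and to
per-grain streams via per-index spawn keys, so any stage or grain can be
re-run in isolation; all derived integer seeds stay below 2³¹. The YAML
pipeline configuration rejects unknown keys and validates ranges at parse
time; a run directory receives the config echo, a config-hash manifest,
the ground-truth population table, measurements, class statistics, the
histogram and a JSON report. CSVs contain no timestamps, so identical
config + seed reproduces them byte-for-byte.

## Problem sizes

Single-grain fidelity checks use 256² ROIs (the regime where rim slopes
are Nyquist-safe, see Phantoms). The end-to-end population analysis in the
test suite and acceptance script uses n = 120 grains at 256² with 120
optimizer iterations per grain (≈ 4–5 min on one CPU), a reduced but
statistically comfortable stand-in for a full 508-grain field study; the
generator itself defaults to n = 508.

## Known limitations

* Grains whose drawn mean phase exceeds ~11 rad at the smallest radii
  (≈ +2.9 sd of the viable class) cross the rim-slope sampling limit and
  reconstruct low; expected ≲ 1 grain per 508, it is the dominant source
  of residual label error.
* No declumping: touching grains segment as one component (they violate
  the isoperimetric bound and can be screened by it downstream).
* The reference-amplitude estimator assumes a transparent, object-free
  border frame; dense fields of view would need an explicit background
  calibration.
* Negative phase contrast (optically rarefied grains) is not simulated;
  phantom phases are nonnegative.
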