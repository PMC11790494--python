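# Methods

This note documents the models, numerical choices and limitations behind
`guvshape`.  All empirical statements below are computed by the test suite
or the `analysis/` scripts.

## Synthetic microscopy

The generator stands in for confocal equatorial slices of dye-labelled
GUVs.  A vesicle outline is a star-convex analytic contour
`r(θ) = R(1 + Σ aₙ cos(nθ + φₙ))` with mode orders `n ≥ 2` and
`Σ|aₙ| < 0.5` (guaranteeing `r > 0` and no self-intersection).  A rendered
frame is

```
pixel = background + (interior | exterior dye level) + peak · exp(−d²/2σ²) + noise
```

where `d` is the distance from the pixel centre to the contour, computed by
dense polyline sampling (0.1° steps) with nearest-segment refinement —
exact to well below the pixel scale without root finding.  The Gaussian
ring cross-section (default σ = 0.15 µm) models confocal blur of a thin
membrane; the tracer only requires a bright ridge.  Noise is Poisson shot
noise (gain in photons per intensity unit) followed by additive Gaussian
read noise; either can be disabled, and a fixed seed gives bit-identical
frames.  Defaults are 512 × 512 px at 0.1 µm/px, matching raw-image
dimensions and 10–40 µm vesicle diameters.  The noise defaults are stated,
not fitted to any instrument.

Influx time-lapses evolve the interior dye level analytically:
`I_in(t) = I_ext − (I_ext − I_current)·e^{−k(t−t₀)}` past the onset `t₀`
(rate `k` in 1/min; `k = 0` is non-permeable), with bleach events rescaling
the interior level instantaneously.  The exact level series doubles as the
ground-truth relative-import curve.  FCS curves evaluate
`G(τ) = (1/N)/(1 + τ/τ_D)` exactly (machine precision at zero noise);
binding series evaluate `I = I_max(1 − e^{−at})`.  FRET spectra are forward
modelled from dye distances via `E = 1/(1 + (r/R₀)⁶)` with Gaussian
emission bands; the Förster radius (default 5.4 nm) is a configuration
parameter, and only state orderings are ever asserted.

The ground-truth curvature statistic of a contour is computed on a dense
angular grid with the *same* least-squares circle definition as the
analysis module, so oracle comparisons test the tracing, not circle
conventions.

What the generator does not emulate: 3D z-stacks and out-of-plane blur,
multi-vesicle crowded fields, uneven illumination, membrane texture from
bound rafts, and photobleaching of the membrane label.  Passing tests
therefore demonstrate correctness of the analysis operations under the
stated image model, not robustness to every real-microscopy artefact.

## Membrane tracing and SD_k

Coordinates are 0-based pixel indices, `(row, col)`, origin top-left;
angles are measured about the centre of mass **x₀** (by default the
intensity-weighted centroid of above-Otsu pixels, standing in for manual
selection; an explicit centre overrides it).

Each of the `360/step` steps (default 3°):

1. **Adaptive threshold** — the mean intensity of a square region centred
   on **x₀** with side `d = |x_seed − x₀| + 20` px (clipped to the frame).
   The region grows with the vesicle and covers mostly lumen, so membrane
   pixels exceed it.  The reference formula fixes the region's width only;
   the height is implemented equal (square region).
2. **Local parabola fit** — above-threshold pixels in a `roi_size`
   (default 21 px, odd) window around the seed are rotated about the seed
   by the negative of its polar angle, making the membrane locally
   horizontal so that `y(x) = a + bx + cx²` is well posed at every angle;
   fitting in raw image coordinates would degenerate on near-vertical
   membrane segments.  The fit is weighted by intensity-above-threshold by
   default: the unweighted fit through binarized pixel coordinates
   estimates the band mid-line with ~0.25 px quantization noise, while the
   weighted fit estimates the bright ridge to ~0.05 px
   (`fit_weighting="none"` restores the unweighted variant).
3. **Vertex and snapping** — the parabola vertex `−b/2c` estimates the
   membrane point, but only where the membrane runs nearly normal to the
   radial ray: on tilted sections it slides tangentially by
   `−tan ψ / κ` (tilt ψ, curvature κ), which is unbounded and stalls the
   angular stepping.  The vertex is therefore used only within
   `vertex_clamp_px` (default 2 px) of the ray, else the ray-crossing
   estimate (`x = 0`) applies.  The above-threshold pixel nearest the
   vertex becomes the traced membrane pixel (ties: higher intensity, then
   lower row, then lower column — deterministic); the next seed is that
   pixel rotated about **x₀** by the step angle.
4. **Failure handling** — an empty thresholded ROI aborts with an error
   naming the step and angle (no silent interpolation, which would bias
   SD_k downward); a point farther than 3× the initial radius from the
   origin aborts as non-convergent wandering.

The trace retains both the snapped pixels and the sub-pixel vertices.  The
reference circle is an algebraic (Kåsa) least-squares fit — closed-form,
deterministic, exact on exact circles; curvature uses the vertex points by
default (`points="pixel"` switches to the strict pixel-snapped variant,
whose ~0.3 px quantization noise floors SD_k at ~0.01 for a 30 px radius).
`SD_k` is the population (divide-by-n) standard deviation of
`kᵢ = R₀/Rᵢ`; with 120 points the n vs n−1 distinction is negligible.  A
vesicle is deformed when `SD_k` strictly exceeds the threshold (default
0.026, the bare-vesicle baseline; `calibrate_baseline` recomputes it from
a user-supplied bare set).  Whether the stepping rotation applies to the
seed or to the snapped pixel is ambiguous in the reference procedure; the
snapped pixel is used here, and per-frame circle fits are used for
time-lapse SD_k.

Measured accuracy (test suite): on noiseless circles of radius 30–200 px
the vertex points lie within 0.5 px of the true circle and SD_k < 0.005;
pipeline SD_k agrees with the analytic oracle within 5% relative over
single-mode amplitudes 0.02–0.15; SD_k is invariant (±0.002) under whole-
pixel translation and 90° rotation.

## FCS density

`fit_fcs_2d` fits `G(τ) = (1/N)/(1 + τ/τ_D)` by least squares with `N` and
`τ_D` log-parameterized (strict positivity without active bounds),
initialized from the smallest-lag amplitude (`N ≈ 1/G`) and the
half-amplitude lag.  Curves must have ≥ 8 points spanning ≥ 2 decades of
lag; flat curves are rejected.  Uniform weighting is the default, with
optional per-point weights.  Triplet/blinking corrections are deliberately
omitted (the model is the pure one-component 2D form); the covariance is
the Gauss–Newton estimate mapped back from log space.  `calibrate_waist`
inverts `τ_D = r₀²/(4D)` for a dye of known, already temperature-corrected
diffusion coefficient, propagating the `τ_D` standard error; the reported
waist uncertainty is fit-propagated only.  `surface_density` computes
`σ = N/(πr₀²)` (µm⁻²) and `φ = σLW` with the raft footprint defaulting to
the near-square 70 × 55 nm; `φ > 1` warns.

## Kinetics and flux

The relative import level `(⟨I_out⟩ − ⟨I_in⟩)/⟨I_out⟩` uses a ~30 × 30 px
interior ROI at the vesicle centre and two ~50 × 50 px exterior ROIs,
defaulting to the frame corners farthest from the centre (manual positions
override; an ROI overlapping a supplied membrane contour is an error).
The two exterior ROIs combine as a mean of means by default
(`combine="pooled"` averages pixels).  The statistic is scale-invariant
and decreases monotonically for monotone interior filling.

FRAP gating reports the recovery fraction
`(I_end − I_post)/(I_pre − I_post)` at a horizon after the bleach; a drop
below 10% of the pre-bleach level is "no detectable bleach event".  The
open/sealed verdict uses an operational cutoff of 0.2 at a 40 min horizon —
an invented threshold standing in for a qualitative readout.  The
molecular-weight cut-off summary reports mean ± s.e.m. per probe and the
first adjacent probe pair whose upper member reaches the 0.5
partial-permeability midpoint.

## Hard-rectangle ordering

Rafts are hard rectangles on a flat periodic square box (the vesicle
radius, ≥ 5 µm, is far above the raft scale, so curvature is negligible
over an ordering domain; membrane coupling is out of scope).  Metropolis
single-particle translation/rotation moves (defaults 5 nm, 0.2 rad) with a
separating-axis overlap test stand in for Brownian dynamics — the
steady-state order, not kinetics, is the quantity of interest.  Initial
states come from random sequential insertion (feasible here for coverages
φ ≲ 0.3).  The square→rod transformation interpolates the half-length
linearly and takes the half-width from a linearly interpolated area
(monotone 3894 → 3800 nm², comfortably within the ≤ 10% per-substep area
bound), relaxing between substeps and retrying particles whose shape
update would overlap; a single-substep jump at φ ≈ 0.23 is geometrically
obstructed, which is why gradual reconfiguration matters.

Order metrics are computed over near-contact neighbour pairs: the default
neighbour radius is half the mean centre-to-centre spacing
(`0.5·box/√n`, ≈ 65 nm at the study conditions).  A radius of the order
of the particle long axis was measured to *dilute* the genuine contact
alignment (close rod pairs have pair-S4 ≈ 0.84) against ~14 mostly
uncorrelated mid-range pairs, while letting sparse square neighbourhoods
(≈ 1.4 pairs) pass the 0.7 local-S4 cutoff by chance — inverting the
expected contrast.  A particle is "ordered" when its mean `cos 4Δθ` over
≥ 1 neighbour exceeds the cutoff (0.7); radius, cutoff and the neighbour
minimum are configuration parameters.

Study conditions (five seeds, n = 200, φ = 0.23): squares equilibrated
10⁴ sweeps; transformation in 20 substeps with 50 relaxation sweeps each,
then 2000 post-transform sweeps — mirroring that the elongated state is
measured after reconfiguration, whose rafts show low mobility, rather than
after indefinite re-equilibration.  Under these conditions the transformed
rods' ordered fraction is ~0.20 versus ~0.006 for squares at equal
coverage.

**Limitation.**  A pure hard-core model at φ = 0.23 does *not* reproduce
the contrast between dynamically transformed rods and rods deposited
directly at the same coverage: both show statistically similar
near-contact order (≈ 0.20 vs ≈ 0.16 across seeds; random sequential
insertion itself plants aligned contacts).  The route dependence observed
experimentally plausibly requires interactions beyond excluded volume
(e.g. membrane-mediated attraction), which this surrogate deliberately
omits.  The module therefore asserts only the robust shape-anisotropy
ordering (rods ≫ squares), never fitted quantities or route effects.

## Pipeline

The time-course runner traces each membrane frame (per-frame circle fit),
computes the per-frame import level on the dye channel, and aligns both on
one time axis.  Shape recovery is the first time from which SD_k stays at
or below the threshold; influx onset is the first frame with import level
below 0.95 (an invented, configurable operationalization of a qualitative
onset); their difference is the reported delay.  Configurations are
strictly validated (unknown keys rejected); every output carries the
config hash and seed, and re-running a config reproduces all outputs
byte-identically.

## Problem sizes

Defaults used throughout the tests and scripts: 512 × 512 px frames
(256 px for small studies), 120-point traces, 64–80-lag FCS curves,
100-replicate recovery ensembles, and the five-seed ordering study above —
sizes chosen so every study runs comfortably on a single CPU while keeping
estimator noise well below the asserted tolerances.
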