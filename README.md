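# guvshape

Quantitative analysis of giant unilamellar vesicle (GUV) remodelling by
membrane-bound, reconfigurable DNA nanorafts — as a tested, reusable Python
package driven entirely by synthetic microscopy data with known ground truth.

Signal-responsive DNA origami rafts switch between a near-square
(70.8 × 55 nm, aspect ratio ~1.3) and an elongated rectangular
(190 × 20 nm, aspect ratio ~9.5) conformation while bound to a GUV membrane.
Their collective reshaping deforms the vesicle, and during the subsequent
shape recovery the locally ordered rafts can perforate the membrane,
forming sealable synthetic channels for large-cargo transport.  This package
implements the analysis stack such experiments require:

- **`guvshape.synthetic`** — ground-truth-known generators: equatorial GUV
  slices (bright thin-ring membrane over interior/exterior dye levels, with
  Poisson–Gaussian noise), influx/FRAP time-lapses, analytic FCS curves,
  binding series and FRET spectra.  Vesicle outlines are analytic
  star-convex contours `r(θ) = R(1 + Σ aₙ cos(nθ + φₙ))` whose exact
  curvature statistic serves as the tracing oracle.
- **`guvshape.tracing`** — the automated membrane tracer: from a centre of
  mass **x₀** and a seed pixel, an adaptive threshold (mean of a square
  region of side `d = |xᵢ| + 20` px on **x₀**), a local parabola fit
  `y(x) = a + bx + cx²` through the above-threshold ROI pixels, vertex
  snapping to the nearest membrane pixel, and rotation stepping from 0° to
  360° in 3° steps.  A reference circle (radius `R₀`, algebraic
  least-squares) through all points gives the normalized local curvatures
  `kᵢ = R₀/Rᵢ`; the deformation statistic is `SD_k = std(kᵢ)`, thresholded
  at the bare-vesicle baseline 0.026, with population deformation
  efficiencies and pooled `kᵢ` histograms.
- **`guvshape.fcs`** — one-component 2D diffusion FCS:
  `G(τ) = (1/N)·1/(1 + τ/τ_D)`, waist calibration `r₀ = √(4Dτ_D)` from a
  dye of known `D`, surface density `σ = N/(πr₀²)` and coverage `φ = σLW`.
- **`guvshape.kinetics`** — raft binding kinetics `I = I_max(1 − e^{−at})`,
  the cargo-flux statistic (relative import level
  `(⟨I_out⟩ − ⟨I_in⟩)/⟨I_out⟩` from interior/exterior ROIs), FRAP
  open/sealed channel gating, molecular-weight cut-off summaries and FRET
  proximity ratios.
- **`guvshape.ordering`** — a hard-rectangle Monte Carlo simulator on a
  periodic plane with an in-place square→rod shape transformation and
  near-contact nematic/tetratic order metrics (S2, S4, ordered fraction,
  cluster sizes).
- **`guvshape.pipeline` / CLI** — the end-to-end time-course runner
  aligning per-frame `SD_k` with the import level, plus
  `guvshape simulate|trace|fcs|flux|order|pipeline` commands.

## Worked example

```python
import numpy as np
from guvshape import synthetic as syn, tracing, fcs

# render a deformed vesicle (mode-2 amplitude 0.10) and trace it
shape = syn.make_contour(10.0, modes=[(2, 0.10, 0.0)])
frame = syn.render_guv_slice(shape, syn.OpticsModel())
trace, circle, profile = tracing.trace_guv(frame.pixels)
print(len(trace), round(profile.sd_k, 4), profile.deformed)
# -> 120 0.0721 True        (analytic ground truth: 0.0715)

# calibrate the FCS detection-area waist from a free dye with D = 414 um^2/s
curve = syn.generate_fcs_curve(8.0, 25.875e-6, np.logspace(-6, 0, 64))
cal = fcs.calibrate_waist(curve, 414.0)
print(round(cal.r0_nm, 1))
# -> 207.0
```

The tracer returns the 120 membrane points of one revolution (3° steps);
`SD_k = 0.0721` exceeds the bare-vesicle baseline 0.026, so the vesicle is
classified deformed, in agreement with the analytic contour's ground-truth
value 0.0715.  The calibration converts the fitted diffusion time
(25.875 µs) into the 207 nm waist radius of the detection area.

The numbered scripts under `analysis/` run the complete studies (curvature
populations, FCS density, cargo cut-off and FRAP gating, raft ordering,
coupled recovery/influx time course) and write their tables under
`results/`.

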