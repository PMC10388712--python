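# holopollen

Quantitative phase imaging pipeline for assessing pollen viability with
digital holographic microscopy (DHM), developed around *Lantana camara*-like
grains. Viable, cytoplasm-filled pollen delays transmitted light much more
than aborted, nearly empty pollen, so the projected optical phase of a grain
— invisible to bright-field imaging — separates the two classes without any
vital stain. This package provides the complete computational chain for
that assay, plus a synthetic-hologram generator with known ground truth for
validating every stage. It is aimed at plant-reproduction, palynology and
QPI-methods researchers.

## Method

An off-axis image-plane hologram records the interference of the in-focus
object field `O(x,y)` with a tilted plane reference `R(x,y)`:

```
H = |O + R|² = |O|² + |R|² + O R* + O* R
```

The phase of `O` is the refractive-index contrast of the grain projected
along the optical axis — an optical height map. Two reconstructions of `O`
from a single hologram are implemented:

* **Fourier-transform method** — isolate the +1-order sideband in the
  spectrum, shift it to baseband, divide out the reference. Simple, but the
  circular low-pass filter limits resolution and blurs edges.
* **Sparse (TV-regularized) optimization** — minimize
  `C(O) = ‖H − |O+R|²‖² + TV(O)`, with
  `TV(O) = Σ √(|∂O/∂x|² + |∂O/∂y|² + ε²)`,
  by alternating Wirtinger-gradient descent: a backtracking step on the
  data term, then a TV step whose displacement is tied to the data step's
  (an adaptive balance, so no regularization constant is tuned). This
  recovers `O` at full resolution over the region of interest.

The wrapped phase `φ = atan2(Im O, Re O)` is unwrapped with a
transport-of-intensity / Poisson solver (DCT, Neumann boundaries) followed
by a congruence correction, flattened by background-plane removal, and
segmented. Per grain the pipeline reports area, perimeter, **mean phase**
(integrated phase / area, the viability discriminant) and **optical
volume** (integrated phase × pixel area). A two-component Gaussian mixture
on the mean-phase values yields class statistics, an equal-posterior
viability threshold, Welch's t-test for class separation, and flags for
grains in the histogram overlap region.

The synthetic generator renders populations of phantoms — hemispherical
phase domes for viable grains, low plateaus with an exine wall for aborted
ones — whose class mean-phase centers default to 8.72 rad (viable) and
4.26 rad (non-viable), with one ROI hologram per grain and full ground
truth.

## Worked example

```
holopollen run --n 20 --seed 7 --out runs/demo
```

simulates 20 grains (256² ROIs), reconstructs each hologram with the
TV-regularized optimizer, unwraps and flattens the phase, measures every
grain and classifies the population. It prints the run report:

```json
{
  "n_simulated": 20,
  "n_measured": 20,
  "class_stats": [
    {"label": "viable",    "n": 10, "mean": 9.234, "sd": 0.870},
    {"label": "nonviable", "n": 10, "mean": 4.354, "sd": 1.352}
  ],
  "threshold": 7.151,
  "n_overlap": 1,
  "t_statistic": 9.598,
  "degrees_freedom": 15.367,
  "p_value": 6.92e-08,
  "label_accuracy": 0.95
}
```

Read: the mixture split the 20 grains 10/10; the class mean phases (9.23
and 4.35 rad) bracket the 7.15 rad threshold; one grain sits in the
overlap band; Welch's t-test rejects equal class means at p ≈ 7e-8; and
19/20 phase-based labels agree with the generating ground truth. The run
directory holds the ground-truth manifest (`population.csv`), per-grain
`measurements.csv`, `class_stats.csv`, a mean-phase histogram and
`report.json`.

Other subcommands (`simulate`, `reconstruct`, `phase`, `measure`,
`classify`, `show-config`) expose the individual stages; `--config FILE`
supplies a YAML configuration overriding any default.

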