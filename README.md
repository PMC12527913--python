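# ermorph

Epithelial wounds close by two orthogonal migration modes: lamellipodial
crawling at convex (outward-bulging) wound edges and purse-string
contraction at concave edges. The endoplasmic reticulum (ER) tracks this
geometry — tubule-dominated ER at convex fronts, dense Climp63-positive
sheets at concave fronts — and its layout feeds back on focal-adhesion
orientation and migration mode. `ermorph` packages the quantitative side of
that biology for image analysts and modellers:

- **geometry** — signed edge curvature κ (µm⁻¹, convex > 0) at the
  single-cell scale (algebraic Taubin circle fits) and tissue scale
  (smoothing-spline κ(s) = (x′y″ − y′x″)/(x′² + y′²)^{3/2}), the
  perimeter-contact inclusion filter (a cell enters curvature analyses only
  when > 20 % of its perimeter touches the wound), and front-band ROIs.
- **ER morphometrics** — three-class pixel segmentation (tubule / sheet /
  background) by a random forest over a trainable-segmentation feature bank
  (Gaussian, Sobel, Hessian, difference-of-Gaussians, membrane
  projections); the front tubule fraction f = A_tubule / (A_tubule +
  A_sheet); the sheet-marker front-intensity fraction; the MDE (mean
  distribution from edge), the intensity-weighted mean distance of a
  component from the wound edge; the shape index P/√A.
- **orientation & dynamics** — Fourier-components orientation histograms
  (6 bins on 0–90° for focal adhesions, 10 bins on 0–180° for
  microtubules); FA detection with angle-to-edge classes (0–18° parallel,
  72–90° perpendicular, otherwise excluded) and ER-contact assignment;
  kymographs with anterograde/retrograde flow calls.
- **mechanics** — a plane-stress finite-element model of the cell front
  (cytoplasm + contractile cortex + ER) comparing the strain energy density
  U = (1/V) ½ ∫ Σ : ε dV of three equal-volume ER layouts (perpendicular
  tubules, parallel tubule cluster, sheet) under protrusion and contraction
  across signed edge curvatures.
- **synthetic data** — a seeded generator of curved-edge scenes (ER, FA and
  time-lapse channels) with exact ground truth, so every estimator in the
  package is validated end to end without external data.

## Worked example

```python
from ermorph import preset_spec, render_er, classify, tubule_fraction
from ermorph.workflows import train_default_classifier

model = train_default_classifier(seed=0)          # seeded synthetic training
img, gt = render_er(preset_spec("convex-default", seed=1))
mask = classify(model, img)
print(tubule_fraction(mask, gt.front_band).f_tubule, gt.f_front)
```

prints `0.6393 0.6412`: the pipeline estimates a front tubule fraction of
0.639 against a generator ground truth of 0.641 — the tubule-dominated
convex operating point (the matching concave preset realizes 0.36). Across 30
scenes spanning true fractions 0.1–0.9, estimated and true fractions
correlate with Pearson r = 0.9994 (`analysis/02_validate_segmentation.py`),
with a mean absolute fraction error of 0.018.

On the mechanics side, `analysis/06_mechanics_flat_edge.py` prints the
flat-edge (κ = 0) comparison: under protrusion the perpendicular-tubule
layout has the lowest strain energy density (2.59 × 10⁻³ vs 3.93 × 10⁻³ kPa
for the sheet) while under contraction the sheet wins (6.80 × 10⁻⁷ vs
7.10 × 10⁻⁷ kPa), with the parallel cluster in between — and the ER
bending-energy fraction is higher under contraction than protrusion for
both layouts. The curvature sweeps (`analysis/07_mechanics_curvature_sweep.py`)
show the perpendicular advantage growing monotonically with convex
curvature under protrusion, and the sheet advantage saturating with concave
curvature under contraction.

The numbered scripts under `analysis/` run the full study pipeline in order
(scene generation, segmentation validation, curvature profiles, FA
orientation/association, flow dynamics, mechanics) and write tidy CSVs to
`results/`.

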