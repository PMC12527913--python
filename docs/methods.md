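# Methods

## Coordinate and sign conventions

All geometry lives in continuous micrometres in the y-down image frame;
pixel index i maps to the pixel-centre coordinate (i + 0.5) · pixel_size.
Signed curvature is positive where the wound edge bulges into the cell-free
gap (convex) and negative where it indents into the monolayer; |κ| = 1/R
for a circular arc of radius R. The sign is assigned by comparing which
side of the edge the osculating-circle centre and a user-supplied gap-side
probe point fall on. Orientation angles (edge tangents, FA axes, Fourier
orientations) all use the same y-down convention, so angles measured by
different modules are directly comparable.

## Curvature estimation

Single-cell curvature uses an algebraic Taubin circle fit — stable on the
short (< 180°) arcs a cell edge presents, where geometric iteration is
poorly conditioned. Collinear input returns an explicit degenerate result
(R = ∞, |κ| = 0) rather than an error: a flat edge is a physical case.
Tissue-scale curvature fits a cubic smoothing spline through the wound
boundary and evaluates κ(s) at uniform arclength; the smoothing parameter
is the FITPACK residual budget, default m − √(2m) for m vertices, exposed
in every API because the appropriate value depends on tracing noise.
A cell contributes to curvature analyses only when more than 20 % of its
perimeter lies within a contact tolerance of the wound edge (strict
inequality; default tolerance one pixel-equivalent) — cells with less
exposure report their neighbours' constraints, not the edge geometry.

## ER segmentation and fraction metrics

Pixels are classified into tubule / sheet / background by a random forest
(100 trees, √n_features per split, fixed seed, out-of-bag accuracy
reported) over a feature bank of Gaussian blur, Sobel magnitude, both
Hessian eigenvalues and difference-of-Gaussians at scales {1, 2, 4, 8} px,
plus membrane projections: the six z-aggregations (sum, mean, max, min,
median, std) of the response to a 19 px line kernel swept over 30
orientations. Membrane projections are computed once from the raw image —
the line kernel has its own fixed scale — rather than per smoothing scale.
The input image is z-normalized before feature extraction, which makes all
downstream fractions exactly invariant to uniform intensity rescaling.
Class ties resolve in the fixed order tubule < sheet < background; an image
with zero variance is all background by definition.

The tubule fraction divides tubule area by total ER (tubule + sheet) area
inside an ROI; unclassified (background) pixels are excluded from the
denominator. The front-intensity fraction subtracts the median
extracellular intensity before ratioing front-band to whole-cell signal.
The MDE normalizes the signal inside the cell to a probability density and
takes its mean Euclidean distance (µm) to the wound-edge polyline —
distances are to the migrating edge, not the whole cell outline, and are
reported in absolute micrometres (no normalization by cell length). Lower
MDE = edge-polarized.

## Orientation and dynamics

Orientation histograms use the Fourier-components method: Hann window,
2D power spectrum, energy binned by spatial-frequency angle with structure
orientation = spectrum angle + 90°, folded into the requested range
relative to the local edge tangent. FA detection thresholds the
background-subtracted channel (Otsu by default), filters components below
0.1 µm², and takes the second-central-moment ellipse axis as the FA axis;
angle classes are parallel 0–18° and perpendicular 72–90°, thresholds
inclusive (the boundary membership is a convention; both endpoints are
stated limits of their ranges). ER contact is the majority ER class within
0.3 µm of the FA footprint.

Kymographs average intensity across a short line width per frame; the space
axis is oriented so increasing index means toward the wound edge. The flow
call scans candidate velocities, shears the mean-subtracted kymograph about
its mid-time and scores the coverage-normalized energy of the collapsed
profile; the mid-time centring makes time reversal map a velocity v to
exactly −v (flow antisymmetry), and the coverage normalization removes the
bias against large shears. Calls below 0.05 µm/min report "none".
`flow_consensus` reads several parallel lines and returns the call from the
most direction-confident line (peak score over mirrored-velocity score) —
the algorithmic version of drawing the kymograph line through visibly
moving structures.

## Synthetic scenes

The generator emulates the statistical structure the estimators face, not
photorealism: a wound edge of prescribed signed curvature (gap at the top
of the frame), a cell filling the monolayer side, ER tubules as persistent
curvilinear strokes (3 px wide, persistence 0.9) both through the cell body
(10 % fill) and in the front band, sheets as one-to-few compact blobs from
a strongly smoothed (8 px) thresholded random field — compact lamellar
domains, not speckle, which also keeps the misclassified blur fringe small
relative to sheet area. The front-band tubule fraction is steered to the
requested value by area accounting (sheet budget (1 − f) and tubule budget
f of half the band area); the realized fraction lands within 0.02 of the
request. Optics: Gaussian PSF (σ = 1.5 px at 0.065 µm/px — typical
spinning-disk values), Poisson shot noise and Gaussian read noise; ground
truth masks are defined before noise, so estimator error is measured
against geometry. FA punctae are ellipses with von Mises angles about the
edge tangent, placed with a minimum separation so neighbouring punctae do
not merge (adhesions are discrete objects). Time lapses translate a
taller-than-frame scene along the edge normal and crop a fixed window, so
the moving content is always real texture rather than boundary padding.
Presets `convex-default` (κ = +0.05, f = 0.64) and `concave-default`
(κ = −0.05, f = 0.35) encode the two observed operating points.

What the generator does not emulate: intracellular organelle crowding,
photobleaching, drift, 3D defocus, and the continuum of morphologies
between a tubule and a sheet. Passing tests therefore demonstrate estimator
correctness against controlled truth, not performance on any particular
microscope's data.

## Cell-front mechanics

The front of one migrating cell is a 2D plane-stress section: width
W = 20 µm along the edge, depth D = 15 µm to the clamped rear (monolayer
side), out-of-plane thickness 1 µm. The leading edge is a circular arc of
signed curvature κ placed area-preservingly (mean edge depth = D for every
κ) so energy densities compare cells of equal volume — the same constraint
imposed on the ER itself, whose area fraction φ (default 0.15) is matched
across layouts within 1 % by bisection on each layout's free length
parameter. Lateral edges are free: with both ends of the contractile
cortex band pinned, the purse-string load case cannot deform at all (a
cable with fixed ends carries tension without displacement), which would
make the contraction comparison degenerate.

Regions: an actin cortex band of thickness 0.2 µm along the edge
(E = 100 kPa), linear-elastic cytoplasm (E = 1 kPa) and ER (E = 10 kPa),
ν = 0.45 throughout. The three layouts at equal ER area: perpendicular
tubules (0.3 µm wide) anchored normal to the local edge and bending into
the rear axis over 3 µm — ER tubules follow inward microtubule tracks
rather than converging on the arc's geometric centre, and the paths are
kept inside the lateral bounds; a parallel cluster of edge-tangent tubule
strips spaced 0.6 µm; and one contiguous sheet slab behind the cortex.

Loads. Protrusion is an outward normal traction on the leading edge whose
amplitude grows with convex curvature, p = p₀ (1 + ℓ_p max(κ, 0)) with
p₀ = 0.1 kPa and ℓ_p = 10 µm: lamellipodial force generation is
curvature-dependent (protrusion probability rises with convex curvature),
and a curvature-blind traction would miss that coupling. Contraction is an
isotropic contractile eigenstress σ_a = 0.1 kPa in the cortex band — the
quasi-static limit of a rate-dependent active cortex; the purse-string's
curvature response then emerges from geometry alone. Because the model is
linear, every energy ordering is invariant to the absolute load magnitude;
only ratios of moduli matter, and the flat-edge orderings are verified over
a 4× range of E_ER/E_cyt and a 2× range of φ.

The solver uses 4-node quadrilaterals with incompatible bending modes
(QM6), statically condensed with the volume-averaged strain correction that
restores the patch test on distorted (sheared) elements; 2×2 Gauss
quadrature; direct sparse factorization. Oracles: patch test to 1e-10,
uniaxial-bar energy σ²/2E to 0.5 %, slenderness-10 cantilever tip
deflection within 2 % of Euler–Bernoulli. Default element size 0.1 µm
resolves the tubule width and cortex thickness with ≥ 2 elements; one
uniform refinement moves U by < 2 % and no ordering changes.

Readouts. U = (1/V) ½ ∫ Σ : ε dV with Σ the elastic stress C : ε — the
contractile eigenstress enters as the load, not the integrand, so U ≥ 0 and
U = 0 iff unloaded. Normalized sweeps divide by the κ = 0
perpendicular-layout energy of the same load mode. Leading-edge ("tip")
displacement is the largest nodal displacement magnitude on the edge, so
both the protrusive bulge and the lateral purse-string pull-in register.
The ER energy split projects each element's strain onto the structure's
local axis (the tubule path direction, or the edge tangent for sheets and
parallel clusters), bins elements along the mid-axis, and calls the
cross-section-mean axial strain membrane (stretching) energy and the
residual across the thickness bending energy; fractions sum to 1.

## Numerical and policy choices

- Layout areas quantize to the mesh; sweep-to-sweep ordering gaps carry
  ~0.5 % jitter from this, which is why the saturation check on the
  concave-contraction gap allows 1 % slack.
- Energies within 0.1 % are reported as ties in `ordering_report`.
- Classifier training samples balanced labelled pixels directly from
  ground-truth masks (the synthetic stand-in for marking areas of each
  category by hand); training and evaluation scene seeds never overlap.
- Problem sizes: 256² px scenes, 30-scene validation, 30 k-element default
  meshes, 8-point curvature sweeps — chosen so the full study (analysis
  scripts, tests, acceptance) runs on a laptop-class single core.

## Known limitations

The mechanics model is a 2D section of a 3D cell: out-of-plane cortex
curvature, apical-basal gradients and the nucleus are absent, and the
rate-dependent cortex rheology is reduced to its quasi-static limit with a
single-parameter viscous update left as an extension hook. The
protrusion-curvature coupling length ℓ_p is an assumption (the qualitative
orderings at fixed κ do not depend on it; the growth of the sheet-vs-
perpendicular gap with convex curvature does). Segmentation quality is
reported against synthetic truth; real micrographs with different optics
need retraining on their own labelled regions.
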