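# Methods

## The diffusion model

Drug transport through microneedle-treated skin is modelled as pure
Fickian diffusion, ∂C/∂t = D(∂²C/∂x² + ∂²C/∂y²), on a two-dimensional
cross-section of one needle and its surrounding skin. A patch is an
array of identical needles with fixed spacing; by symmetry each
needle–skin unit is treated as independent, and only the half unit cell
is simulated: the needle's symmetry axis forms the left boundary, the
midline between adjacent needles the right boundary, and the skin
surface the top — all no-flux. The bottom row exchanges drug with the
receptor compartment of a Franz diffusion cell.

Assumptions, in the order they matter:

1. the needle is incompressible and non-degrading once inserted;
2. the drug is initially uniformly distributed (in the needle for
   hydrogel MNs; in the needle-shaped skin cavities plus a donor
   solution layer for plastic MNs);
3. the diffusion coefficient D is uniform and constant in the domain —
   no partition coefficients at the needle/skin or skin/receptor
   interfaces, no temperature dependence;
4. the receptor is well mixed (instant distribution on arrival);
5. the skin membrane is 1 mm thick by default.

Both MN classes use the same solver. Hydrogel needles carry the load in
the needle cells. Plastic needles pre-treat the skin; the drug solution
fills the needle-shaped cavities and a donor layer of configurable
height (default 200 µm) above the skin surface, all initialized at a
common concentration.

### Discretization

The scheme is forward-time centred-space (FTCS) on a uniform grid
(default dx = dy = 2 µm), written in *flux form*: each pair of adjacent
cells exchanges α·(C_neighbour − C_cell) per step with α = D·dt/h².
Boundary cells simply have fewer exchange partners — the five mesh
element classes (corner, bottom corner, edge, bottom edge, internal) —
which realises the no-flux conditions and makes mass conservation exact
to floating-point (verified to 1e-9 relative in the tests). The time
step is min(user dt, 0.9 × dx²dy²/(2D(dx²+dy²))), the explicit-scheme
stability bound (dx²/4D on a square grid); with D = 1000 µm²/min and
dx = 2 µm that bound is 0.001 min. Output times are linearly
interpolated between steps.

Needle rasterization marks, per grid row, the smallest cell set
covering the analytic half-width profile evaluated at the row-centre
depth (`ceil(w/dx)` cells). This covering rule guarantees at least one
marked cell for any needle with positive dimensions and converges
first-order to the analytic cross-section area under refinement; a
pure cell-centre test can drop thin needle tips entirely.

### Receptor coupling

Two receptor modes exist. `sink` fixes the receptor concentration at
zero (the classic perfect-sink Franz assumption) and is used for the
analytic validation below. `finite` (default) treats the receptor as a
well-mixed compartment of volume V (default 5000 µL, a typical Franz
receptor; no published value constrains it) exchanging bidirectionally
with the bottom row. Its 2D equivalent is a virtual bottom row of area
(V / diffusion-window area) × half-cell width: the needles tile the
window and the whole receptor sits beneath it, so the equivalent depth
is V divided by the window area. This mapping is deliberately
independent of the needle count, which preserves an exact physical
invariance: splitting a fixed total load over more needles leaves the
permeation curve unchanged. The finite receptor produces the observed
plateau — permeation stops when needle, skin and receptor
concentrations equilibrate.

### From 2D fraction to reported permeation

The 2D simulation is a mass-fraction machine. The receptor mass
fraction of one needle's load multiplies load-per-needle × needle count
to give the patch-level cumulative mass, which is divided by the
device's diffusion window — 1.00 cm² (vertical cell) or 1.13 cm²
(horizontal cell) — and reported as µg per 1 cm². The percentage
response is 100 · m_t / m_total.

### Validation against an analytic oracle

With a degenerate "needle" spanning the whole cell width the model
reduces to 1D release from a uniformly loaded slab with one sealed face
and one perfect-sink face, whose fractional release has the classical
series solution 1 − Σ 8/((2n+1)²π²)·exp(−D(2n+1)²π²t/4L²). The solver
matches this series within 1% absolute at dx = 2 µm (the test uses a
200 µm slab so the dy/2 offset of the discrete sink boundary stays well
inside that band). Sensitivity behaviours are verified as properties:
permeation increases with D, needle length and loading; loading moves
the output far more than length over their plausible ranges; and grid
refinement converges.

### Default problem sizes

Production resolution is dx = dy = 2 µm. The test suite and the
synthetic-data generator run the same solver at 10–50 µm grids and
shorter horizons — the package's chosen trade-off between resolution
and batch throughput; the grid-convergence property test quantifies
what coarsening costs.

## Geometry

Hydrogel needles are conical frustums, plastic needles regular square
pyramids. Skin-contact surface areas exclude the base face attached to
the patch backing: frustum S = πr² + π(R + r)l (top cap + lateral
surface; r top radius, R base radius, l slant height), pyramid
S = 4·(a/2)·√((a/2)² + h²) (four lateral triangles). Patch total
S_total = S·n. Internal lengths are µm; areas are reported in mm².
When only record-level fields (MN type, length, patch area) are known,
`synthetic_data.needle_for` inverts these formulas — directly for the
pyramid, numerically for a frustum with a fixed 1:10 tip:base taper.

Needle lengths in compiled datasets reach 1250 µm, slightly beyond the
nominal 1 mm membrane; for such records the simulated membrane is
deepened to the needle length plus two cells so the tip never touches
the receptor boundary.

## The statistical models

Records are encoded as nine numeric columns: one-hot skin type (R, H),
one-hot MN type (hydrogel, plastic), then needle length (µm), patch
needle surface area (mm²), drug loading (µg), permeation time (h) and
molecular weight (Da). Drug identity is *not* a feature — predictions
depend only on measurable device/drug properties.

* **MLR** is ordinary least squares via `numpy.linalg.lstsq`. The
  one-hot pairs plus intercept are collinear by construction, so the
  minimum-norm solution is returned with a warning; individual one-hot
  coefficients are then not identifiable but fitted values and the
  coefficients of varying numeric features are.
* **RF** is scikit-learn's `RandomForestRegressor`;
  **XGBoost** is `XGBRegressor`. Reference hyperparameters per target
  are recorded in `REFERENCE_HYPERPARAMS`; the boosted model's γ and λ
  regularizers stay at library defaults (γ = 0, λ = 1) since no
  reference values constrain them, and they are recorded in the model
  card. Training rows are sorted into a canonical order before fitting
  so that seeded fits are invariant to the caller's row order
  (bootstrap draws index rows by position).
* **Feature importance** pools one-hot columns back to their semantic
  feature and normalizes to unit sum. RF uses impurity importance,
  XGBoost total gain.

Two separate models are fitted per family — one for the amount target,
one for the percentage — never a multi-output model.

## Evaluation protocol

One uniform random 7:3 split (train size = round-half-up of 0.7·N;
for N = 191 that is 134/57), models fitted on the training rows,
RMSE and R² computed on the held-out rows. R² may be negative
out-of-sample and is reported unclipped. The mechanistic route joins
the comparison only when per-drug diffusion coefficients are supplied;
it is evaluated on the same test rows without training. A repeated-
split mode (loop over seeds) is used in the tests to check stability
of the method ordering. Leave-one-drug-out holds out every row of one
compound to measure extrapolation.

## Synthetic data

The generator emulates a compiled Franz-cell database: six permeants
with MW 64–66,430 Da, patch designs drawn from a seven-entry pool of
(MN type, length 700–1250 µm, patch area 26.76–36.86 mm², needle
count 64 or 351), loadings log-uniform in 50–70,940 µg, and a typical
sampling grid 0.25–48 h. Plastic patches are assigned the vertical
device, hydrogel patches the horizontal one. Diffusion coefficients
come from a Stokes–Einstein-like map D = clip(c·MW^(−1/3), 50, 1000)
µm²/min anchored at D(194 Da) = 600 µm²/min — small molecules diffuse
near the middle of the plausible range, the 66 kDa protein near the
lower clip.

Noise is multiplicative lognormal on the amount (sd 0.15, the 10–20%
coefficient of variation typical of in-vitro permeation replicates);
the percentage is recomputed from the noisy amount so each row stays
internally consistent. A fixed 191-row "replica" configuration mirrors
the composition of the compiled experimental database (lidocaine 73
rows = 38%, five other drugs covering the remainder) for bookkeeping
and pipeline tests.

What the generator does *not* emulate — and hence what passing tests on
it cannot show: real skin heterogeneity (stratum corneum vs dermis),
drug–skin binding and metabolism, partitioning between needle material
and tissue, inter-donor variability, and any systematic (non-lognormal)
measurement error. Results on synthetic data validate the pipeline's
mechanics and the qualitative method ordering, not clinical
predictive accuracy.

## Degenerate inputs and tie-breaks

Zero-dimension needles rasterize to an empty mask and simulate as "no
drug anywhere" (an error, since no cell can carry load); D = 0 or zero
loading short-circuit to an all-zero curve. Dataset rows with
percentage > 100 are retained but flagged, never silently dropped;
out-of-range times/loadings warn rather than fail. Grids smaller than
2×2 and unknown categorical levels are rejected outright.

## Known limitations

* The finite-receptor volume and the needle spacing (half-cell width,
  default 300 µm ≈ half of √(window/needles) for a 351-needle patch)
  are not constrained by published values; absolute plateau levels
  therefore depend on configuration, though orderings and invariances
  do not.
* The 2D half-cell with uniform D is a strong simplification of 3D
  transport through layered skin.
* MLR coefficients on the one-hot design are reported as the
  minimum-norm solution; interpret only the identifiable combinations.
* Tree-model accuracy claims on synthetic data are bounded by the
  generator's noise level; they transfer to experimental data only in
  their qualitative form (tree ensembles ≫ linear model, extrapolation
  to out-of-range drugs fails).
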