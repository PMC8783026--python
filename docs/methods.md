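# Methods

This note documents the models, parameter choices and numerical decisions
behind `defect2eis`, in the order the pipeline runs.

## Defect sets and the clustering statistic σ

A defect set is an ordered list of center coordinates (nm, image convention:
origin top-left, y downward) on a rectangular field, with a per-defect
bounding-box half-width (default 25 nm, i.e. the equalised 50 nm detection
box; the source AFM pixel pitch is 2000 nm / 512 px = 3.90625 nm).

The clustering statistic σ is the standard deviation (ddof = 1) of the
Voronoi cell areas of the defect centers, each multiplied by the defect
density — equivalently divided by the mean cell area, so the normalised
areas average to one. Cells are clipped to the field rectangle *exactly* by
tessellating the point set together with its mirror images across all four
field edges: every original cell is then bounded by the field, and the cell
areas sum to the field area to machine precision (asserted in tests at 1e-6
relative). σ = 0 for a perfect lattice; a homogeneous Poisson pattern gives
σ ≈ 0.53–0.56 at N = 200 (boundary clipping pushes the unbounded-window
value of ≈ 0.53 up slightly); clustered membranes observed by AFM sit near
0.8–1.2. σ is computed on the full field, not per image fragment. Duplicate
coordinates are rejected (degenerate tessellation), as is N < 3.

## Detection scoring

True and predicted defects are compared through their equalised
50 nm × 50 nm boxes. Matching is greedy, one-to-one, by ascending Euclidean
center distance with ties broken by lower true then lower predicted index;
this is deterministic and near-optimal for sparse sets (tests check it
against exhaustive maximum-cardinality matching on small random sets, ≥95%
agreement). A pair is a true positive only if IoU is strictly above the 0.5
threshold; assigned pairs that fail the threshold still consume their
indices. Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic
mean (0 when both are 0, NaN with a warning when a denominator vanishes),
Q_N = predicted/true density.

A geometric note that matters for expectations: two 50 nm boxes offset
diagonally lose IoU > 0.5 at about 9.2 nm *per axis*, well before the
16.7 nm axis-aligned threshold. With 4 nm Gaussian jitter per axis, roughly
0.4% of matches therefore break, and jitter-only F1 for N ≈ 170 lands in
0.98–1.00 rather than exactly 1. The published synthetic-study F1 maxima
(0.98/1.00/0.99) show the same effect. Survival bounds additionally assume
defects separated at the box scale; annotated ground truth is
resolution-limited in this way, and the test fixtures for jitter-survival
anchors use a 40 nm hard-core pattern accordingly.

## Degradation simulation

Each synthetic "detector output" is built from the truth by (1) jittering
every coordinate with independent N(0, s²) draws per axis (s = 4 nm; the
jitter-equation in compact notation shares the symbol δ between x and y, but
independent draws are the only reading consistent with isotropically
imperfect localisation), (2) removing n_remove defects, each the surviving
defect nearest to a fresh sample of the Gaussian KDE (bandwidth 400 nm) of
the true coordinates, and (3) adding n_add defects at KDE samples,
rejection-resampled into the field. Sampling removals and additions from the
same KDE keeps the degraded set's clustering close to the truth (batch σ
histograms bracket the true σ). Removal targets are drawn without
replacement; jittered coordinates are clipped to the field.

The study design steps n_remove and n_add from 0 in increments of
round(0.03 N), strictly below floor(N/2), taking the full Cartesian product.
This reproduces the published case counts for all three test surfaces:
N = 172 → 18² = 324, N = 158 → 16² = 256, N = 97 → 16² = 256. N < 17 (zero
step) is rejected with advice to supply cases explicitly. Batch case seeds
are spawned deterministically from one parent seed, so batches are exactly
reproducible.

## EIS forward model

The 3D electrochemistry is reduced to a 2D thin-film formulation of the
submembrane reservoir: potential phasor u on the patch Ω obeys

    g_s ∇²u − iω(C_H + C_m) u = −iω C_m U₀,

with u = U₀ on every defect rim (ideal defect: zero internal pore
resistance), zero normal flux on the patch boundary (a finite scanned patch,
no periodic images), and admittance Y = (1/AU₀)∫ iωC_H u dA, with u ≡ U₀
over the defect disks. Defaults (all overridable): C_m = 0.8 µF/cm²,
C_H = 9.0 µF/cm², d_sub = 1.5 nm — literature-typical tBLM values —
and ρ_sub = 10^4.5 Ω·cm, the conventional prior estimate. The drive
amplitude U₀ cancels (linear system; asserted). Bulk-solution series
resistance is off by default (phase → 90° at high f) and available as
`r_solution` (Ω·cm²), applied as Y → Y/(1 + R·Y).

Zero defects gives the exact series-capacitor limit
Y = iω C_m C_H/(C_m+C_H), returned analytically (flat 90° phase, hence no
interior phase minimum — reported as an error by the feature extractor).

### Discretisation

Linear (P1) triangular elements on a point cloud triangulated by Delaunay:
geometric rings of nodes around each rim (first ring on the circle, ≥ 24
nodes by default ⇒ rim elements ≈ r_def/4; radius growth 1.2 per ring) blend
into a hexagonal background lattice (spacing `h_far`, default field/100).
Ring patches are capped at 0.45× the defect's nearest-neighbour distance so
patches in clusters do not collide, and a coarse-to-fine thinning pass drops
any candidate node that crowds an already-kept one (rim nodes are always
kept). Triangles whose centroid falls inside a defect disk are removed
(holes); their area enters the admittance integral analytically with u = U₀.
Mass matrices are lumped. One sparse complex LU solve per frequency;
stiffness/mass assembly is reused across frequencies and across the whole
ρ_sub axis of a fit grid (the mesh depends on r_def only).

Overlapping defect disks (center distance ≤ 2 r_def) are a geometry error:
the Dirichlet rims would intersect. During grid fits, radii that make a
clustered set infeasible are scored l1 = ∞ and flagged rather than aborting
the fit. Defects whose disk crosses the field edge are meshed with the disk
clipped to the field.

### Verification

An independent semi-analytic oracle solves the radially symmetric problem
for a single centered defect in a disk domain with complex modified Bessel
functions (I₀, K₀ of argument kr, k² = iω(C_H+C_m)/g_s), with the annulus
admittance integral in closed form; in the |kR| overflow regime the outer
boundary is unreachable and the pure-K₀ decay branch is used. The 2D FEM
solver on the same disk geometry agrees with the oracle to < 1% in |Y| and
< 0.3° in phase across 0.1 Hz–100 kHz at the default mesh; the oracle itself
is cross-checked against a 1D finite-difference solve on 10⁴ radial nodes
(< 0.1° phase). Physical sanity checks: passivity (Re Y ≥ 0,
0° ≤ arg Y ≤ 90°), monotone f_min in ρ_sub (f_min ∝ g_s exactly, since ω and
g_s enter only through ω/g_s) and in defect density; at equal density a
strongly clustered pattern yields measurably different phase-minimum
features than a homogeneous one.

### Spectral features

The phase minimum is located by discrete argmin refined with a three-point
parabola in (log₁₀ f, phase); the vertex formula is exact for non-uniform
log-spacing and clamped to the bracketing interval. A minimum at either grid
endpoint raises an error. Features are stable to < 0.01 decade under grid
doubling. Spectrum deltas are true-minus-predicted: Δf_log in decades,
Δarg Y in degrees; both negate under argument swap.

## Parameter fitting

Fixed grid: r_def ∈ {1, 3, …, 13} nm × ρ_sub ∈ {10^4.0, …, 10^5.0} Ω·cm
(steps of 0.1 in the exponent), 77 combinations. The published minimisation
mixes decades and degrees without a stated weighting; here the phase term is
divided by 90° so both terms are O(1): l1 = |Δlog₁₀ f_min| + |Δarg Y|/90.
The weight is an argument (`phase_scale`). Ties break toward smaller ρ
exponent, then smaller radius. Self-generated on-grid references are
recovered exactly (l1 = 0 at the generating grid point, since the solver is
deterministic and the mesh depends only on r_def). Under feature noise
(±0.05 decade, ±1°) the recovered ρ exponent spreads far less than the
recovered radius (both normalised to their grid ranges): f_min is weakly
sensitive to r_def, so ρ_sub is the better-determined parameter.

## Synthetic data

*Point patterns.* Homogeneous Poisson (N ~ Poisson(density·area), uniform
positions) or Thomas/Neyman–Scott clusters (Poisson parents on a field
padded by 3 cluster spreads for edge-unbiased density; Poisson offspring
counts; Gaussian scatter; off-field offspring discarded). Three presets
emulate the imaged surfaces' regimes — densities 6.06–10.75 µm⁻², σ roughly
0.8–1.2 — calibrated by matching density and σ, not by mechanism.

*AFM-lookalike images.* Height maps at the 3.90625 nm/px pitch: correlated
Gaussian roughness (RMS 0.3 nm, correlation 40 nm), per-scanline offsets
(0.05 nm), and a Gaussian pit (depth 2 nm, apparent radius 15 nm) per
defect. These are lookalikes for exercising the detection pipeline — no AFM
tip convolution, feedback artefacts or stitching seams — so closed-loop
detection tests demonstrate pipeline correctness, not real-image detector
performance. The published detection scores on real images are out of reach
without the original scans, by design.

*Blob detector (CNN stand-in).* Multi-scale Laplacian-of-Gaussian on the
inverted, depth-normalised image; the detection threshold is a fraction of
the deepest-pit response. At defaults it recovers well-separated rendered
defects perfectly and produces ≤ 2 false positives per 4 × 4 µm of pure
noise at a conservative threshold (0.35). Tight clusters (spread ≈ 50 nm)
merge pits and lower recall relative to matched homogeneous patterns — the
same failure mode reported for real detectors on clustered surfaces.

*Reference spectra.* Forward-model output with independent Gaussian phase
noise per frequency (the complex admittance is rotated, keeping |Y|
consistent); 0.5° noise moves f_min by < 0.05 decade on average.

## Problem sizes and runtime choices

Accuracy and fit studies in the tests and the acceptance script run at
reduced scale, chosen so the full pipeline exercises every code path on one
core in minutes: study surfaces of 20–30 defects on 1.5–2 µm fields, meshes
with `h_far` = 60–75 nm / ring growth 1.3–1.45, and frequency grids of 3–5
points per decade over 0.1 Hz–10 kHz. Feature *differences* at this scale
are within ~0.01 decade and ~0.3° of fine-mesh values, well inside the 0.1
decade fit-grid resolution; single-spectrum reference computations (oracle
comparisons) use the default fine mesh. The degradation batches run at full
published scale (256–324 cases), since detection scoring is cheap.

## Known limitations

- The thin-film reduction ignores the 3D bathing electrolyte; with the
  series element off, the high-frequency phase tends to 90° rather than
  rolling off through the solution resistance.
- Ideal defects: the pore interior is an equipotential at the drive
  amplitude (no internal pore resistance or access resistance).
- The zero-flux rectangular boundary mirrors a finite scanned patch; a
  membrane continuing beyond the patch would lower edge-cell impedance
  contributions slightly.
- Greedy matching is not globally optimal for pathological configurations
  (it can differ from maximum-cardinality matching in ≤ 5% of crowded small
  sets).
- Rendered images do not model tip geometry; detector scores on them say
  nothing quantitative about real AFM imagery.
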