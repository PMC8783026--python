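# defect2eis

From AFM images of damaged membranes to impedance spectra — and back to
physical membrane parameters.

## The problem

Pore-forming toxins punch nanometer-scale conductive defects into tethered
bilayer lipid membranes (tBLMs). Atomic force microscopy (AFM) can image the
defects and give their coordinates; electrochemical impedance spectroscopy
(EIS) measures the electrical response of the same membrane. The two are
linked by a physical model: each defect shorts the AC drive into the thin
aqueous reservoir between bilayer and electrode, from where the current
spreads laterally and leaks out capacitively. Given defect coordinates, the
EIS spectrum is therefore *predictable* — and comparing predicted with
measured spectra lets one estimate parameters that neither technique yields
alone, notably the specific resistance ρ_sub of the submembrane reservoir
and the electrochemical defect radius r_def.

Automated defect detection is imperfect, so this package also quantifies how
detection accuracy propagates into spectral-feature errors: it scores
predicted against true coordinate sets (IoU matching → precision, recall,
F1, and the density ratio Q_N), and generates synthetic "detector outputs"
of controlled accuracy by KDE-guided defect removal/addition plus coordinate
jitter.

## The model

The submembrane potential phasor u obeys a complex thin-film equation on the
membrane patch Ω:

    g_s ∇²u − iω(C_H + C_m) u = −iω C_m U₀      in Ω
    u = U₀                                       on defect rims (radius r_def)
    ∂u/∂n = 0                                    on the patch boundary

with sheet conductance g_s = d_sub/ρ_sub, membrane capacitance C_m,
Helmholtz capacitance C_H and drive amplitude U₀. The area-normalised
admittance is Y(ω) = (1/AU₀)∫ iωC_H u dA. Its Bode phase curve arg Y(log f)
has an interior minimum whose coordinates (f_min, arg Y_min) encode defect
density and membrane parameters: f_min grows roughly linearly with defect
density and inversely with ρ_sub.

The equation is solved by linear finite elements on a graded Delaunay mesh
(rim-resolving rings blending into a hexagonal background lattice), one
sparse complex solve per frequency. A semi-analytic radial solution (complex
modified Bessel functions) for a single centered defect serves as an
independent numerical oracle; the two agree to <1% in |Y| and <0.3° in
phase.

Parameter recovery is a fixed 7 × 11 grid search over r_def ∈ {1,3,…,13} nm
and ρ_sub ∈ {10^4.0, 10^4.1, …, 10^5.0} Ω·cm (77 combinations), minimising
the L1 distance between phase-minimum coordinates, |Δlog₁₀ f_min| +
|Δarg Y_min|/90°.

## Worked example

```python
import numpy as np
import defect2eis as d2e

# 1. ground truth: clustered pattern on a 4 x 4 um field
truth = d2e.sample_point_process(
    d2e.PointProcessParams(kind="thomas", density=6.06, parent_density=1.3,
                           cluster_spread=200.0, seed=15))

# 2. synthetic detector output and its score
degraded = d2e.degrade(truth, d2e.DegradationParams(n_remove=12, n_add=9, seed=1))
match, metrics = d2e.evaluate(truth, degraded)

# 3. forward EIS model of both sets and spectral comparison
mp = d2e.MembraneParams(r_def=2.7, rho_sub=10**4.5)
fg = d2e.FrequencyGrid.logspaced(0.1, 1e4, 5)
mesh = d2e.MeshParams(h_far=60.0, growth=1.3, min_ring_points=16)
sp_true = d2e.model_spectrum(truth, mp, fg, mesh)
sp_pred = d2e.model_spectrum(degraded, mp, fg, mesh)
delta = d2e.compare_spectra(sp_true, sp_pred)

# 4. recover (r_def, rho_sub) from a noisy reference spectrum
reference = d2e.synth_reference_spectrum(truth, mp, fg, noise_sd_phase_deg=0.5,
                                         seed=2, mesh=mesh)
result = d2e.fit(truth, reference, d2e.FitGrid(), d2e.MembraneParams(), fg, mesh)
```

This prints (a couple of minutes on one core):

```
N = 97, N_def = 6.06 um^-2, sigma = 1.09
TP/FP/FN = 84/10/13, precision = 0.894, recall = 0.866, F1 = 0.880, Q_N = 0.969
true spectrum: f_min = 272 Hz, argY_min = 47.0 deg
delta_f_log = +0.027, delta_argY = -0.09 deg
fit: r_def = 1 nm, rho_sub = 10^4.4 Ohm cm, l1 = 0.0129
```

Reading the numbers: the clustered 97-defect surface (clustering statistic
σ = 1.09, where a homogeneous pattern gives ≈ 0.53) was degraded to a
detector-like output with F1 = 0.88; despite 23 wrong detections the phase
minimum of its predicted spectrum moved by only 0.027 decades — spectral
features depend mainly on defect density, not on which defects were found.
The grid fit against a 0.5°-noise reference recovers ρ_sub within one grid
step (10^4.4 vs 10^4.5) while r_def lands far from the generating 2.7 nm:
the phase minimum is weakly sensitive to the radius, so ρ_sub is determined
considerably better than r_def.

A CLI mirrors the library: `defect2eis simulate|eval|degrade|model|compare|fit|study`
(every stochastic subcommand requires `--seed`).

## Layout

| module | contents |
| --- | --- |
| `defect_sets` | `DefectSet` container, density, Voronoi clustering σ, CSV I/O |
| `detection_eval` | IoU, greedy matching, precision/recall/F1/Q_N |
| `degradation_sim` | KDE model, jitter/remove/add degradation, case grids, batches |
| `eis_model` | thin-film FEM solver, radial Bessel oracle, phase-minimum features |
| `param_fit` | 77-point (r_def, ρ_sub) grid search |
| `synthetic_data` | point processes, AFM-image rendering, blob detector, noisy references |
| `pipeline` / `cli` | accuracy & fit studies, manifests, command-line interface |

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
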