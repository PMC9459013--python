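# stenoflow

Fast surrogate prediction of mean blood flow in stenosed arteries.

Clinically useful hemodynamic quantities (jet velocities, pressure drop
across a narrowing) come from CFD, but high-fidelity simulation is far
too slow for interactive use. `stenoflow` implements a hybrid
CFD + learning chain for idealized stenosed vessels at Re = 100:

1. **Geometry** — a stenosis of axial extent D (the healthy diameter) is
   a fifth-order polynomial wall profile `y(x) = a1 x^5 + … + a6` with
   clamped ends `y(0) = y(D) = D`, `y'(0) = y'(D) = 0`, parameterized by
   depth h and throat location x\*; 3D tubes are axisymmetric
   (`R(x) = y(x)/2`) or asymmetric (a periodized-Gaussian circumferential
   invasion weight).
2. **Flow solver** — an immersed-boundary multi-relaxation-time
   lattice-Boltzmann method (D2Q9/D3Q19, Guo forcing, non-equilibrium
   extrapolation inlet/outlet, feedback (Goldstein) immersed-boundary
   walls with a 4-point Peskin kernel) produces the time-averaged,
   nondimensional fields `u_m = ū/U0`, `c_p = (p̄ − p_ref)/(½ρU0²)` on
   the region from D upstream to 4D downstream of the stenosis.
3. **Shape encoder** — a convolutional encoder–decoder compresses binary
   stenosis rasters (214×214 in 2D, 61³ in 3D) to a low-dimensional
   feature vector (16 / 8 values) supervised by surface-coordinate
   reconstruction.
4. **Pointwise surrogate** — a 5×128 fully-connected network maps
   (shape features, node coordinates) → (mean velocities, pressure
   coefficient), trained with RMSE loss and Adam; once trained it
   replaces the CFD solver for mean-field prediction.

Everything is generated internally — there is no external data. The
neural networks run on a small numpy engine included in the package
(`stenoflow.nn`), gradient-checked against finite differences.

## Worked example

Validate the solver against plane Poiseuille flow (IB-walled channel,
Re = 100, mesh D/25):

```python
>>> from stenoflow.pipeline import channel_validation
>>> rep = channel_validation(mesh=25, dev_tol=5e-5, T_avg=0.5, max_steps=30000)
>>> rep["result"].steps
13250
>>> round(rep["centerline_ratio"], 4)
1.0028
>>> round(rep["l2_rel_err"], 4)
0.0112
```

The centerline velocity reaches 1.5 U0 to 0.3% and the whole profile
matches the parabola of effective width D + 0.5Δx to ~1% in L2.

Simulate one stenosis and inspect the physics:

```python
>>> import numpy as np
>>> from stenoflow import SimConfig, run_case, solve_stenosis_polynomial
>>> from stenoflow.pipeline import extract_region
>>> shape = solve_stenosis_polynomial(D=1.0, h=0.5, x_star=0.5)
>>> cfg = SimConfig(dimension=2, Re=100.0, cells_per_D=25, T_avg=8.0,
...                 dev_tol=1e-3, dev_max_D=20.0)
>>> field = extract_region(run_case(cfg, shape))
>>> round(float(field.u_m.max()), 2)   # jet through the 50% throat
2.73
>>> up = field.coords[:, 0] < -0.5     # upstream of the stenosis
>>> round(float(field.u_m[up].max()), 2)
1.37
```

The throat jet accelerates well above the upstream centerline value
(continuity) and `field.cp_m` drops across the narrowing.

The command line wraps the same library: `stenoflow gen` samples and
rasterizes shapes, `stenoflow sim` runs archived shapes, `stenoflow
validate-pipe` prints the Poiseuille error report, `stenoflow
train-shape` / `stenoflow pipeline` / `stenoflow predict` train and
apply the learning stages. `stenoflow pipeline --config cfg.yaml --out
run/` executes the five stages (generate → encoder → simulate →
assemble → surrogate) with a manifest that lets interrupted runs resume.

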