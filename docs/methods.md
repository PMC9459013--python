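# Methods

`stenoflow` predicts time-averaged blood flow in idealized stenosed
arteries with a four-stage chain: a parametric geometry model, an
immersed-boundary multi-relaxation-time lattice-Boltzmann (IB-MRT-LBM)
solver that generates mean-flow training data at Re = 100, a
convolutional shape encoder, and a pointwise fully-connected surrogate
that maps (shape features, node coordinates) to the mean velocity and
pressure-coefficient fields.  This note records the model assumptions,
the numerical choices, and what the desk-scale tests do and do not show.

## Stenosis geometry

A stenosis of axial extent D (the healthy diameter) is a fifth-order
polynomial wall profile y(x) clamped to the healthy wall:
y(0) = y(D) = D, y'(0) = y'(D) = 0.  The two remaining degrees of
freedom are parameterized by the depth h = D − min y and the throat
location x\*, through y(x\*) = D − h and y'(x\*) = 0; the resulting 6×6
linear system is uniquely solvable and yields a single-throat narrowing.
Profiles whose quintic leaves (0, D] are rejected and redrawn — the
feasible throat band is roughly x\* ∈ [0.4 D, 0.6 D] regardless of
depth.  Sampling is uniform over configurable (h, x\*) ranges; the
defaults are h ∈ [0.3, 0.7] D and x\* ∈ [0.4, 0.6] D.  In 2D the
stenosis sits on one wall (the other wall stays flat); the axisymmetric
3D tube has local radius y(x)/2; asymmetric 3D tubes modulate the radial
invasion with a periodized-Gaussian angular weight w(θ) of center θ0,
spread σ, and peak amplitude A ≤ 1, which reduces exactly to the
axisymmetric tube for A = 1, σ → ∞.

Rasters are binary supercovers: 214×214 pixels over the stenosis extent
in 2D (the wall is a polynomial graph, so each column's exact y-range
follows from endpoint values and derivative roots — the rasterization is
exact and scale-consistent under 2× downsampling), and 61³ voxels at
0.02 D spacing in 3D (dense surface sampling at one-third voxel pitch).

## IB-MRT-LBM solver

D2Q9/D3Q19 lattices with the standard orthogonal moment bases; conserved
moments relax at 0, viscous moments at 1/τ with ν = (τ − 1/2) c_s² Δt
and c_s = Δx/(√3 Δt), and the free (ghost) rates at documented defaults
(2D: s_e = s_ε = 1.4, s_q = 1.2; 3D: s_e = 1.19, s_ε = 1.4, s_q = 1.2,
s_π = 1.4, s_m = 1.98).  Equilibrium moments are taken as M g_eq with
g_eq the second-order Maxwellian, so collision is applied in population
space through precomputed matrices A = M⁻¹SM and B = M⁻¹(I − S/2)M.
Body forces use the Guo scheme with the half-force velocity correction.
All cases run in lattice units Δx = Δt = 1 with inlet speed U0 = 0.05
(Mach ≈ 0.087) unless noted; Re = U0·D/ν = 100 throughout.

Walls are rigid and enforced by a feedback (Goldstein-type) immersed
boundary: markers at half the fluid spacing carry a PI force law
F = α∫(U_m − U_wall)dt′ + β(U_m − U_wall) with the 4-point Peskin
kernel for interpolation and (adjoint) spreading.  Two choices matter
for stability and accuracy:

- The feedback velocity is the half-force-corrected velocity of the
  *previous* step.  Feeding back the bare pre-force velocity leaves a
  full step of loop delay, which destabilizes the integral gain in slow
  wind-up; including the half force removes half the delay and makes
  strong gains stable.  Defaults α = −0.15, β = −1.5 (lattice units)
  give interior marker slip of order 10⁻⁶ U0 in the plane-channel test.
- With converged integral feedback, no-slip holds exactly *at* the
  markers and the diffuse force shell displaces the effective
  hydrodynamic wall about 0.78 Δx inside the marker surface (measured on
  body-force-driven periodic channels/pipes at D/25 and D/50; the offset
  in cells is mesh-independent).  Markers are therefore placed a
  calibrated 0.78 Δx outside the geometric wall along the local normal,
  so the effective lumen equals the nominal geometry plus the standard
  half-cell diffuse-interface correction: the measured parabolic-fit
  diameter of the IB pipe is D + 0.5 Δx to within a tenth of a cell,
  the convention used by the analytic validation profiles.

Domain closure: a non-equilibrium-extrapolation (NEE) velocity inlet, an
NEE outlet at fixed reference density with copied velocity (pressure
anchor), NEE no-slip lateral faces, and the IB wall in between.  The
inlet prescribes a plug of mean speed U0 across the *effective lumen*
(wall + quarter-cell offset), tapered to zero over two cells strictly
inside the lumen with the plateau raised to conserve the flux U0·A_eff
exactly.  Keeping the inlet shear layer inside the lumen and closing the
exterior portions of both faces matters: a hard plug edge at the
face/wall corner drives a parasitic recirculation through the sealed
exterior gap that robs up to 10% of the lumen flux (the faces are not
mass-conserving, so such loops are self-sustaining).

Initial fields use the analytic developed profile of the effective lumen
(quiescent outside); the steady/statistically-steady state does not
depend on this, it only shortens the transient.

Each case runs until five centerline probes change by less than a
relative tolerance per 0.5 D/U0 interval (default 10⁻³ for stenosed
cases), or until a development cap `dev_max_D` (in D/U0) is reached —
deep stenoses at Re = 100 shed vortices and never meet a steady-state
criterion; their wake limit cycle needs ≈ 30–40 D/U0 to establish, and
starting the averaging early biases the mean field by several percent of
the peak velocity.  Mean fields are then accumulated over `T_avg` D/U0
(the full-scale reference window is 50; desk-scale runs use 15 with a
residual window-sensitivity of order 1–2% of the peak velocity near deep
stenoses).  Monitoring aborts on NaN or non-positive density.

Mean fields are nondimensionalized as u_m = ū/U0 and
c_p = (p̄ − p_ref)/(½ρU0²) with p = c_s²(ρ − ρ0) and p_ref the
outlet-plane mean pressure (LBM pressure is defined up to a constant; a
per-run outlet reference makes c_p comparable across shapes).  The
training region keeps lumen nodes with x ∈ [x_start − D, x_end + 4D]
(the stenosis extent is [x_start, x_end], length D), coordinates in
units of D relative to the stenosis start.

Validations: the Taylor-Green vortex checks ν = (τ − ½)c_s²Δt to 1%;
the IB plane channel reaches centerline 1.5 U0 within 0.5% at D/25; the
uniform-inflow 3D pipe at D/25 measured 5D from the inlet matches
u = 2U0(1 − 4r²/D_eff²), D_eff = D + 0.5Δx, with centerline error
≈ 0.7% and L2 error ≈ 0.7%; refinement studies on streamwise-periodic
driven segments isolate the discretization error and decrease
monotonically from D/25 to D/50.

## Shape encoder (CNN)

Encoder-decoder supervised by surface-coordinate reconstruction: three
convolution stages (32/64/128 filters, kernel 4 per axis, ReLU) with 3×
max pooling after the first two stages (2D: 214→71→23 with floor
division; 3D: 61→21→7 with ceiling), then fully-connected layers
128–128–n_f–128–128 with tanh activations around the bottleneck
(n_f = 16 in 2D; 8 by default in 3D, with 16/32 available for the
feature-count study), and a linear output: 201 wall ordinates in 2D, 400
(radius, axial) surface points in 3D.  Loss is the mean squared
coordinate error; the optimizer is Adam.  The full-scale learning rate
is 10⁻⁴ (with ~1000-sample datasets); desk-scale 2D runs use 3×10⁻⁴
with an encoder dataset an order of magnitude larger than the simulated
set (geometry-only shapes are nearly free) so the code stays in the
tanh's responsive range — under-populated encoder datasets rail most
bottleneck units to ±1 and the resulting near-binary codes cannot be
interpolated by the surrogate.  The 3D encoder
instead uses 2×10⁻⁴: Adam's normalized steps saturate the tanh
bottleneck of the 43904-input dense stage within one epoch at 10⁻³,
collapsing every raster onto the same feature vector.  Labels are
standardized per entry during optimization (and de-standardized by the
decoder): most surface coordinates barely vary across shapes, and on
the raw scale the decoder can fit the dataset-mean surface without ever
sending gradient to the encoder.  Binary {0,1} rasters are fed without
standardization.

## Pointwise surrogate (DNN)

Inputs are the shape feature vector plus the node coordinates (input
width n_f + d); five hidden layers of 128 rectified units; linear output
of width 3 (2D: u_m, v_m, c_p) or 4 (3D: +w_m).  Loss is the RMS error;
Adam starts at 10⁻³ and halves on validation plateaus (patience 10)
down to a 4×10⁻⁵ floor.  Feature vectors are standardized with
training-split statistics stored on the model; coordinates are already
order-one.  Targets are scaled by their per-output training standard
deviation during optimization and rescaled at prediction — c_p spans
roughly ±12 dynamic heads across a deep stenosis while the velocities
span ~±4, and an unweighted loss would starve the velocity outputs.
Splits are by whole simulations, never by node.  Training-row
subsampling per simulation (validation fields kept complete) bounds the
table size; both the subsampling and the batch order are seeded, so
training histories are bit-reproducible.  At prediction time, feature
vectors outside the training hull are clipped per dimension (with a
warning): rectifier networks extrapolate linearly without bound, and a
shape whose features fall outside the trained region would otherwise
receive arbitrarily large fields.  The guard is inactive when features
lie inside the hull, which is the expectation at full scale.

## Synthetic-data realism and desk-scale limits

All data are generated internally; the generator *is* the study: plug
inflow at Re = 100, rigid walls, Newtonian fluid, single-throat
quintic stenoses.  Real arteries add pulsatility, compliance,
non-Newtonian rheology, branching, and imaging noise — none of which
these tests exercise.  Within the model, the desk-scale studies differ
from the full-scale ones in three measured ways: coarser meshes (D/25 in
2D, D/12 in 3D versus D/50+), shorter averaging windows (15 versus 50
D/U0, worth ~1–2% of peak velocity near deep stenoses), and far fewer
training simulations.  The held-out prediction error of the surrogate is
dominated by interpolation across shape space and scales roughly as
n_train^(−1/2); the full-scale studies (100–120 simulations) reach
max local velocity errors below 5%, while desk-scale runs land
proportionally higher (roughly 10–27% at 10–30 simulations in 2D, and
11–20% mean absolute error for the 5-simulation asymmetric-tube smoke
study, whose four training shapes cannot span the five geometric
degrees of freedom).  The encoder is similarly scale-limited: trained
on tens of rasters its 16 features interpolate worse than the six
quintic coefficients themselves, a comparison that reverses at full
scale where the encoder sees on the order of a thousand shapes.  The
acceptance chain reports its own measured values at the sizes it ran.

## Degenerate inputs and tie-breaks

Zero-depth profiles are valid flat walls (constructible directly, not
sampled); throats within 10⁻⁶ D of a clamped end raise a degeneracy
error; rasters clip boundary-row indices so a flat wall fills the top
pixel row; max-pooling distributes gradients equally among ties; the
plateau learning-rate monitor uses validation loss when a validation
split exists, else training loss.
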