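# Methods

## The hemodynamic model

The forward model is the classic Balloon model in its four-ODE form. A
flow-inducing signal *s* integrates the neuronal input *u* with decay and
feedback autoregulation; inflow *f* follows *s*; venous volume *v* fills at
the inflow rate and drains through the stiffness nonlinearity *v*^{1/α};
deoxyhemoglobin content *q* balances delivery, governed by the oxygen
extraction fraction E(f, E₀) = 1 − (1 − E₀)^{1/f}, against washout. All
hemodynamic variables are normalized to their resting values, so
(s, f, v, q) = (0, 1, 1, 1) is an exact fixed point of the dynamics.
Extraction *falls* toward 0 as inflow grows and rises toward 1 as inflow
vanishes — the imbalance between flow and extraction is what creates the
BOLD effect.

The observation is the static nonlinear map
y = V₀·(k₁(1 − q) + k₂(1 − q/v) + k₃(1 − v)) with the 1.5 T calibration
k₁ = 7E₀, k₂ = 2, k₃ = 2E₀ − 0.2 (the coefficients are configurable for
other field strengths). y is exactly linear in V₀ and zero at rest, which is
the root of the identifiability problem this package studies: a change in V₀
can always be absorbed by a compensating change in the neuronal efficacy ε,
to first order in the stimulus amplitude, so only the product ε·V₀ is
determined by the data. V₀ is therefore always supplied externally —
assumed, or calibrated from angiography — and never estimated.

### Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| ε | neuronal efficacy | 1/s per unit input | 0.54 |
| τₛ | signal decay time constant | s | 1.54 |
| τ_f | autoregulation time constant | s | 2.46 |
| τ₀ | mean venous transit time | s | 0.98 |
| E₀ | resting O₂ extraction fraction | — | 0.34 |
| α | vessel stiffness exponent | — | 0.2 (fixed, never estimated) |
| V₀ | resting blood volume fraction | — | 0.02 tissue / 0.1 vein-dominated |

The defaults are standard literature values for hemodynamic modeling and are
used here only as synthetic ground truth. α is held fixed because its
influence on the output is marginal compared with its cost in conditioning.

### Numerics

Integration is fixed-step classical RK4 (default internal step 0.01 s for
simulation, 0.1 s inside the filter), with the boxcar input sampled
piecewise-constant per substep; block edges fall on step boundaries for the
default designs, preserving the nominal fourth-order accuracy (observed
agreement between dt = 0.01 and dt = 0.001 is ~4e-11 max-abs over a 220 s
run). f, v, q are floored at 1e-6 during propagation — this matters only for
degenerate sigma points, and the number of floored components is reported per
run. The extraction term uses an analytic branch at f = 1 (E = E₀ exactly);
the generic expression leaves an ~1e-16 residue there through float
cancellation, which would otherwise break the exactness of the resting fixed
point.

## V₀ calibration

Large veins are bright in time-of-flight angiography, so segmentation is a
plain intensity threshold (an explicit configuration value — no automatic
threshold selection), followed by an isolated-voxel rule: a supra-threshold
voxel with no supra-threshold neighbor is treated as noise and excluded.
Neighborhood is 26-connectivity in 3-D by default (6-connectivity available);
this is the sole de-noising step. The binary mask is then reduced onto the
functional grid by exact integer counting of vessel subvoxels per functional
voxel block, and the per-voxel V₀ is the two-component mixture
V₀ = λ·v_blood + (1 − λ)·v_tissue with v_tissue = 0.02 (capillary-only
tissue) and v_blood = 1.0 (a vessel subvoxel is pure blood), both
configurable. Registration and reslicing are out of scope: the module
requires the high-resolution volume to be grid-aligned with exact integer
per-axis downsampling factors and raises otherwise. Indices are 0-based and
functional voxel (i, j, k) owns the half-open subvoxel block
[i·fx, (i+1)·fx) × ….

ROI time series are the unweighted mean over a center voxel and its in-slice
edge neighbors (corners excluded, at most 5 voxels), with the member list
returned for audit.

## Joint state/parameter estimation

Estimation is a scaled sigma-point (unscented) Kalman filter over an
augmented state: the hidden hemodynamic states plus log ε, log τₛ, log τ_f,
log τ₀ and logit E₀. The transforms guarantee that every sigma point decodes
to valid physiology. Parameters follow a random walk with small intensity
(default variance 1e-6 per observation step) so the filter can track them;
their initial uncertainty (default sd 0.5 for log ε, 0.25 for the log time
constants, 0.4 for logit E₀) does most of the adaptation work. The
measurement noise variance is a configuration value; in the synthetic studies
it is set to the generating noise variance.

Sigma scaling defaults to α_ukf = 1, β = 2, κ = 0. The conventional tiny
α_ukf (1e-3) gives a zeroth covariance weight of ≈ −1/α_ukf², and under the
strongly nonlinear v^{1/α} drainage term during large transients that
near-cancellation of huge weights destroys positive-definiteness; unit
scaling is stable for every study in this package and reproduces the
closed-form Kalman filter exactly on linear systems. The filter uses a plain
covariance parameterization with symmetrization after every update and a
jittered Cholesky (escalating from 1e-12) rather than a square-root
propagation; divergence (non-finite or exploding state) aborts with a
diagnostic. An unscented Rauch–Tung–Striebel smoothing pass is available and
off by default; parameter estimates are read from the final filtered mean,
which already conditions on the full series.

The two-region DCM run augments the state further with two neuronal states
z₁, z₂ (linear dynamics dz/dt = A z + C u; the neuronal state replaces the
extrinsic input in each region's *s* equation) and the two inter-region
couplings a₁₂, a₂₁ as Gaussian states initialized at 0 (prior sd 0.5). The
self-connectivities, input gains and the per-region V₀ are fixed; τₛ, τ_f,
τ₀ and E₀ are shared between regions while ε is per-region, which keeps the
augmented dimension at 18.

## Synthetic study conditions

The generators emulate a block-design visual experiment: TR = 2 s, 200
scans, 20 s on/off blocks (9 blocks), i.i.d. Gaussian measurement noise with
sd set from the requested SNR (peak noiseless amplitude / noise sd, default
10). The default single-region truth is a vein-dominated voxel (V₀ = 0.1);
the two-region truth pairs it with a tissue-only region (V₀ = 0.02), with
couplings a₁₂ = 0.4, a₂₁ = 0.6 s⁻¹, self-connectivities −1 s⁻¹ and input
gains 0.25/0.1.

Stimulus amplitude is 0.3 by default: with ε = 0.54 and sustained 20 s
blocks this yields peak inflow ≈ 1.46 and ≈ 10 % peak BOLD at V₀ = 0.1, the
regime of a strongly activated voxel. (A full-amplitude boxcar would drive
f ≈ 2.3 and a 21 % signal change — outside the physiological range, and
outside the range a V₀ = 0.02 observation model can produce at all.) The
small-signal scenario uses amplitude 0.05, where the first-order ε·V₀
trade-off holds to within a few percent; this is the regime in which product
identifiability is evaluated.

Recovery and noise-ladder studies initialize the filter prior at a
deliberately offset parameter set (ε 0.4, τₛ 1.25, τ_f 2.0, τ₀ 1.25, E₀
0.45). Initializing at the generating values would make recovery trivial —
in the high-noise limit the estimate simply stays at the prior, which is
already the truth — so the offset makes bias shrinkage with decreasing noise
a genuine property. The ladder uses SNR ∈ {2, 10, 50}.

Vessel phantoms rasterize straight cylinders (graded intensities 400–1000
over background 100) on a 32×32×16 subvoxel lattice (8×8×4 functional grid,
4³ subvoxels per voxel) and inject a configurable number of isolated
supra-threshold noise voxels placed at Chebyshev distance ≥ 2 from every
vessel and from each other, so the isolated-voxel rule provably removes
exactly the injected set. The generator's fraction table is computed by
exact integer counting and serves as a zero-error oracle for the calibration
pipeline.

What the generators do **not** emulate: MRI physics (k-space, partial-volume
blurring at acquisition, drift, physiological or temporally autocorrelated
noise), curved or branching vasculature, registration error between the
angiographic and functional grids, and trial-to-trial parameter variability.
Passing tests therefore demonstrate the internal consistency and the
V₀-sensitivity structure of the method under its own assumptions, not its
accuracy on scanner data.

## Problem sizes

All studies run at desk scale: 20 seeds per study, 200 scans per series,
8×8×4-voxel phantoms, three noise levels in the ladder. The full test suite
and the acceptance script each complete in well under a minute on one CPU.

## Known limitations

- The filter is a local Gaussian approximation; strongly misspecified runs
  (assumed V₀ far below truth at large signal amplitudes) show transient
  state overshoot before the efficacy estimate adapts, and data whose
  amplitude exceeds the observation model's attainable range cannot be fit
  at all.
- Only the final filtered parameter estimate is reported (no posterior over
  trajectories of parameters); the smoother smooths states, not the
  parameter random walk's history.
- The DCM is limited to two regions with linear (non-modulatory) coupling,
  and the swap symmetry of a fully symmetric two-region problem holds only
  up to the triangular structure of the sigma-point factorization.
- V₀ calibration trusts the segmentation threshold; there is no partial
  volume model at the vessel boundary (a subvoxel is either vessel or
  tissue).
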