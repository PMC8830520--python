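# Methods

## Model

An oblate spheroid with semi-axes a > b (aspect ratio e = a/b; the default
is the quiescent-platelet geometry a = 2 µm, b = 0.5 µm, e = 4) tumbles in
the flow–gradient plane of a steady laminar shear flow. With dimensionless
time γ̇t (physical time × shear rate), the classical Jeffery description is

    φ̇ = ½ (Λ cos 2φ + 1),    Λ = (e² − 1)/(e² + 1),

whose exact solution with φ(0) = 0 is tan φ = e tan(e γ̇t/(e² + 1)),
branch-continued so the angle is continuous and unbounded. (The widely
quoted closed form with 1/e inside the arctangent solves
½(1 − Λ cos 2φ), a π/2-phase-shifted convention; this package treats the
speed ODE as canonical because every downstream computation consumes
φ̇(φ), and implements the matching closed form.) The classical flip
period — the time for φ to advance by π — is π(e + 1/e), ≈ 13.3518 for
e = 4.

Real cells are neither rigid nor perfect oblates. The learned equation
adds three dimensionless corrections,

    φ̇ = ½ (Λ cos 2ψ + 1 + κ₀)(1 + λ₀ + λ₁ sin 2ψ),    ψ = φ − φ₀,

with κ₀ the fluid–object coupling constant, λ₀/λ₁ coarse- and
fine-grained shape deviations, and φ₀ a learnable phase rectifying a
constant measurement misalignment. At κ₀ = λ₀ = λ₁ = 0 it reduces exactly
to the classical equation; at κ₀ = λ₀ = 0 it contains the two-harmonic
inertial correction (+β₁ sin 2φ + β₂ sin 4φ) via β₁ = λ₁/2,
β₂ = λ₁Λ/4. In the expanded basis {1, cos 2ψ, sin 2ψ, sin 4ψ} the four
coefficients determine (κ₀, λ₀, λ₁) uniquely away from degeneracies, which
is what makes online parameter recovery well-posed.

## Synthetic ground truth

The generator emulates streaming output of a particle-based multiscale
simulation, which is what the learner would consume in production:

- clean dynamics: RK4 integration of the learned equation, optionally
  with linearly drifting parameters (drift held piecewise-constant per
  integration step);
- surface quiver (deformable bodies only): an additive sinusoid on the
  angle with period 0.2 dimensionless time — far below the flip period —
  and a per-series random phase, standing in for membrane quivering whose
  spectrum the underlying simulations do not constrain;
- measurement noise: i.i.d. Gaussian on the angle; the reported raw speed
  is the analytic speed at the noisy angle plus independent Gaussian noise
  of the same standard deviation, so the filtering/differentiation path in
  preprocessing is testable against an independent raw channel.

Default test scenarios use κ₀ = 0.5, λ₀ = −0.4, λ₁ = 0.1 (deformable) and
κ₀ = 0.5, λ₀ = −0.1, λ₁ = 0 (rigid) — plausible magnitudes for
shear-driven platelets, chosen once as generator fixtures, not as claims
about any particular cell. The sampling interval defaults to 0.005
dimensionless time so the moving-average stride maps to one sample.

What the generator does *not* emulate: particle-level deformation (the
rotation axis of a real deformable body wanders out of plane),
configuration-dependent noise correlations, and long-range secular changes
beyond linear parameter drift. Passing recovery tests therefore
demonstrates that the estimation machinery is correct and noise-robust at
the stated amplitudes, not that the equation captures every feature of
real cell trajectories.

## Preprocessing

Order: fold the raw angle modulo π into [−π/2, π/2) → branch-continue
(unwrap with period π) so linear filters never straddle the fold → moving
average (window 0.08, stride 0.005 dimensionless time, converted to sample
counts by half-up rounding; edge-truncated windows dropped; output stamps
at window centres) → wavelet denoising → refold → angular transform
φp = 1 − 2|φf|/π ∈ [0, 1], which removes the π-periodicity before
learning. Folding first makes the pipeline invariant under adding integer
multiples of π to the raw angle.

Wavelet denoising uses Daubechies-4 (a standard choice for smooth signals;
the family is configurable), symmetric extension, decomposition level
J = 4 or the maximum the series length allows, and soft thresholding of
every detail level with the single universal threshold
μ = η√(2 ln n), η = median(|D₁|)/0.6745 estimated from the finest-scale
details (n = series length). The training speed φ̇ is recomputed from the
denoised angle by central differences (exact for quadratics, second-order
convergent); a flag instead routes the raw speed channel through the same
MA + wavelet filters.

## Sampling policy

At training time τ the dataset is 40 short series of Ns = 10 consecutive
processed samples drawn from the trailing window [τ − W, τ] with W = 8
(about half a rotation period) and hot width w = W/8 = 1. Sampling is
stratified: series starts are uniform within each of the four regions
[τ−1, τ], [τ−2, τ−1], [τ−5, τ−2], [τ−8, τ−5] with fixed counts
{12, 10, 9, 9}, equivalent to a normalised staircase density
(heights 0.3, 0.25, 0.075, 0.075 per unit time). Series may cross region
boundaries but never extend past τ (no lookahead). Region membership is
decided by the start time. A series must end by τ, so hot-region starts
are capped at τ − (Ns−1)·Δt; the uniformity tests account for this end
guard. Training advances on the arithmetic grid τ₀ = W, τ_{k+1} = τ_k + Δl
with stride Δl = 0.25; streams whose processed grid starts after t = 0
(the moving average trims edges) skip training times whose window is not
yet fully covered.

## Online learning

The surrogate network is a fully connected feed-forward net with four
hidden layers of 20 tanh units, Xavier-initialised, mapping the encoding
(cos 2φ, sin 2φ) of the denoised folded angle to a speed. The encoding
respects the π-periodicity of the observable, matches the harmonics of the
learned equation, and avoids the branch discontinuity a direct φp input
would see at window edges. The network, its backpropagation and the Adam
optimiser are implemented in NumPy; the model is small enough that
full-batch matmuls on one CPU take well under a millisecond.

Each training process runs 200 (rigid) or 300 (deformable) full-batch
epochs of the joint loss L = L1(φ̇GT, φ̇ML) + L2(φ̇ML, φ̇TH), both MSE,
with split gradient routing: L1 updates only the network, L2 updates only
the equation parameters (κ₀, λ₀, λ₁, φ₀) with φ̇ML treated as a constant.
A joint-update mode (L2 also flowing into the network) sits behind a flag.
One epoch is one full pass over the 40-series batch as a single gradient
step. The learning rate is 0.002·0.95^k floored at 0.0005, with k the
training-process index. φ₀ is kept in (−π/2, π/2) through the
reparameterisation φ₀ = (π/2)·tanh(u) with u unconstrained. Equation
parameters start at κ₀ = λ₀ = λ₁ = 0 (the classical equation). A
non-finite loss aborts the process and restores the pre-process state.

L3(φ̇GT, φ̇TH) is evaluated per process on freshly arriving samples in
(τ, τ + Δl], never on the training window (falling back to the hot window
at the stream end). The termination signal ζ fires once at least 10
processes have run and the mean and standard deviation of their last 10
total losses are below 10⁻³ each (all configurable; the loop records ζ but
by default keeps consuming the stream, since here the stream is
pre-generated rather than an expensive live simulator that ζ would shut
down).

## Accuracy metrics

ε = 1 − Er/Rn with Er the *sum* over test points of |φ̇GT − φ̇TH|/φ̇GT and
Rn the test-interval width (the literal reading; a value-range reading of
Rn is available behind a flag). Because Er is a sum, ε depends on the
test-point density, so the test grid is fixed to the processed-stream
grid. Points with exactly zero ground-truth speed are excluded with a
warning. The theory-comparison metric is the trapezoidal time integral of
the squared speed difference divided by the spanned time (grid-resolution
independent); the comparison table reports it for the classical equation,
the inertial correction with betas derived from the learned λ₁, and the
learned equation, plus the improvement ratio (JOE − LJOE)/LJOE as a
percentage. The hyperparameter search averages ε over three
(training, test) interval setups — default [0,16]/[16,24], [0,32]/[32,40],
[0,44]/[44,50] — and returns the argmax point.

## Numerical choices and problem sizes

RK4 with fixed step 10⁻³ (trajectory oracles) or the sampling interval
(generation); flip periods by adaptive quadrature of 1/φ̇ with a strict
positivity guard on a dense grid (a non-positive speed means the body
stalls and is rejected). Analytic parameter gradients of the learned speed
are verified against central finite differences to 10⁻⁵ relative error.
Checkpoints are JSON with full-precision floats and round-trip bitwise.

Tests and the acceptance script run recovery experiments on streams of one
sampling window plus one flip period (duration ≈ 17–22 dimensionless time,
sample interval 0.005, ~2 × 10³ processed samples, 35–55 training
processes) — enough for the two-stage convergence pattern (a steep loss
drop within the first flip period, then fine tuning) while keeping a full
multi-seed suite under a minute on one CPU.

## Known limitations

- Strictly in-plane rotation; no 3D orbit dynamics or wobble of the
  rotation axis.
- The staircase masses are realised through stratified fixed counts, so
  the *number* of hot/cold series per batch never fluctuates; only start
  positions are random.
- Parameter drift is linear in time; regime switches are not modelled.
- The recovery guarantees quoted in the tests are for the synthetic noise
  model above; heavy-tailed or correlated measurement noise is untested.
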