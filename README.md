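# tumblefit

Online learning of corrected Jeffery-orbit equations for oblate cells
tumbling in shear flow.

A rigid oblate spheroid (aspect ratio e = a/b, shape constant
Λ = (e² − 1)/(e² + 1)) suspended in steady viscous shear tumbles with the
classical Jeffery angular speed φ̇ = ½(Λ cos 2φ + 1) in dimensionless time
γ̇t. Real cells — platelets, red and white blood cells — are deformable
and interact with the surrounding fluid, so the classical equation drifts
badly off their measured rotation. `tumblefit` implements a learned
three-parameter correction,

    φ̇ = ½ (Λ cos 2(φ−φ₀) + 1 + κ₀) (1 + λ₀ + λ₁ sin 2(φ−φ₀)),

and estimates (κ₀, λ₀, λ₁, φ₀) *online* from a noisy streaming rotation
trajectory, the way one would against a live, expensive particle-based
simulation: a small tanh surrogate network and the equation parameters are
trained jointly on batches drawn from a trailing window by a staircase
hot/cold sampling policy, under the two-term loss
L = L1(φ̇GT, φ̇ML) + L2(φ̇ML, φ̇TH) with split gradient routing
(L1 → network, L2 → equation). A termination signal fires when recent
losses are small and stable — the cue to switch the expensive simulator
off. At zero parameters the learned equation reduces exactly to Jeffery's;
at κ₀ = λ₀ = 0 it contains the classical two-harmonic inertial correction
(β₁ = λ₁/2, β₂ = λ₁Λ/4).

The package is aimed at researchers in cell biomechanics and
simulation-surrogate methods: it ships the dynamics (closed form,
integrator, flip periods), a synthetic streaming ground-truth generator
with deformable-body noise, the denoising/feature pipeline (moving
average, universal-threshold wavelet shrinkage, angular transform), the
sampling policy, the online learner (as a scikit-learn estimator), and
accuracy metrics with theory-comparison tables.

## Worked example

Recover the parameters of a deformable-body scenario
(κ₀, λ₀, λ₁) = (0.5, −0.4, 0.1) from a stream with 0.01-rad measurement
noise, training online over one sampling window plus one flip period:

```python
import numpy as np
from tumblefit import (BIOLRegressor, EquationParams, PLATELET,
                       generate_ground_truth, preprocess_series)
from tumblefit.dynamics import flip_period
from tumblefit.evaluate import compare_theories
from tumblefit.synthetic import default_deformable_scenario

params = EquationParams(kappa0=0.5, lambda0=-0.4, lambda1=0.1)
T = flip_period(params, PLATELET)
print("flip period:", round(T, 4))

scenario = default_deformable_scenario(duration=8.0 + T + 0.5,
                                       quiver_amplitude=0.0, seed=1)
series = generate_ground_truth(scenario)
processed = preprocess_series(series.samples)

est = BIOLRegressor(body_type="deformable", random_state=1)
est.fit(processed[["gamma_t", "phi_f", "phi_dot"]].to_numpy())
p = est.params_
print(f"learned: kappa0={p.kappa0:.3f} lambda0={p.lambda0:.3f} "
      f"lambda1={p.lambda1:.3f} phi0={p.phase_offset:.3f}")
print(compare_theories(series, p, PLATELET).round(4))
```

prints

```
flip period: 8.7423
learned: kappa0=0.425 lambda0=-0.347 lambda1=0.097 phi0=0.016
       normalized_l3  improvement_pct
JOE           0.0163              NaN
M-JOE         0.0140              NaN
L-JOE         0.0004        4306.4228
```

The flip period is the time for the angle to advance by π (8.74 here —
the corrections speed the tumble up relative to the classical 13.35 for
e = 4). Each learned parameter lands within 0.08 of its true value
despite the noise, and the learned equation's time-averaged squared speed
error (`normalized_l3`) is ~40× below the fixed classical equation's,
with the inertial two-harmonic correction in between — the expected
ordering when the data contain physics beyond both.

The same pipeline is scriptable from a shell:

```bash
tumblefit simulate   --config cfg.yml --seed 1 --out raw.csv
tumblefit preprocess --series raw.csv --seed 1 --out proc.csv
tumblefit learn      --config cfg.yml --stream proc.csv --seed 1 --out traj.csv
tumblefit evaluate   --series raw.csv --trajectory traj.csv --seed 1 --out table.csv
tumblefit search     --config cfg.yml --stream proc.csv --seed 1 --out grid.csv
```

Series files are plain CSV with `# key=value` metadata headers; configs
are YAML mirroring every default (sampling policy, filters, network,
optimiser, termination, metrics). See `docs/methods.md` for the model,
the noise model, and every numerical choice.

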