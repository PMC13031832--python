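# mmscalib

Rapid Bayesian calibration of cardiac tissue models: a static ensemble
Kalman filter whose measurement operator is an uncertain Gaussian process
emulator, applied to the modified Mitchell–Schaeffer (mMS) monodomain
model under S1S2 pacing.

## Who this is for

Personalised models of atrial electrophysiology need tissue parameters
estimated from the sparse, noisy measurements available during a clinical
mapping procedure — a handful of local activation times (LATs) and, at
extra cost, action potential durations (APDs). Markov chain Monte Carlo
on an emulated likelihood gives the right posterior but is serial and
slow; the point of this package is a calibration that runs in seconds
once the emulators are trained offline, so parameter estimates (with
uncertainty) could in principle be produced inside a procedure. The same
machinery applies to any static inverse problem `y = h(θ) + ε` where `h`
is only available as a trained emulator.

## The method

The posterior `π(θ|y) ∝ π(y|θ) π(θ)` is approximated by evolving N
parameter particles drawn from a uniform prior box for K iterations.
Each iteration: particles take a small random-walk step
(`θ̃ = θ + σ_θ ξ`); the GP emulators supply mean `m̄(θ̃)` and variance
`k̄(θ̃, θ̃)`; each particle assimilates its own re-perturbed datum
`yⁿ = y + ηⁿ, ηⁿ ~ N(0, K·R)` (iteration-scaled noise, so K assimilations
count the datum once); and the Kalman update

    θ ← θ̃ + G (yⁿ − m̄(θ̃)),   G = C_θm (C_mm + V̄ + K·R)⁻¹

corrects every particle, with the ensemble-averaged emulator variance V̄
sitting in the innovation covariance alongside the observation noise.
With `σ_θ = 0`, exact `h` and zero emulator variance this is the textbook
static ensemble Kalman filter; the final ensemble approximates the best
Gaussian fit to the posterior, with covariance inflated by at most
`σ_θ σ_θᵀ K`.

Around the calibrator the package provides the full desk-scale pipeline:
an S1S2-paced mMS monodomain solver (0D cell, 1D cable, 2D sheet; numba
time loop), LAT/APD extraction, maximin Latin hypercube designs with
cell- and tissue-level feasibility rejection, per-output GP emulators with
held-out validation, an adaptive Metropolis benchmark on the same emulated
posterior, and identifiability / field-RMSE / reentry-probability studies.
See `docs/methods.md` for the model, the numerical choices and their
rationale.

## Worked example

```python
import numpy as np
from mmscalib.design import build_training_ensemble
from mmscalib.emulator import fit_emulators
from mmscalib.enkf import EnkfConfig, calibrate
from mmscalib.observables import add_noise

ensemble = build_training_ensemble(target_m=202, seed=11)
print(ensemble.stage_log)
emulators, report = fit_emulators(ensemble, test_fraction=0.2, seed=3)
print(f"min held-out R^2 over {len(report)} outputs: {report.r2.min():.4f}")

truth_row = 17                       # a stored ensemble member as ground truth
noisy = add_noise(ensemble.observation(truth_row), seed=7)
result = calibrate(noisy, emulators, EnkfConfig(n_particles=300, n_steps=30, seed=1))
print("truth     :", np.round(ensemble.params[truth_row], 3))
print("posterior :", np.round(result.posterior_mean, 3))
print("sd        :", np.round(result.posterior_sd, 3))
print("converged at iteration", result.convergence_iteration)
```

Output from this exact script:

```
{'design': 505, 'cell_pass': 494, 'tissue_simulated': 205, 'final': 202}
min held-out R^2 over 45 outputs: 0.9751
truth     : [  0.336   4.531 155.832 181.168   0.241]
posterior : [  0.298   6.579 155.953 136.103   0.213]
sd        : [ 0.038  1.285  8.023 20.492  0.029]
converged at iteration 6
```

Reading it: 505 design points were filtered to 202 feasible S1S2
simulations; all 45 GP outputs clear 95% held-out variance explained; the
calibrated posterior recovers the excitability `τ_in` and diffusivity `D`
(they control the LATs) within about one posterior sd, while the recovery
constants come back with much wider posteriors — `τ_close` here sits two
sds from its truth — exactly the practical-identifiability pattern the
study code quantifies. The ensemble mean settles at iteration 6, well
inside the 30-step budget.

A CLI mirrors the pipeline for shell use:

```bash
mmscalib design --target-m 202 --seed 11 --out ensemble.h5
mmscalib emulate --ensemble ensemble.h5 --test-frac 0.2 --seed 3 --out gpe.h5
mmscalib simulate --out run.h5
mmscalib observe --run run.h5 --noise-sd 1.0 --seed 7 --out y.csv
mmscalib calibrate --gpe gpe.h5 --obs y.csv --n 300 --k 30 --seed 5 --out post.h5
mmscalib study identifiability --ensemble ensemble.h5 --gpe gpe.h5 --n-truths 10
```

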