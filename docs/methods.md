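# Methods

## Problem

Given a sparse, noisy vector of pacing measurements
`y = h(θ) + ε, ε ~ N(0, R)`, infer the posterior distribution of the five
homogeneous tissue parameters `θ = (τ_in, τ_out, τ_open, τ_close, D)` of a
modified Mitchell–Schaeffer (mMS) monodomain model. The forward map `h` is
expensive in general, so all inference runs against a precomputed ensemble
`E = {θ_m, h(θ_m)}` through Gaussian process emulators (GPEs), and the
posterior is approximated in near real time with a modified ensemble Kalman
update whose gain accounts for the emulator's own uncertainty.

## Forward model

The monodomain mMS system couples a normalised voltage `v ∈ [0, 1]` and a
recovery gate `h ∈ [0, 1]`:

    ∂v/∂t = ∇·(D ∇v) + h v (v − v_gate)(1 − v)/τ_in − (1 − h) v/τ_out + F_stim
    ∂h/∂t = (1 − h)/τ_open   if v ≤ v_gate,   −h/τ_close  otherwise

with no-flux boundaries, resting initial conditions and `v_gate = 0.1`
fixed. Geometry is desk-scale by design: the default domain is a 20 mm
cable at `dx = 0.2 mm` (101 nodes); a 50 × 50 mm sheet at `dx = 0.5 mm` is
used for reentry experiments. The inference machinery is
geometry-agnostic, so nothing downstream depends on this choice.

Numerics: operator splitting per time step — explicit Euler for the
reaction terms and stimulus, the gate advanced by the *exact* exponential
solution of its piecewise-linear ODE (branch chosen from the start-of-step
voltage), then an explicit finite-difference diffusion step with an
edge-replicated no-flux stencil (symmetric, hence conservative to
round-off). Default `dt = 0.05 ms` satisfies the explicit stability bound
`dt ≤ dx²/(2 d D)` with equality at the largest admissible diffusivity
(`D = 0.4 mm²/ms` in 1D); the solver refuses to run outside the bound. The
time loop is JIT-compiled (numba), so a full S1S2 cable run costs ~20 ms
and a 0D cell run ~1 ms, which is what makes hundreds of design
simulations and the 2D reentry indicator affordable.

Pacing follows the S1S2 restitution protocol: 3 S1 stimuli 800 ms apart
and one premature S2 at a 500 ms coupling interval, delivered as a
+1.0 ms⁻¹ forcing for 2 ms on the first five cable nodes (stimulus
amplitude and duration are not externally constrained; these values give
reliable capture across the prior box without dominating the upstroke).
Runs extend 600 ms past the S2 so its repolarisation completes.

## Measurements

Three output types at 15 sensor sites (45 outputs): LAT of the final S1
beat, LAT of the S2 beat, APD of the S2 beat. LAT is the first upward
crossing of 0.75 (linearly interpolated, a sample exactly on the threshold
counts), reported relative to the beat's own stimulus onset; LRT is the
first time after the beat's peak at which the voltage falls to 10% of the
peak; APD = LRT − LAT. Missing features (failed capture or recovery) are
*absent*, marking the observation infeasible rather than raising.

Default sensors are evenly spaced along the cable starting 2 mm downstream
of the electrode. The first iteration of the layout placed the first
sensor directly adjacent to the stimulated nodes; its LAT varied by
~0.2 ms across the entire prior box — stimulus artefact, not propagation —
making that output unlearnable for any regressor. Physical mapping
electrodes are not placed inside the pacing artefact either, so the
standoff is the physiologically sensible default.

Observation noise is independent zero-mean Gaussian, default sd 1.0 ms per
output (configurable per type; study code also uses 0.1 ms as the "precise
datum" condition). Traces are sampled at 0.25 ms, which keeps the
interpolation error of threshold crossings well below the noise floor.

## Design and feasibility

The training ensemble targets M ≈ 200 feasible runs (the pipeline default
is 202): a maximin Latin hypercube (best of 20 seeded candidates by
minimum pairwise distance) of 2.5 × M points over the prior box

| parameter | low | high | units |
|---|---|---|---|
| τ_in | 0.1 | 0.5 | ms |
| τ_out | 2 | 12 | ms |
| τ_open | 80 | 200 | ms |
| τ_close | 80 | 200 | ms |
| D | 0.05 | 0.4 | mm²/ms |

chosen to bracket standard mMS values and to span S2 APDs of roughly
60–500 ms on the cable, so the feasibility cuts are active. Stage 1
rejects cell-infeasible points using the cheap 0D model: every S1 beat
must capture, the S2 must capture at the 500 ms coupling, and no measured
beat APD may exceed 500 ms. (The APD cut is applied to the final S1 beat
as well as the S2 beat: under this protocol a genuinely long APD shows up
as a failed S1 recovery or an S2 block, and checking only the
restitution-shortened S2 APD would never fire.) A gradient-boosted
probabilistic classifier trained on labelled cell runs is available as a
faster stage-1 surrogate; direct rejection is the default at desk scale
where 1,000 cell runs cost ~1.5 s. Stage 2 simulates survivors on the
tissue grid and drops any run with an absent output. Acceptance on the
default box is high (~95–99%), dominated by S2 capture failures and
unrecovered long-APD beats.

## Emulation

One GP per output (independent outputs; no cross-output covariance),
anisotropic squared-exponential kernel with a white-noise nugget on inputs
standardised to the prior unit cube, hyperparameters by marginal
likelihood with multiple restarts (default 6: the steep near-refractory
S2 outputs occasionally trap a less-restarted optimiser in a poor local
optimum). Outputs are emulated on the **log scale**
(automatically, for outputs whose training values are all positive — LATs
and APDs always are) and z-scored there; predictive moments return to
physical units via the exact lognormal mean/variance. The log transform
is the single most consequential modelling choice: activation times
compose a launch latency with conduction effects multiplicatively, and the
steep near-refractory S2 response is far better behaved in log units
(minimum held-out R² over the 45 outputs rises from ≈ 0.95 to ≈ 0.98–0.99
at M ≈ 200). The nugget is bounded in [1e-13, 1e-2] on the z-scale: the
simulator is deterministic, but feature extraction leaves a small rough
component that the nugget absorbs, and letting marginal likelihood set it
keeps the nominal-95% predictive intervals honest (pooled held-out
coverage ≈ 0.87–0.89). Validation reports per-output held-out R² (an
80/20 split by default) and interval coverage.

## Calibration: ensemble Kalman update with an uncertain operator

N particles (default 300) are drawn from the uniform prior box and
updated for K iterations (default 30):

1. *predict* — pseudo-dynamics `θ̃ = θ + σ_θ ξ`, `ξ ~ N(0, I)`;
2. *emulate* — `μ = m̄(θ̃)`, `v = k̄(θ̃, θ̃)` (diagonal);
3. *perturb* — per-particle re-noised datum `yⁿ = y + ηⁿ`,
   `ηⁿ ~ N(0, K·R)`: assimilating the same datum K times with K-fold
   inflated noise counts it exactly once (in the linear-Gaussian case the
   split likelihood composes exactly; verified in the tests);
4. *gain* — `G = C_θm (C_mm + V̄ + K R)⁻¹` with sample (cross-)covariances
   over the ensemble (divisor N−1) and `V̄` the ensemble-averaged emulator
   variance, solved by Cholesky with minimal logged jitter on failure;
5. *update* — `θ = θ̃ + G (yⁿ − μ)`;
6. *boundary* — reflection at the box faces (clipping available).

Placing the averaged emulator variance additively in the innovation
covariance, and using the emulator mean (not per-particle draws) in the
innovation, is the package's reconstruction of the gain from first
principles; a `sample_emulator` flag enables the per-particle-draw variant
for comparison. With `σ_θ = 0`, an exact `h` and zero emulator variance
the scheme is the textbook static ensemble Kalman filter, and the tests
hold it to that reference step for step.

`σ_θ` defaults to 0.5% of each prior range per unit pseudo-time step, so
the cumulative posterior-variance inflation is bounded by
`σ_θ σ_θᵀ K ≈ 0.08%` of the prior variance at K = 30 — negligible, and the
bound itself is asserted in the tests. Convergence is declared at the
first iteration where the ensemble-mean drift stays below 1% of the prior
range componentwise for two consecutive iterations; the loop always runs
all K steps and the final ensemble is the posterior sample (interpreted as
the best Gaussian approximation of the posterior).

## MCMC benchmark

The gold standard samples the same emulated posterior: flat prior on the
box, Gaussian likelihood with covariance `R + diag k̄(θ, θ)` (so emulator
uncertainty widens the likelihood exactly as it widens the Kalman
innovation). The reference sampler is adaptive random-walk Metropolis:
chains advance in lock-step (batched density evaluations), the diagonal
proposal scale adapts toward ~30% acceptance during burn-in and is then
frozen, keeping the post-burn-in chain exactly Metropolis.
Post-processing drops burn-in, thins, concatenates and reports split-chain
R-hat (warning threshold 1.05). Reference settings — 10 chains × 40,000
samples, 10,000 burn-in, thinning 10 — retain 30,000 samples.

## Studies

*Identifiability*: ground truths are rows of the stored ensemble (so the
synthetic datum comes from the true simulator, keeping emulator bias
honest), noise is added, and calibration runs separately for S1-only,
S1+S2, and S1+S2+APD. Aggregates are per-parameter truth-vs-estimate
Pearson correlation and the contraction ratio median(posterior sd)/prior
sd. On the cable, τ_in and D are identifiable from any combination
(LAT intercept and slope separate launch latency from conduction); τ_out,
τ_open, τ_close stay at the prior under S1-only data (contraction ≈ 0.96–
0.99) and contract to 0.2–0.3 with all three measurement types.

*Field RMSE*: true and calibrated parameters are re-simulated on the full
grid and S1 LAT / S2 LAT / APD are compared over **all** nodes, not just
sensors. The S2 LAT error collapses once S2 measurements enter the
calibration (median ≈ 1.4 → 0.4 ms on the desk model) and the APD error
falls monotonically across the three combinations (≈ 42 → 32 → 1.4 ms).

*Reentry probability*: the clinical target quantity
`P(sustained | y) = ∫ g(θ) π(θ|y) dθ` is a Monte-Carlo mean of a binary
simulation outcome over posterior samples, with binomial standard error.
The desk-scale indicator launches an S1 plane wave across the sheet and a
cross-field half-plane S2 into the repolarising tail; "sustained" means
activity persists in the final 200 ms of a 2,000 ms run *and* the sheet
centre re-activates at least 3 times after the S2. The S2 timing
(322 ms) was located once by bisection on the earliest-capture boundary at
the prior-box midpoint and is held fixed; short-APD/slow-conduction
parameter vectors (wavelength shorter than the sheet) sustain spirals,
long-APD or fast ones terminate. This sheet criterion is a stand-in for
anatomical reentry induction on an atrial geometry; quantitative sustain
rates are not expected to transfer.

## What the synthetic conditions do and do not show

The desk model preserves the structure of the inference problem — a
5-parameter excitable-tissue model, S1S2 features at 15 sites with
Gaussian noise, feasibility-filtered GP training, the identical
calibration algorithm — but not atrial geometry, fibre anisotropy,
spatial parameter heterogeneity, or clinical noise structure. Passing
tests therefore validate the *method* (emulator fidelity, posterior
correctness in tractable limits, identifiability orderings), not
patient-level predictive accuracy.

## Problem sizes

Defaults were chosen so the full pipeline is interactive on one CPU:
ensemble construction ≈ 5 s (505-point design, ~205 tissue runs), 45 GP
fits ≈ 50 s, one calibration (N = 300, K = 30) ≈ 1.5 s, one reentry
indicator evaluation ≈ 2 s. The identifiability/RMSE studies default to
10 truths × 3 combinations; 50 truths is a flag away.

## Known limitations

- The posterior is a Gaussian approximation; a bimodal posterior would
  collapse onto one mode depending on initialisation.
- Independent-output GPs ignore cross-output correlations; whitened
  residual structure is not modelled.
- The reflect boundary slightly biases posteriors whose mass abuts a box
  face.
- The near-electrode S2 LAT outputs carry genuine small-scale response
  roughness; their GPs carry a larger nugget (up to 0.1 sd on the z-scale)
  and interpolate only to that level.
- The reentry indicator is deterministic and protocol-specific; it probes
  one induction mechanism at one fixed S2 timing.
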