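# Methods

`barncast` forecasts environmental factors of a mechanically ventilated pig
barn — ammonia (NH₃), hydrogen sulfide (H₂S), temperature and humidity —
one 30-minute step ahead, from the joint history of twelve sensor channels.
It couples three components: a sensor-cleaning chain, a causal-convolution +
gated-recurrent forecaster, and a swarm optimizer that selects the
forecaster's architecture. A seeded synthetic barn generator stands in for
field data.

## Preprocessing chain

Order: **outlier repair → Savitzky–Golay smoothing → min–max normalization.**

* **3σ rule.** A point is abnormal when its residual about the per-channel
  global mean exceeds `sigma_multiplier` (default 3) population standard
  deviations (ddof = 0). Residuals are taken about the global mean: it is the
  simplest reference consistent with the normal-density framing of the rule,
  and it makes the mask invariant under channel-wise affine rescaling.
  Zero-variance channels produce no flags. Flagged points are repaired by
  linear interpolation between the nearest clean neighbours (boundary points
  fall back to the nearest clean value), preserving the time grid.
* **Savitzky–Golay.** Window 11 samples (5.5 h), polynomial order 3.
  Edge handling uses the edge-window polynomial evaluated at the edge
  positions (scipy's `interp` mode) rather than signal padding, so the
  filter's defining property — polynomials up to the fit order pass through
  unchanged, everywhere — holds exactly; padding schemes break it at the
  boundaries.
* **Min–max scaling** maps each channel to [0, 1]; the per-channel min/max
  are kept so predictions can be reported in physical units. Statistics are
  computed on the leading 80 % of the timeline only, to keep test-period
  extremes out of the scaler. A stuck sensor (max = min) maps to all zeros
  by convention instead of erroring.

## Forecaster

Input is a sliding window of `lookback` = 48 steps (24 h) × 12 channels; the
output is the target channel at the step immediately after the window. Each
of the twelve parameters is predicted in turn by its own single-output model,
with the target's own history among the inputs.

Architecture: two causal dilated convolution blocks (TCN) with F1 and F2
filters, kernel 3, dilations 1 and 2, each block
`relu(causal_conv(x) + b) + x·P` with a 1×1 residual projection `P`; then two
GRU layers (N1 units sequence-to-sequence, N2 units final-state) using the
classical gates — reset applied to the hidden state *before* the recurrent
matrix — and an affine scalar head. Causality is exact: the activation at
step *t* never sees inputs after *t* (verified by perturbation probes in the
tests).

The network is implemented directly in numpy with hand-derived
backpropagation (through time for the GRU) and Adam. Gradients are verified
against central finite differences. Numerical choices that matter:

* **Small-gain initialization.** Convolution kernels and GRU gate matrices
  start at one tenth of the Glorot scale, so the initial function is
  dominated by the linear residual/readout path (the same idea as near-zero
  residual-branch initialization in deep residual networks). Sensor dynamics
  are close to linear; starting near the linear regime roughly halves
  validation error on held-out data compared with plain Glorot at equal
  budgets.
* **Learning rate 0.001 (Adam), cosine-annealed to zero** over the epoch
  budget. Small-batch Adam at a constant rate leaves the final weights
  wherever the last noisy step landed; the anneal makes the delivered weights
  a settled minimizer rather than a random late iterate.
* **Batch size 8 for final training.** With a few hundred training windows,
  batch 32 yields only ~16 updates per epoch; batch 8 gives the fixed epoch
  budget enough optimizer steps to converge. Architecture-search proxy runs
  keep batch 32 — they only need to rank candidates.
* Training aborts with a diagnostic on a non-finite loss; during
  architecture search such candidates score worst-case fitness instead of
  aborting the search.

## Architecture search

The four searched hyperparameters (F1, F2, N1, N2) live in the
integer-relaxed boxes F1 ∈ [1, 32], F2 ∈ [16, 128], N1 ∈ [1, 32],
N2 ∈ [16, 128] (lower-layer sizes search the small box, upper-layer sizes
the large one). Fitness of a candidate position is the validation MSE after
a short proxy training run (rounded to integers first); results are cached
by rounded tuple, so repeated probes are free and "fitness unchanged" is
exact. The search runs the improved swarm optimizer below with population 3
for at most 50 rounds, stopping when the best fitness changes by less than
10⁻¹² for three consecutive rounds. The per-round log records
(round, F1, F2, N1, N2, best fitness).

## The swarm optimizer

The baseline dung beetle optimizer (DBO) updates four behavioural roles per
iteration — defaults follow the original 30-beetle reference split
6 : 6 : 7 : 11 (rollers : brood : small : thieves):

* *rollers*: `x ← x + α·k·x_prev + b·|x − x_worst|` with α = −1 with
  probability 0.1 (else +1), k = 0.1, b = 0.3; with probability 0.1 the
  beetle instead *dances*: `x ← x + tan θ·|x − x_prev|`, θ ~ U[0, π],
  unchanged at θ ∈ {0, π/2, π};
* *brood balls* move inside a spawning box around the current-iteration best
  X\*, whose half-width shrinks with the inertia weight R = 1 − t/T_max;
* *small beetles* forage in the analogous box around the global best;
* *thieves* jump to `X_best + S·g·(|x − X*| + |x − X_best|)`, g standard
  normal, S = 0.5.

All moves hard-clip to the search box; the incumbent is tracked greedily so
the best-so-far fitness is non-increasing. The local best X\* is the best
member of the current population (the update rule for it is a design choice;
this is the simplest consistent one).

The improved variant (OTDBO) changes three things:

1. **Latin hypercube initialization** — exactly one sample per equal
   sub-interval in every dimension (scipy's sampler), giving uniform coverage
   at small populations;
2. **Osprey-style exploration** replaces rolling/dancing:
   `x ← x + r∘(F − I·x)` with F a uniformly chosen strictly-better population
   member (global best if none), r ~ U(0,1)^D, I ∈ {1, 2}. The first-phase
   osprey update formula is adopted in its canonical form since rolling's
   replacement is specified only behaviourally;
3. **Adaptive t-perturbation with greedy acceptance** — once per iteration
   the incumbent is mutated per dimension by `X_b(1 + t(df))` with Student-t
   degrees of freedom equal to the iteration number (capped at 100, beyond
   which the distribution is numerically normal); the mutant is kept only if
   strictly better, ties keep the incumbent. Perturbation is applied every
   iteration (a config flag can restrict or extend it); heavy Cauchy-like
   tails early give global jumps, Gaussian-like tails late give local
   polish.

With population sizes below four the roles cannot all be staffed; roles are
assigned round-robin and rotated every iteration so all four strategies stay
exercised (this is what the population-3 architecture search uses).

Note a structural property of the published region equations: the
spawning/foraging boxes contract toward the *origin-scaled* incumbent
(`X*·(1±R)`), so benchmarks whose optimum sits at the origin (sphere,
Rastrigin) are solved to machine precision quickly. The ablation
(OTDBO ≤ DBO on 10-D Rastrigin medians) is therefore a non-inferiority
check rather than a strict separation on these benchmarks.

## Evaluation

Windows are split 8 : 2 chronologically (first ⌊0.8 n⌋ train); no shuffling,
so every test target lies strictly after all training information. Metrics
are MSE, MAE and R² = 1 − Σ(ŷ−y)²/Σ(ȳ−y)², reported on the denormalized
physical scale. Constant truth flags R² as undefined rather than returning
a number. The reference model is the persistence baseline: forecast = last
observed target value, which on 30-minute autocorrelated series is a strong
yardstick. The Pearson channel-correlation matrix flags zero-variance
channels as NaN rather than silently zero.

## Synthetic barn generator

Real deployments of this kind do not publish their sensor tables, so the
generator emulates the documented setting: a summer barn sampled every 30
minutes, two instrumented pens (temperature, humidity, CO₂, NH₃; H₂S in pen
a only) plus outdoor temperature, humidity and wind speed — 12 channels.
Construction, per channel: diurnal sinusoid (afternoon temperature peak,
night-time CO₂ peak) plus stationary AR(1) noise (coefficient 0.9,
emulating slow environment/sensor persistence). Couplings carry the signs
the barn physics dictates: NH₃ rises with CO₂ (strongest partner) and
indoor humidity, falls with indoor temperature; H₂S is analogous but weaker
and noisier; indoor temperature falls with wind-driven ventilation. Both
pens share the barn-level latents but carry independent sensor noise, whose
scale follows the deployed instruments' resolution/accuracy (e.g. 0.2 ppm
for NH₃, ±0.2 °C for temperature). Anomaly injection flips points with a
given probability by ±`magnitude`·σ of their channel and returns the truth
mask.

What the generator does **not** model: ventilation control feedback, animal
growth and occupancy changes, weather fronts, sensor drift and missing
samples. Passing tests therefore demonstrate correct mechanics and
recoverable structure under realistic noise — not field accuracy on any
particular barn.

The `learnable_toy` fixture (target = fixed linear readout of the window's
last step + optional Gaussian noise) has a known Bayes-optimal MSE equal to
the noise variance, giving the training tests an exact floor.

## Problem sizes in the shipped tests and acceptance script

Fourteen simulated days (672 rows → 624 windows of lookback 48), search
population 3 × 5 rounds with 5-epoch proxy fits, and a 50-epoch final fit;
optimizer benchmarks use 30 beetles × 100 iterations (sphere) and
× 200 iterations on 10-D Rastrigin over 20 seeds. These sizes exercise every
code path at desk scale; the defaults for real use are 50 search rounds and
200 final epochs.

## Known limitations

* One-step-ahead only; multi-step decoding is out of scope.
* The optimizer handles box constraints only, by hard clipping.
* Training is single-threaded numpy; wall-clock scales with F2·N2·lookback.
* The stall rule compares cached fitness values exactly; if the proxy
  fitness is made stochastic across probes (it is not, by construction),
  the stall rule would need a tolerance matched to that noise.
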