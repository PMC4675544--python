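# Methods

`locustmarch` simulates one-dimensional self-propelled-particle (SPP) models
of marching locust nymphs in a ring arena and reduces their collective
dynamics to a coarse-grained description of the directional order parameter.
This note records the models as implemented, the parameter choices that
matter, the numerical conventions, and what the synthetic protocols do and
do not establish.

## The alignment-model family (`spp_core`)

`N` particles live on a periodic segment of length `L` (density
`rho = N/L`). Particle `i` has position `x_i ∈ [0, L)` and a dimensionless
velocity `u_i`; it advances at `v·u_i` and interacts with the set
`A_i = {j : d(x_i, x_j) ≤ Δ}` of neighbours within the minimal-image ring
distance `Δ`. The propulsion nonlinearity

    G(u) = (u + sign(u)) / 2,  G(0) = 0

is odd and pushes any non-zero input toward ±1. The continuous dynamics

    dx_i = v u_i dt
    du_i = [G(⟨u⟩_i) − u_i] dt + σ dW_i

is integrated with Euler–Maruyama; `dt = 1` reduces the velocity update to
the discrete form `u_i(t+1) = G(⟨u⟩_i) + ξ_i`. Noise is either uniform
`U[−η/2, η/2]` or Gaussian; the two amplitudes are tied by `σ² = η²/12`, the
variance of the uniform law.

Model variants:

- **czirok** — full relaxation to `G` of the self-*inclusive* local average.
  An isolated particle then obeys `du = −(u ∓ 1)/2 dt + σ dW`: an
  Ornstein–Uhlenbeck process with mean ±1 and stationary variance `σ²`.
  These particles are genuinely self-propelled.
- **individual_choice** — at every step each particle independently keeps
  its velocity with probability `α` (internal noise) and otherwise applies
  the alignment update. Noise enters both branches; with that convention
  the persistence-weighted model below is exactly the deterministic
  (Bernoulli-averaged) version of this one, and `α = 0` reproduces the base
  model draw-for-draw.
- **buhl** — `u_i(t+1) = α u_i + (1−α) G(⟨u⟩_i⁻) + ξ_i` with the
  self-*excluded* average `⟨u⟩_i⁻` (zero for a lone particle). An isolated
  particle obeys `du = −u dt + σ dW`: zero mean, stationary variance
  `σ²/2` — not self-propelled. (The rate doubles relative to the
  self-inclusive limit, which is why the variance halves.)
- **bode** — the 1D three-zone model: per time step, `N` asynchronous
  sub-updates each pick a random focal individual and a random neighbour
  `k`; within the alignment radius `r2` the focal adopts `G(u_k)`, in the
  attraction annulus `(r2, Δ]` it heads toward `k` with speed growing
  linearly from 0 at `r2` to 1 at `Δ`:
  `u_i = G(sgn(x_k − x_i)·(d − r2)/(Δ − r2))`. The 1D geometry has no
  avoidance zone.

Reference parameters for comparative runs: `N = 100, η = 2, Δ = 1, v = 0.1`
with the density `rho` swept; discrete stepping (`dt = 1`) is used for these
runs (the continuous variant at `dt = 0.1` gives indistinguishable
switching rates per unit time at high density).

**Randomness protocol.** `run_simulation` derives four independent
substreams from the seed — initial conditions, Bernoulli/pick choices,
noise, stop/start events — so that models which consume different choice
variables still share identical noise streams. This is what makes the
`α = 0` equivalence an exact, bit-level property rather than a statistical
one. Initial conditions default to `x ~ U[0, L)`, `u ~ U[−1, 1]`, all
moving. The compiled (numba) block kernels are cross-checked against the
pure-numpy single-step functions draw-for-draw in the test suite.
Asynchronous updating and single-random-neighbour alignment are available
as flags and take the (slower) reference path.

## Pause-and-go (`pause_and_go`)

Marching locusts move intermittently; as few as ~10% of hoppers may be
walking at a given moment. Each agent is either walking (advancing at
`v·u_i`) or standing (ignored by walkers and excluded from all averages):

- a walker stops at rate `k_walk`;
- a stander starts at rate `k_stand(n_moving)`, a step function jumping
  from `k_stand0` to `k_stand1` once the number of *moving* neighbours
  within `Δ` reaches `n_c_moving` (inclusive threshold) — moving neighbours
  recruit standing ones;
- a starting particle aligns with probability
  `α(m) = clip(a0 + a1·|m|, 0, 1)`, `m` the moving-only local average
  (magnitude, so both rotation senses recruit equally); aligning applies
  the usual relaxation toward `G(m)`, otherwise the heading is kept; noise
  enters both branches.

Rates map to per-step probabilities through the exact exponential
`1 − exp(−k dt)`, making bout statistics robust to the step size. Within a
step all statistics are evaluated at time t; walkers displace during the
step and may stop at its end; starters draw their new heading immediately
but begin displacing on the next step.

**Default rates** (per unit time, `dt = 0.1`): `k_walk = 0.5`,
`k_stand0 = 0.02`, `k_stand1 = 1.5`, `n_c_moving = 3`, `a0 = 0.1`,
`a1 = 0.9`. Only the functional forms of these laws are dictated by the
model; the numbers are this package's choice, picked once so the model
reproduces the qualitative phenomenology it is meant to exhibit at the
reference geometry: an isolated animal walks ~4% of the time
(`k_stand0/(k_stand0 + k_walk)`), recruitment makes activity bistable
(a low-activity disordered state and a high-activity marching state), and
the coarse-grained drift at high density is tristable (see below). All are
config-exposed.

The moving-only order parameter `ϕ_moving` is reported as 0 with an
explicit undefined flag when no particle moves; downstream statistics skip
flagged samples.

A degenerate-limit caveat: alignment fires only on stand→walk transitions,
so there is no parameter limit in which the model reduces *exactly* to an
always-moving alignment model (with `k_walk = 0` nobody ever stops and
headings freeze). The reduction test is therefore distributional: in the
high-churn, always-align limit the stationary mean `|ϕ_moving|` matches
the continuous alignment model's mean `|ϕ|` within a loose tolerance.

## Escape and pursuit (`escape_pursuit`)

A 2D Langevin model motivated by cannibalistic interactions:
`du_i = (−γ u_i + F_i) dt + √(2D) dW_i` on a periodic square. Neighbours
within radius `R` are classified by the signs of `u_i·r̂` (front/behind)
and `u_ji·r̂` (approaching/receding). Only front-receding (pursuit,
strength `χ_p`) and back-approaching (escape, `χ_e`) neighbours
contribute; each class contributes its mean projected relative velocity
`(u_ji·r̂) r̂`. Heaviside gates are strict (`H(0) = 0`), so exactly
perpendicular, co-moving or coincident pairs contribute nothing —
measure-zero configurations should not inject force discontinuities.

The 1D ring variant exists as a structural diagnostic: the same gating
implies that particles with opposite-signed `u` exert exactly zero force
on one another (for a pursuit force `j` must recede ahead, for an escape
force `j` must approach from behind; both require `u_j > u_i` along the
focal's heading, impossible across the sign split). The population
therefore fractures into non-interacting clockwise and counter-clockwise
groups — this interaction alone cannot produce the directional switching
seen in ring arenas.

## Coarse-graining (`coarse_grain`)

The order parameter `ϕ(t) = (1/N) Σ u_i` (or its moving-only variant)
dwells near ±1 with rare switches when the swarm is ordered. Two
reductions are implemented:

**Two-state switching statistics.** Metastable sets `A± = {±ϕ > p}` with
cutoff `p = 0.7`. A switch is an entry into `A±` after most recently
residing in the opposite set; intermediate sub-threshold samples do not
reset the residence, so same-side re-entries are not counted. Waiting
times are gaps between consecutive opposite-state entries; the rate is
switches per unit observed time. Waiting times are fit by maximum
likelihood (`rate = 1/mean`) and tested against the exponential family
with the Lilliefors-corrected KS test (statsmodels), which accounts for
the estimated scale. The exponential law holds in the strongly metastable
regime (mean wait ≫ the deterministic traverse time between thresholds);
at moderate density the traverse time produces a short-wait deficit that a
powerful GOF correctly detects, so the exponentiality check is run in the
strongly metastable regime where the two-state Markov reduction applies.

**Effective diffusion.** `dϕ = F(ϕ) dt + √(2 D(ϕ)) dW`, estimated by hard
binning of increments on a uniform grid over [−1.2, 1.2] (default 51
bins): per bin, `F` is the mean increment over `dt_cg` and `D` the
variance (or, optionally, raw second moment) over `2 dt_cg`. The two `D`
variants agree as `dt_cg → 0` and diverge monotonically as it grows (the
drift contribution `(F dt_cg)²` enters the second moment). Bins with fewer
than `min_count` (default 100) increments are masked, never extrapolated.
The coarse step is a tunable; `L/v` (one lap) is the natural scale for
comparison with arena experiments, while fixed-point structure is resolved
at smaller `dt_cg`. Fixed points are sign changes of `F` between
consecutive valid bins (linear interpolation; + → − stable, − → + unstable);
bins with an exactly-zero estimate are bridged, invalid gaps are not.

`synth_sde` integrates arbitrary drift/diffusion specs (descriptor tuples
run compiled; callables run in Python) and is the independent oracle for
estimator tests: on Ornstein–Uhlenbeck and double-well paths the
estimators recover the generating functions within a few percent at the
problem sizes used (T = 1e5, dt = 0.01).

**Drift-profile sampling.** Long ordered runs rarely visit intermediate
ϕ, so profiles are estimated from ensembles of short runs
(`fd_profile`): initial order spread over [−1.05, 1.05], increments
pooled. For the alignment models 1500 runs of 12 steps resolve the
high-density bistable structure (stable ≈ ±1, unstable ≈ 0). For
pause-and-go the order dynamics couple to activity, and ϕ alone is not a
Markov coordinate: states with the same ϕ but different walker fractions
have different drifts. `png_fd_profile` therefore initialises runs in and
around the two *natural* metastable states — the low-activity disordered
state (random-heading pool, ~8% walking) and high-activity ordered states
(ordered pool, order spread over ±[0.5, 1.1]) — and lets each branch's own
fluctuations populate the ϕ axis. At the reference geometry this yields a
robustly tristable drift: stable zeros near 0 and ±0.95 with unstable
zeros near ±0.8. Mixing branches arbitrarily (e.g. all-moving starts at
every ϕ) dilutes the disordered branch's restoring force and makes the
mid-drift sign sampling-dependent; the branch-faithful protocol avoids
that.

## Experiments and I/O

`scan_density` (rho swept at fixed N), `scan_N` (fixed L or fixed rho) and
`compare_models` (identical seeds and geometry across models) return tidy
per-replicate tables (model, param, value, seed, mean_order, rate,
n_switches, n_steps); `summarize` aggregates to mean ± s.e.m. Default scan
horizons are 2×10⁵ steps per replicate. Every CLI run writes a JSON
sidecar (model, full parameters, seed, version) from which the run can be
reproduced bit-exactly; trajectories and order series are plain CSV with
12 significant digits.

## Known behaviours and limitations

- **Low-density coarsening.** At `rho = 0.1`, `N = 100` the finite ring
  slowly coarsens into locally aligned clusters, so the time-averaged
  `|ϕ|` sits near 0.4–0.6 over desk-scale horizons rather than at the
  `O(N^{-1/2})` level of true disorder; the contrast with the ordered
  phase (≈ 0.99 at `rho = 3.2`) remains large. Statements about the
  disordered phase at this size are statements about these horizons.
- **Switching-rate ratio.** At `α = 0.66` the individual-choice model
  switches ≈ 30× faster than the base model at `rho = 3.2` (measured over
  8 seeds × 2×10⁵ steps), not ≈ 10×; the ratio is a steep function of the
  (here noisy-persistence) retain branch and of `α`, for which no value is
  canonical in the comparative-figure setting. The acceptance script
  reports the measured ratio.
- **Pause-and-go rates are illustrative.** The defaults realise the
  qualitative regime (intermittency, recruitment, tristability); they are
  not fits to arena data.
- The synthetic protocols exercise the models' internal consistency and
  the estimators' correctness; they do not validate any model against
  real locust trajectories.
- 2D escape-and-pursuit phase diagrams, continuous (PDE) swarm models and
  evolutionary variants are out of scope.
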