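# locustmarch

Simulation and coarse-grained analysis of one-dimensional self-propelled
particle (SPP) models of marching locust nymphs.

Marching bands of locust hoppers in a ring-shaped arena synchronise into
clockwise or counter-clockwise motion and occasionally switch direction —
rare, collective events whose statistics discriminate between competing
models of the underlying animal–animal interactions. This package is for
researchers in collective animal behaviour and active matter who want to
run those models under a common interface and compare them quantitatively:
it implements a family of 1D ring-geometry alignment models (continuous
and discrete relaxation, individual-choice, persistence-weighted,
three-zone), an intermittent pause-and-go model with movement-gated
alignment, an escape-and-pursuit social-force model, and the machinery to
reduce any of them to low-dimensional descriptions of the order parameter.

## The models in brief

`N` particles with positions `x_i` on a ring of length `L` and
dimensionless velocities `u_i` follow

    dx_i = v u_i dt,
    du_i = [G(⟨u⟩_i) − u_i] dt + σ dW_i,

where `⟨u⟩_i` is the mean velocity of neighbours within distance `Δ` and
`G(u) = (u + sign(u))/2` propels any non-zero consensus toward ±1
(`dt = 1` gives the discrete update `u_i(t+1) = G(⟨u⟩_i) + ξ_i`;
`σ² = η²/12` for uniform noise of width `η`). Variants weigh the
individual against the crowd differently — a Bernoulli retain-vs-align
choice with probability `α`, the deterministic persistence form
`u(t+1) = αu + (1−α)G(⟨u⟩_i⁻) + ξ` with the self-excluded average, a
three-zone alignment/attraction rule, a two-state walk/stand model whose
standing animals are invisible to the moving crowd, and an
escape-and-pursuit force gated on front-receding and back-approaching
neighbours.

Analysis reduces the swarm to the order parameter `ϕ(t) = (1/N) Σ u_i`:

- metastable states `A± = {±ϕ > p}` (`p = 0.7`), switching counts/rates
  and waiting-time statistics with an exponential (maximum-likelihood +
  Lilliefors) fit;
- an effective diffusion `dϕ = F(ϕ)dt + √(2D(ϕ))dW` with binned
  conditional-increment estimators
  `F(ϕ) = ⟨Δϕ⟩_ϕ/Δt`, `D(ϕ) = Var[Δϕ]_ϕ/(2Δt)`, and classification of the
  stable/unstable zeros of `F` that mark the metastable states.

See `docs/methods.md` for the full model definitions, parameter defaults
and numerical conventions.

## Worked example

```python
import locustmarch as lm

params = lm.reference_params(rho=3.2)          # N=100, eta=2, Delta=1, v=0.1
traj = lm.run_simulation("czirok", params, 200_000, seed=1)
series = lm.order_parameter(traj)
print(f"mean order  <|phi|> = {lm.mean_order(series):.3f}")

stats = lm.transitions(series, p=0.7)
print(f"switches: {stats.n_switches}  rate: {stats.rate:.2e} per step")

est = lm.fd_profile("czirok", params, seed=10, n_runs=1500, run_steps=12,
                    n_bins=25, min_count=100)
for fp in lm.classify_fixed_points(est):
    print(f"fixed point at phi = {fp.location:+.2f} ({fp.stability})")
```

prints

```
mean order  <|phi|> = 0.994
switches: 5  rate: 2.50e-05 per step
fixed point at phi = -1.00 (stable)
fixed point at phi = -0.01 (unstable)
fixed point at phi = +1.00 (stable)
```

At this density the swarm is almost perfectly ordered (`⟨|ϕ|⟩ ≈ 0.99`),
direction switches are rare (5 in 2×10⁵ steps), and the estimated drift
has the bistable signature of the ordered phase: stable fixed points at
ϕ ≈ ±1 with an unstable point at ϕ ≈ 0. The same calls with
`model="pause_and_go"` and `lm.png_fd_profile` expose the qualitatively
different tristable structure of the intermittent-motion model, where the
disordered state is itself metastable.

The same functionality is scriptable from the shell:

```
locustmarch simulate --model individual_choice --rho 3.2 --alpha 0.66 \
    --steps 200000 --seed 1 --out run1
locustmarch coarsegrain --series run1_series.csv --p 0.7 --out run1
```

Every run writes a JSON sidecar with the model id, full parameter set and
seed, from which it can be reproduced bit-exactly.

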