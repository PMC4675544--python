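"""Intermittent pause-and-go motion with movement-gated alignment.

Marching locusts do not walk continuously: individuals alternate walking
bouts and stops, and the fraction moving at any instant can be small.  Here
each particle is either walking (advancing at ``v * u_i``) or standing
(``v = 0``).  Standing particles "do not participate in the game": they are
excluded from local averages and from the moving-only order parameter

    phi_moving(t) = (1 / N_moving) * sum over moving i of u_i.

Transitions are rate-driven:

* a walker stops with rate ``k_walk``;
* a stander starts with rate ``k_stand(n_moving)``, a step function that
  jumps from ``k_stand0`` to ``k_stand1`` once the number of *moving*
  neighbours within ``delta`` reaches ``n_c_moving`` — local movement
  recruits standing animals;
* a starting particle aligns with the moving crowd with probability
  ``alpha(m) = clip(a0 + a1 |m|, 0, 1)`` where ``m`` is the moving-only
  local average — animals align more readily with ordered crowds;
  otherwise it keeps its heading.  Noise enters in both branches.

Rates are mapped to per-step probabilities via the exact exponential
``1 - exp(-k dt)`` so bout statistics are robust to the step size.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .spp_core import ModelParams, SwarmState, _draw_noise, g_function, \
    ring_distance


@dataclasses.dataclass(frozen=True)
class PnGParams(ModelParams):
    """Pause-and-go parameters on top of the shared geometry/noise record.

    All rates are per unit time.  Defaults place the model in the regime
    where both the onset of order and the tristable drift structure are
    observable at the reference geometry (N = 100, delta = 1, v = 0.1).
    """

    k_walk: float = 0.5
    k_stand0: float = 0.02
    k_stand1: float = 1.5
    n_c_moving: int = 3
    a0: float = 0.1
    a1: float = 0.9
    dt: float = 0.1

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.k_walk < 0:
            raise ValueError("k_walk must be >= 0")
        if not 0 <= self.k_stand0 <= self.k_stand1:
            raise ValueError("need 0 <= k_stand0 <= k_stand1")
        if self.n_c_moving < 1:
            raise ValueError("n_c_moving must be >= 1")
        if self.a1 < 0:
            raise ValueError("a1 must be >= 0 (alignment increases with order)")


def stand_rate(n_moving: int, params: PnGParams) -> float:
    """Start rate of a stander with ``n_moving`` moving neighbours.

    The threshold is inclusive: ``n_moving >= n_c_moving`` selects the high
    rate.  Non-decreasing in ``n_moving``.
    """
    if n_moving < 0:
        raise ValueError("n_moving must be >= 0")
    return params.k_stand1 if n_moving >= params.n_c_moving else params.k_stand0


def alignment_probability(local_order: float, params: PnGParams) -> float:
    """Probability that a starting particle aligns, given the local order.

    Linear and increasing in ``|local_order|``, clipped to [0, 1]; the
    magnitude is used so clockwise and counter-clockwise order recruit
    equally.
    """
    if abs(local_order) > 1.0 + 1e-9:
        raise ValueError("local_order must lie in [-1, 1]")
    return float(np.clip(params.a0 + params.a1 * abs(local_order), 0.0, 1.0))


def phi_moving(state: SwarmState) -> float:
    """Order parameter over moving particles; 0 when none are moving.

    The zero returned for an empty moving set is a convention, not a
    measurement — check ``state.n_moving`` (downstream series carry an
    undefined mask for such samples).
    """
    if not state.moving.any():
        return 0.0
    return float(state.u[state.moving].mean())


def step_png(state: SwarmState, params: PnGParams,
             rng: np.random.Generator) -> SwarmState:
    """One synchronous pause-and-go step.

    All neighbour statistics and event probabilities are evaluated on the
    state at time t.  Walkers displace during the step and may stop at its
    end; standers may start (drawing their new heading now) and begin
    displacing on the next step.  Per step, the stop/start event uniforms
    are drawn first, then the align-vs-retain uniforms, then the noise,
    each in particle order.
    """
    N = state.N
    ev = rng.random(N)
    ch = rng.random(N)
    xi = _draw_noise(rng, params, N)

    d = np.abs(state.x[:, None] - state.x[None, :])
    d = np.minimum(d, params.L - d)
    nbr = (d <= params.delta) & state.moving[None, :]
    np.fill_diagonal(nbr, False)
    counts = nbr.sum(axis=1)
    means = np.where(counts > 0, (nbr @ state.u) / np.maximum(counts, 1), 0.0)

    dt = params.dt
    sq = math.sqrt(dt)
    p_stop = 1.0 - math.exp(-params.k_walk * dt)
    p_start = 1.0 - np.exp(-np.where(counts >= params.n_c_moving,
                                     params.k_stand1, params.k_stand0) * dt)

    u_new = state.u.copy()
    moving_new = state.moving.copy()

    walkers = state.moving
    moving_new[walkers] = ev[walkers] >= p_stop

    standers = ~walkers
    starts = standers & (ev < p_start)
    moving_new[starts] = True
    align_p = np.clip(params.a0 + params.a1 * np.abs(means), 0.0, 1.0)
    aligns = starts & (ch < align_p)
    retains = starts & ~aligns
    u_new[aligns] = state.u[aligns] \
        + (g_function(means[aligns]) - state.u[aligns]) * dt + sq * xi[aligns]
    u_new[retains] = state.u[retains] + sq * xi[retains]

    x_new = state.x.copy()
    x_new[walkers] = (state.x[walkers]
                      + params.v * state.u[walkers] * dt) % params.L
    return SwarmState(state.t + dt, x_new, u_new, moving_new)


def moving_neighbor_count(state: SwarmState, i: int, delta: float,
                          L: float) -> int:
    """Number of moving neighbours of ``i`` within ``delta`` (self excluded)."""
    d = ring_distance(state.x[i], state.x, L)
    mask = (d <= delta) & state.moving
    mask[i] = False
    return int(mask.sum())
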