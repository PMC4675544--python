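"""Shared types, ring geometry and the 1D alignment-model family.

Marching locust nymphs in a ring-shaped arena are modelled as ``N``
self-propelled particles on a periodic segment of length ``L``.  Particle
``i`` carries a position ``x_i`` in ``[0, L)`` and a dimensionless velocity
``u_i``; it advances at speed ``v * u_i`` and relaxes its velocity towards a
propulsion function ``G`` of the local average direction within an
interaction range ``delta``, subject to noise.  The continuous dynamics

    dx_i = v u_i dt
    du_i = [G(<u>_i) - u_i] dt + sigma dW_i

is integrated with Euler-Maruyama; a step size ``dt = 1`` recovers the
classic discrete update ``u_i(t+1) = G(<u>_i) + xi_i``.  Model variants
implemented here differ in how the individual weighs its own heading against
the crowd:

``czirok``
    velocity fully relaxes to ``G`` of the self-inclusive local average.
``individual_choice``
    at every step a particle keeps its heading with probability ``alpha``
    and otherwise applies the alignment update (internal noise).
``buhl``
    deterministic persistence weighting
    ``u(t+1) = alpha u + (1 - alpha) G(<u>_i^-) + xi`` with the
    *self-excluded* local average.
``bode``
    the 1D three-zone model: asynchronous random pairwise updates with an
    alignment zone of radius ``r2`` and an attraction zone out to ``delta``.

Two single-particle limits anchor the family analytically: with the
self-inclusive average, an isolated particle obeys an Ornstein-Uhlenbeck
process with mean ``+-1`` and stationary variance ``sigma^2``; with the
self-excluded average it fluctuates around zero.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Optional

import numpy as np

from . import _kernels

_SQRT12 = math.sqrt(12.0)

UPDATE_MODES = ("synchronous", "asynchronous")
NEIGHBOR_MODES = ("local_mean", "single_random_neighbor")
NOISE_KINDS = ("uniform", "gaussian")

#: Reference parameter set used throughout the comparative runs:
#: N = 100, eta = 2, Delta = 1, v = 0.1 on a ring sized by the density rho.
REFERENCE_PARAMS = dict(N=100, eta=2.0, delta=1.0, v=0.1, dt=1.0)


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Parameters of a 1D alignment model.

    Exactly one of ``L`` (ring length) and ``rho`` (density N/L) must be
    given; the other is derived.  Exactly one of ``eta`` (width of the
    uniform noise ``U[-eta/2, eta/2]``) and ``sigma`` (noise standard
    deviation) must be given; they are tied by ``sigma^2 = eta^2 / 12``.
    """

    N: int
    L: Optional[float] = None
    rho: Optional[float] = None
    v: float = 0.1
    eta: Optional[float] = None
    sigma: Optional[float] = None
    delta: float = 1.0
    dt: float = 1.0
    alpha: float = 0.0
    update_mode: str = "synchronous"
    neighbor_mode: str = "local_mean"
    noise_kind: str = "uniform"
    include_self: bool = True

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if (self.L is None) == (self.rho is None):
            if self.L is None:
                raise ValueError("specify one of L or rho")
            if not math.isclose(self.rho * self.L, self.N, rel_tol=1e-9):
                raise ValueError("inconsistent L and rho: rho * L must equal N")
        elif self.L is None:
            object.__setattr__(self, "L", self.N / self.rho)
        else:
            object.__setattr__(self, "rho", self.N / self.L)
        if self.L <= 0:
            raise ValueError("L must be > 0")
        if (self.eta is None) and (self.sigma is None):
            raise ValueError("specify one of eta or sigma")
        if self.eta is None:
            object.__setattr__(self, "eta", self.sigma * _SQRT12)
        elif self.sigma is None:
            object.__setattr__(self, "sigma", self.eta / _SQRT12)
        elif not math.isclose(self.sigma, self.eta / _SQRT12, rel_tol=1e-9):
            raise ValueError("inconsistent eta and sigma: sigma^2 must equal eta^2/12")
        if self.sigma < 0:
            raise ValueError("noise amplitude must be >= 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.update_mode not in UPDATE_MODES:
            raise ValueError(f"update_mode must be one of {UPDATE_MODES}")
        if self.neighbor_mode not in NEIGHBOR_MODES:
            raise ValueError(f"neighbor_mode must be one of {NEIGHBOR_MODES}")
        if self.noise_kind not in NOISE_KINDS:
            raise ValueError(f"noise_kind must be one of {NOISE_KINDS}")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with ``changes`` applied.

        Replacing one member of a derived pair (``L``/``rho`` or
        ``eta``/``sigma``) re-derives the other.
        """
        d = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        if "L" in changes and "rho" not in changes:
            d["rho"] = None
        if "rho" in changes and "L" not in changes:
            d["L"] = None
        if "eta" in changes and "sigma" not in changes:
            d["sigma"] = None
        if "sigma" in changes and "eta" not in changes:
            d["eta"] = None
        d.update(changes)
        return type(self)(**d)


@dataclasses.dataclass(frozen=True)
class BodeParams(ModelParams):
    """Parameters of the 1D three-zone model.

    ``r2`` is the alignment-zone radius; pairs farther than ``r2`` but within
    ``delta`` interact through attraction.  The 1D model has no avoidance
    zone.
    """

    r2: float = 0.5

    def __post_init__(self) -> None:
        super().__post_init__()
        if not 0.0 < self.r2 < self.delta:
            raise ValueError("r2 must satisfy 0 < r2 < delta")


def reference_params(rho: float = 3.2, **overrides) -> ModelParams:
    """The comparative-run parameter set (N=100, eta=2, delta=1, v=0.1)."""
    kw = dict(REFERENCE_PARAMS)
    kw["rho"] = rho
    kw.update(overrides)
    return ModelParams(**kw)


@dataclasses.dataclass
class SwarmState:
    """Positions, dimensionless velocities and motion flags at one instant."""

    t: float
    x: np.ndarray
    u: np.ndarray
    moving: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.moving = np.asarray(self.moving, dtype=bool)
        if not (self.x.shape == self.u.shape == self.moving.shape):
            raise ValueError("x, u and moving must have equal length")

    @property
    def N(self) -> int:
        return self.x.size

    @property
    def n_moving(self) -> int:
        return int(self.moving.sum())

    @classmethod
    def random(cls, params: ModelParams, rng: np.random.Generator,
               all_moving: bool = True) -> "SwarmState":
        """Uniform initial conditions: x ~ U[0, L), u ~ U[-1, 1]."""
        x = rng.uniform(0.0, params.L, params.N)
        u = rng.uniform(-1.0, 1.0, params.N)
        moving = np.full(params.N, all_moving, dtype=bool)
        return cls(t=0.0, x=x, u=u, moving=moving)

    def validate(self, L: float) -> None:
        if np.any((self.x < 0) | (self.x >= L)):
            raise ValueError("positions must lie in [0, L)")

    def copy(self) -> "SwarmState":
        return SwarmState(self.t, self.x.copy(), self.u.copy(), self.moving.copy())


@dataclasses.dataclass
class Trajectory:
    """Result of a simulation run.

    ``phi`` holds the order parameter after every step (``phi[0]`` is the
    initial value), at the times in ``times``.  ``phi_moving``/``n_moving``
    are populated by the pause-and-go model.  Snapshots, if requested, are
    stored in ``states`` (each carries its own time stamp).
    """

    model: str
    params: ModelParams
    seed: int
    times: np.ndarray
    phi: np.ndarray
    phi_moving: Optional[np.ndarray] = None
    n_moving: Optional[np.ndarray] = None
    states: Optional[list] = None

    @property
    def final_state(self) -> Optional[SwarmState]:
        return self.states[-1] if self.states else None


# ---------------------------------------------------------------------------
# geometry and interaction primitives

def ring_distance(x1, x2, L: float):
    """Minimal-image distance between positions on a ring of length L."""
    if L <= 0:
        raise ValueError("L must be > 0")
    d = np.abs(np.asarray(x1) - np.asarray(x2))
    out = np.minimum(d, L - d)
    return float(out) if out.ndim == 0 else out


def signed_ring_displacement(x_from, x_to, L: float):
    """Minimal-image displacement from ``x_from`` to ``x_to``, in [-L/2, L/2)."""
    if L <= 0:
        raise ValueError("L must be > 0")
    d = (np.asarray(x_to) - np.asarray(x_from) + 0.5 * L) % L - 0.5 * L
    return float(d) if d.ndim == 0 else d


def g_function(u):
    """Odd propulsion nonlinearity: (u + sign(u)) / 2 for u != 0, else 0."""
    u = np.asarray(u, dtype=float)
    out = np.where(u == 0.0, 0.0, 0.5 * (u + np.sign(u)))
    return float(out) if out.ndim == 0 else out


def _neighbor_mask(x: np.ndarray, L: float, delta: float,
                   include_self: bool, moving: Optional[np.ndarray] = None
                   ) -> np.ndarray:
    """Boolean (N, N) matrix: mask[i, j] iff j is averaged for focal i."""
    d = np.abs(x[:, None] - x[None, :])
    d = np.minimum(d, L - d)
    mask = d <= delta
    if not include_self:
        np.fill_diagonal(mask, False)
    if moving is not None:
        mask &= moving[None, :]
    return mask


def local_mean_u(state: SwarmState, i: int, delta: float, L: float,
                 include_self: bool = True, moving_only: bool = False) -> float:
    """Average velocity over the neighbours of particle ``i`` within ``delta``.

    Returns 0 when the qualifying set is empty (the conventional value of
    the local average for an isolated particle).
    """
    if not 0 <= i < state.N:
        raise IndexError("particle index out of range")
    d = ring_distance(state.x[i], state.x, L)
    mask = d <= delta
    if not include_self:
        mask[i] = False
    if moving_only:
        mask &= state.moving
    if not mask.any():
        return 0.0
    return float(state.u[mask].mean())


def _local_means(state: SwarmState, params: ModelParams,
                 include_self: bool) -> np.ndarray:
    mask = _neighbor_mask(state.x, params.L, params.delta, include_self)
    counts = mask.sum(axis=1)
    sums = mask @ state.u
    return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)


def _draw_noise(rng: np.random.Generator, params: ModelParams, size) -> np.ndarray:
    if params.noise_kind == "uniform":
        return rng.uniform(-params.eta / 2.0, params.eta / 2.0, size)
    return rng.normal(0.0, params.sigma, size)


def _check_dt(params: ModelParams) -> None:
    # Euler guard: the deterministic relaxation u <- u + (G - u) dt is
    # contractive only for dt <= 2.
    if params.dt > 2.0:
        raise ValueError("dt > 2 is unstable for the velocity relaxation")


def _align_targets(state: SwarmState, params: ModelParams, include_self: bool,
                   rng: Optional[np.random.Generator]) -> np.ndarray:
    """Per-particle alignment input: local mean or a single random neighbour."""
    if params.neighbor_mode == "single_random_neighbor":
        if rng is None:
            raise ValueError("single_random_neighbor mode needs an rng")
        mask = _neighbor_mask(state.x, params.L, params.delta, include_self)
        picks = rng.random(state.N)
        m = np.zeros(state.N)
        for i in range(state.N):
            nbrs = np.nonzero(mask[i])[0]
            if nbrs.size:
                m[i] = state.u[nbrs[min(int(picks[i] * nbrs.size), nbrs.size - 1)]]
        return m
    return _local_means(state, params, include_self)


# ---------------------------------------------------------------------------
# single-step updates (reference implementations)

def _advance_positions(state: SwarmState, params: ModelParams,
                       u_new: np.ndarray) -> SwarmState:
    x_new = (state.x + params.v * state.u * params.dt) % params.L
    return SwarmState(state.t + params.dt, x_new, u_new, state.moving.copy())


def step_czirok(state: SwarmState, params: ModelParams,
                rng: np.random.Generator) -> SwarmState:
    """One step of the alignment model (Euler-Maruyama; dt=1 is discrete).

    Per step, any alignment-target picks are drawn before the noise
    variables, each in particle order.
    """
    _check_dt(params)
    if params.update_mode == "asynchronous":
        return _step_async(state, params, rng, retain_prob=None)
    m = _align_targets(state, params, params.include_self, rng)
    xi = _draw_noise(rng, params, state.N)
    u_new = state.u + (g_function(m) - state.u) * params.dt \
        + math.sqrt(params.dt) * xi
    return _advance_positions(state, params, u_new)


def step_individual_choice(state: SwarmState, params: ModelParams,
                           rng: np.random.Generator) -> SwarmState:
    """Retain heading with probability ``alpha``, else align as in the base
    model; noise is applied in both branches.

    Per step all Bernoulli retain draws come first, then any alignment-target
    picks, then the noise variables, each in particle order, so that
    ``alpha = 0`` reproduces :func:`step_czirok` draw-for-draw when the two
    models read noise from matched streams.
    """
    _check_dt(params)
    if params.update_mode == "asynchronous":
        return _step_async(state, params, rng, retain_prob=params.alpha)
    retain = rng.random(state.N) < params.alpha
    m = _align_targets(state, params, params.include_self, rng)
    xi = _draw_noise(rng, params, state.N)
    sq = math.sqrt(params.dt)
    aligned = state.u + (g_function(m) - state.u) * params.dt + sq * xi
    kept = state.u + sq * xi
    u_new = np.where(retain, kept, aligned)
    return _advance_positions(state, params, u_new)


def step_buhl(state: SwarmState, params: ModelParams,
              rng: np.random.Generator) -> SwarmState:
    """Persistence-weighted update with the self-excluded local average:
    ``u(t+1) = alpha u + (1 - alpha) G(<u>_i^-) + xi``."""
    m = _align_targets(state, params, include_self=False, rng=rng)
    xi = _draw_noise(rng, params, state.N)
    u_new = params.alpha * state.u + (1.0 - params.alpha) * g_function(m) + xi
    return _advance_positions(state, params, u_new)


def _step_async(state: SwarmState, params: ModelParams,
                rng: np.random.Generator,
                retain_prob: Optional[float]) -> SwarmState:
    """N sequential sub-updates of randomly chosen particles (with repeats)."""
    new = state.copy()
    sq = math.sqrt(params.dt)
    for _ in range(state.N):
        i = int(rng.integers(state.N))
        if retain_prob is not None and rng.random() < retain_prob:
            xi = _draw_noise(rng, params, 1)[0]
            new.u[i] = new.u[i] + sq * xi
        else:
            m = local_mean_u(new, i, params.delta, params.L,
                             include_self=params.include_self)
            if params.neighbor_mode == "single_random_neighbor":
                d = ring_distance(new.x[i], new.x, params.L)
                mask = d <= params.delta
                if not params.include_self:
                    mask[i] = False
                nbrs = np.nonzero(mask)[0]
                m = 0.0 if nbrs.size == 0 else float(
                    new.u[nbrs[int(rng.integers(nbrs.size))]])
            xi = _draw_noise(rng, params, 1)[0]
            new.u[i] = new.u[i] + (g_function(m) - new.u[i]) * params.dt + sq * xi
        new.x[i] = (new.x[i] + params.v * new.u[i] * params.dt) % params.L
    new.t = state.t + params.dt
    return new


def bode_target_u(u_k: float, signed_disp: float, params: BodeParams) -> float:
    """Velocity adopted by a focal particle referencing neighbour ``k``.

    Within the alignment zone (``|disp| <= r2``) the focal copies ``G(u_k)``;
    in the attraction zone it heads toward the neighbour with a speed that
    grows linearly from 0 at ``r2`` to 1 at ``delta``:
    ``G(sgn(disp) * (d - r2) / (delta - r2))``.
    """
    d = abs(signed_disp)
    if d <= params.r2:
        return float(g_function(u_k))
    w = (d - params.r2) / (params.delta - params.r2)
    return float(g_function(math.copysign(w, signed_disp) if signed_disp != 0 else 0.0))


def step_bode(state: SwarmState, params: BodeParams,
              rng: np.random.Generator) -> SwarmState:
    """One time step of the three-zone model: N asynchronous sub-updates.

    Each sub-update picks a uniform-random focal particle; if it has
    neighbours within ``delta`` it references a uniform-random one of them,
    then advances its position.  Particles without neighbours keep their
    velocity.
    """
    new = state.copy()
    for _ in range(state.N):
        i = int(rng.integers(state.N))
        d = ring_distance(new.x[i], new.x, params.L)
        nbrs = np.nonzero((d <= params.delta) & (np.arange(state.N) != i))[0]
        if nbrs.size:
            k = int(nbrs[int(rng.integers(nbrs.size))])
            disp = signed_ring_displacement(new.x[i], new.x[k], params.L)
            new.u[i] = bode_target_u(new.u[k], disp, params)
        new.x[i] = (new.x[i] + params.v * new.u[i] * params.dt) % params.L
    new.t = state.t + params.dt
    return new


# ---------------------------------------------------------------------------
# driver

_CHUNK = 8192

ALIGNMENT_MODELS = ("czirok", "individual_choice", "buhl")
MODELS = ALIGNMENT_MODELS + ("bode", "pause_and_go")

_KERNEL_MODE = {
    "czirok": _kernels.MODE_CZIROK,
    "buhl": _kernels.MODE_BUHL,
    "individual_choice": _kernels.MODE_INDIVIDUAL_CHOICE,
}


def run_simulation(model: str, params: ModelParams, n_steps: int,
                   sample_every: int = 1, seed: int = 0,
                   init: Optional[SwarmState | Callable] = None,
                   store_states: bool = False) -> Trajectory:
    """Run ``n_steps`` of the named model and record the order parameter.

    Deterministic for fixed ``(model, params, n_steps, seed)``.  Four
    independent substreams are derived from ``seed`` — initial conditions,
    per-step Bernoulli/pick choices, noise, and stop/start events — so that
    models consuming different choice variables still share identical noise
    streams (e.g. individual choice at ``alpha = 0`` versus the base model).

    ``phi`` is recorded after every step; snapshots are stored every
    ``sample_every`` steps when ``store_states`` is true.  ``init`` may be a
    :class:`SwarmState` or a callable ``(rng, params) -> SwarmState``.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if model == "bode" and not isinstance(params, BodeParams):
        raise TypeError("the bode model requires BodeParams")
    if model == "pause_and_go":
        from .pause_and_go import PnGParams
        if not isinstance(params, PnGParams):
            raise TypeError("the pause_and_go model requires PnGParams")
    if model in ("czirok", "individual_choice"):
        _check_dt(params)

    root = np.random.default_rng(seed)
    init_rng, choice_rng, noise_rng, event_rng = root.spawn(4)
    if init is None:
        state = SwarmState.random(params, init_rng)
    elif callable(init):
        state = init(init_rng, params)
    else:
        state = init.copy()
    state.validate(params.L)

    n_rec = n_steps + 1
    times = state.t + params.dt * np.arange(n_rec)
    phi = np.empty(n_rec)
    phi[0] = state.u.mean()
    is_png = model == "pause_and_go"
    phi_mov = np.empty(n_rec) if is_png else None
    n_mov = np.empty(n_rec, dtype=np.int64) if is_png else None
    if is_png:
        n_mov[0] = state.n_moving
        phi_mov[0] = state.u[state.moving].mean() if n_mov[0] else 0.0
    states = [state.copy()] if store_states else None

    fast = (params.update_mode == "synchronous"
            and params.neighbor_mode == "local_mean")
    chunk = sample_every if store_states else _CHUNK
    done = 0
    while done < n_steps:
        n = min(chunk, n_steps - done)
        lo, hi = done + 1, done + 1 + n
        if fast:
            _run_block(model, params, state, n, choice_rng, noise_rng,
                       event_rng, phi[lo:hi],
                       None if phi_mov is None else phi_mov[lo:hi],
                       None if n_mov is None else n_mov[lo:hi])
            state.t += n * params.dt
        else:
            for s in range(n):
                state = _python_step(model, state, params, choice_rng,
                                     noise_rng, event_rng)
                phi[lo + s] = state.u.mean()
                if is_png:
                    c = state.n_moving
                    n_mov[lo + s] = c
                    phi_mov[lo + s] = state.u[state.moving].mean() if c else 0.0
        done += n
        if store_states and done % sample_every == 0:
            snap = state.copy()
            snap.t = times[done]
            states.append(snap)
    return Trajectory(model=model, params=params, seed=seed, times=times,
                      phi=phi, phi_moving=phi_mov, n_moving=n_mov,
                      states=states)


def _run_block(model: str, params: ModelParams, state: SwarmState, n: int,
               choice_rng, noise_rng, event_rng,
               phi_out, phi_mov_out, n_mov_out) -> None:
    N = params.N
    if model in ALIGNMENT_MODELS:
        if model == "individual_choice":
            retain = choice_rng.random((n, N)) < params.alpha
        else:
            retain = np.zeros((1, 1), dtype=bool)
        xi = _draw_noise(noise_rng, params, (n, N))
        include_self = params.include_self and model != "buhl"
        _kernels._align_block(state.x, state.u, xi, retain,
                              _KERNEL_MODE[model], params.alpha, params.v,
                              params.dt, params.delta, params.L,
                              include_self, phi_out)
    elif model == "bode":
        pick_i = choice_rng.random((n, N))
        pick_k = choice_rng.random((n, N))
        _kernels._bode_block(state.x, state.u, pick_i, pick_k, params.v,
                             params.dt, params.delta, params.r2, params.L,
                             phi_out)
    else:  # pause_and_go
        ev = event_rng.random((n, N))
        ch = choice_rng.random((n, N))
        xi = _draw_noise(noise_rng, params, (n, N))
        p_stop = 1.0 - math.exp(-params.k_walk * params.dt)
        p0 = 1.0 - math.exp(-params.k_stand0 * params.dt)
        p1 = 1.0 - math.exp(-params.k_stand1 * params.dt)
        _kernels._png_block(state.x, state.u, state.moving, ev, ch, xi,
                            params.v, params.dt, params.delta, params.L,
                            p_stop, p0, p1, params.n_c_moving,
                            params.a0, params.a1,
                            phi_out, phi_mov_out, n_mov_out)


def _python_step(model: str, state: SwarmState, params: ModelParams,
                 choice_rng, noise_rng, event_rng) -> SwarmState:
    # Variant modes (asynchronous / single-random-neighbour) take this
    # slower path; the per-step functions own the draw protocol.
    if model == "czirok":
        rng = choice_rng if params.update_mode == "asynchronous" \
            or params.neighbor_mode == "single_random_neighbor" else noise_rng
        return step_czirok(state, params, rng)
    if model == "individual_choice":
        return step_individual_choice(state, params, choice_rng)
    if model == "buhl":
        return step_buhl(state, params, choice_rng)
    if model == "bode":
        return step_bode(state, params, choice_rng)
    from .pause_and_go import step_png
    return step_png(state, params, event_rng)
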