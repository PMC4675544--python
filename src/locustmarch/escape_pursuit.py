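"""Escape-and-pursuit social forces, motivated by cannibalistic interactions.

Each particle follows Langevin dynamics

    dx_i = v u_i dt
    du_i = (-gamma u_i + F_i) dt + sqrt(2 D) dW_i,

where the social force ``F_i = f_e + f_p`` sums an *escape* response to
conspecifics approaching from behind and a *pursuit* response toward
conspecifics receding in front.  Neighbours within the interaction radius
``R`` are classified by two signs: front/behind by ``u_i . r_hat`` and
approaching/receding by ``u_ji . r_hat`` (``r_hat`` the unit vector from i
to j, ``u_ji = u_j - u_i``).  Only front-receding (pursuit) and
back-approaching (escape) neighbours contribute; each class is averaged
over its own count and scaled by ``chi_p`` or ``chi_e``.  The contribution
of a pair is the projected relative velocity ``(u_ji . r_hat) r_hat``.
Heaviside gates use strict inequalities, so exactly perpendicular or
co-moving pairs contribute nothing.

The primary model is 2D on a periodic square.  A 1D variant on the ring is
provided as a structural diagnostic: with the same gating, particles moving
in opposite directions exert exactly zero force on one another, so the
population splits into non-interacting clockwise and counter-clockwise
groups — the reason this interaction scheme cannot, by itself, explain
directional switching in a ring arena.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

from .spp_core import SwarmState, signed_ring_displacement

PAIR_CLASSES = ("front_approaching", "front_receding", "back_approaching",
                "back_receding", "out_of_range", "degenerate")


@dataclasses.dataclass(frozen=True)
class EPParams:
    """Escape-and-pursuit parameters.

    ``box`` is the side of the periodic square (or the ring length in the
    1D variant); ``gamma`` and ``diff`` are the friction and diffusion
    coefficients of the velocity Langevin equation; ``chi_e``/``chi_p`` the
    escape and pursuit strengths; ``R`` the interaction radius.
    """

    N: int
    box: float
    gamma: float = 1.0
    diff: float = 0.1
    chi_e: float = 1.0
    chi_p: float = 1.0
    R: float = 1.0
    v: float = 0.1
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.box <= 0:
            raise ValueError("box must be > 0")
        if self.gamma < 0 or self.diff < 0:
            raise ValueError("gamma and diff must be >= 0")
        if self.chi_e < 0 or self.chi_p < 0:
            raise ValueError("interaction strengths must be >= 0")
        if self.R <= 0:
            raise ValueError("R must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclasses.dataclass
class SwarmState2D:
    """Positions in [0, box)^2 and 2-vector dimensionless velocities."""

    t: float
    pos: np.ndarray  # (N, 2)
    vel: np.ndarray  # (N, 2)

    def __post_init__(self) -> None:
        self.pos = np.atleast_2d(np.asarray(self.pos, dtype=float))
        self.vel = np.atleast_2d(np.asarray(self.vel, dtype=float))
        if self.pos.shape != self.vel.shape or self.pos.shape[1] != 2:
            raise ValueError("pos and vel must both have shape (N, 2)")

    @property
    def N(self) -> int:
        return self.pos.shape[0]

    @classmethod
    def random(cls, params: EPParams, rng: np.random.Generator,
               speed: float = 1.0) -> "SwarmState2D":
        pos = rng.uniform(0.0, params.box, (params.N, 2))
        theta = rng.uniform(0.0, 2.0 * math.pi, params.N)
        vel = speed * np.column_stack([np.cos(theta), np.sin(theta)])
        return cls(t=0.0, pos=pos, vel=vel)

    def copy(self) -> "SwarmState2D":
        return SwarmState2D(self.t, self.pos.copy(), self.vel.copy())


def _wrapped_separations(pos: np.ndarray, i: int, box: float) -> np.ndarray:
    """Minimal-image displacement vectors from particle i to all others."""
    r = pos - pos[i]
    return (r + 0.5 * box) % box - 0.5 * box


def classify_pair(state: SwarmState2D, i: int, j: int,
                  params: EPParams) -> str:
    """Classify neighbour ``j`` relative to focal ``i``.

    Ties (zero separation, exactly perpendicular heading, or zero projected
    relative velocity) are reported as ``"degenerate"``: they fall in no
    force class and contribute nothing.
    """
    if i == j:
        raise ValueError("classify_pair requires i != j")
    r = _wrapped_separations(state.pos, i, params.box)[j]
    dist = float(np.linalg.norm(r))
    if dist == 0.0:
        return "degenerate"
    if dist >= params.R:
        return "out_of_range"
    rhat = r / dist
    front = float(state.vel[i] @ rhat)
    appr = float((state.vel[j] - state.vel[i]) @ rhat)
    if front == 0.0 or appr == 0.0:
        return "degenerate"
    if front > 0.0:
        return "front_receding" if appr > 0.0 else "front_approaching"
    return "back_approaching" if appr < 0.0 else "back_receding"


def social_force(state: SwarmState2D, i: int, params: EPParams) -> np.ndarray:
    """Escape-plus-pursuit force on particle ``i`` (2-vector).

    Pursuit averages the projected relative velocities over front-receding
    neighbours (scaled by ``chi_p``); escape over back-approaching
    neighbours (scaled by ``chi_e``); the other two classes are ignored.
    """
    r = _wrapped_separations(state.pos, i, params.box)
    dist = np.linalg.norm(r, axis=1)
    ok = (dist > 0.0) & (dist < params.R)
    ok[i] = False
    force = np.zeros(2)
    if not ok.any():
        return force
    idx = np.nonzero(ok)[0]
    rhat = r[idx] / dist[idx, None]
    front = rhat @ state.vel[i]
    appr = np.einsum("kd,kd->k", state.vel[idx] - state.vel[i], rhat)
    proj = appr[:, None] * rhat  # (u_ji . r_hat) r_hat
    pursuit = (front > 0.0) & (appr > 0.0)
    escape = (front < 0.0) & (appr < 0.0)
    if pursuit.any():
        force += params.chi_p * proj[pursuit].sum(axis=0) / pursuit.sum()
    if escape.any():
        force += params.chi_e * proj[escape].sum(axis=0) / escape.sum()
    return force


def step_ep(state: SwarmState2D, params: EPParams,
            rng: Optional[np.random.Generator] = None) -> SwarmState2D:
    """Euler-Maruyama step of the 2D escape-and-pursuit dynamics."""
    N = state.N
    if params.chi_e == 0.0 and params.chi_p == 0.0:
        forces = np.zeros((N, 2))
    else:
        forces = np.array([social_force(state, i, params) for i in range(N)])
    noise = 0.0
    if params.diff > 0.0:
        if rng is None:
            raise ValueError("diff > 0 requires an rng")
        noise = math.sqrt(2.0 * params.diff * params.dt) * rng.normal(size=(N, 2))
    vel = state.vel + (-params.gamma * state.vel + forces) * params.dt + noise
    pos = (state.pos + params.v * state.vel * params.dt) % params.box
    return SwarmState2D(state.t + params.dt, pos, vel)


# ---------------------------------------------------------------------------
# 1D diagnostic variant

def social_force_1d(state: SwarmState, i: int, params: EPParams,
                    subset: Optional[np.ndarray] = None) -> float:
    """Escape-plus-pursuit force on ring particle ``i`` (scalar).

    ``subset`` optionally restricts the candidate neighbours (used to test
    the structural claim that opposite-direction groups do not interact).
    """
    L = params.box
    disp = signed_ring_displacement(state.x[i], state.x, L)
    dist = np.abs(disp)
    ok = (dist > 0.0) & (dist < params.R)
    ok[i] = False
    if subset is not None:
        ok &= subset
    if not ok.any():
        return 0.0
    idx = np.nonzero(ok)[0]
    rhat = np.sign(disp[idx])
    front = state.u[i] * rhat
    appr = (state.u[idx] - state.u[i]) * rhat
    proj = appr * rhat
    pursuit = (front > 0.0) & (appr > 0.0)
    escape = (front < 0.0) & (appr < 0.0)
    force = 0.0
    if pursuit.any():
        force += params.chi_p * proj[pursuit].sum() / pursuit.sum()
    if escape.any():
        force += params.chi_e * proj[escape].sum() / escape.sum()
    return float(force)


def step_ep_1d(state: SwarmState, params: EPParams,
               rng: Optional[np.random.Generator] = None) -> SwarmState:
    """Euler-Maruyama step of the 1D escape-and-pursuit variant on a ring."""
    N = state.N
    forces = np.array([social_force_1d(state, i, params) for i in range(N)])
    noise = 0.0
    if params.diff > 0.0:
        if rng is None:
            raise ValueError("diff > 0 requires an rng")
        noise = math.sqrt(2.0 * params.diff * params.dt) * rng.normal(size=N)
    u = state.u + (-params.gamma * state.u + forces) * params.dt + noise
    x = (state.x + params.v * state.u * params.dt) % params.box
    return SwarmState(state.t + params.dt, x, u, state.moving.copy())
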