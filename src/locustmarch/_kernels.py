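"""Compiled inner loops for long simulation runs.

Every kernel advances the swarm over a *block* of pre-drawn random numbers,
so that all randomness is owned by ``numpy.random.Generator`` streams at the
Python level and runs stay bit-reproducible regardless of block size.

The kernels are private: :func:`locustmarch.spp_core.run_simulation` is the
supported entry point.  The pure-numpy single-step functions in
:mod:`locustmarch.spp_core` and :mod:`locustmarch.pause_and_go` implement the
same updates and are cross-checked against these kernels in the test suite.
"""

import math

import numpy as np
from numba import njit

# velocity-update modes for _align_block
MODE_CZIROK = 0  # Euler-Maruyama of the continuous model; dt = 1 is the discrete model
MODE_BUHL = 1  # persistence-weighted, self-excluded average, dt = 1
MODE_INDIVIDUAL_CHOICE = 2  # Bernoulli retain-vs-align


@njit(cache=True)
def _ring_dist(a, b, L, half):
    d = a - b
    if d < 0.0:
        d = -d
    if d > half:
        d = L - d
    return d


@njit(cache=True)
def _g(u):
    if u > 0.0:
        return 0.5 * (u + 1.0)
    elif u < 0.0:
        return 0.5 * (u - 1.0)
    return 0.0


@njit(cache=True)
def _align_block(x, u, xi, retain, mode, alpha, v, dt, delta, L,
                 include_self, phi_out):
    """Advance an alignment model by ``xi.shape[0]`` synchronous steps.

    ``x`` and ``u`` are modified in place; ``phi_out[s]`` receives the order
    parameter after step ``s``.  ``xi`` holds the unscaled noise draws (one
    row per step, variance sigma^2); ``retain`` is only read when
    ``mode == MODE_INDIVIDUAL_CHOICE``.
    """
    n_steps, N = xi.shape
    half = 0.5 * L
    sqdt = math.sqrt(dt)
    unew = np.empty(N)
    for s in range(n_steps):
        for i in range(N):
            acc = 0.0
            cnt = 0
            for j in range(N):
                if not include_self and j == i:
                    continue
                if _ring_dist(x[i], x[j], L, half) <= delta:
                    acc += u[j]
                    cnt += 1
            m = acc / cnt if cnt > 0 else 0.0
            g = _g(m)
            if mode == MODE_CZIROK:
                unew[i] = u[i] + (g - u[i]) * dt + sqdt * xi[s, i]
            elif mode == MODE_BUHL:
                unew[i] = alpha * u[i] + (1.0 - alpha) * g + xi[s, i]
            else:  # MODE_INDIVIDUAL_CHOICE
                if retain[s, i]:
                    unew[i] = u[i] + sqdt * xi[s, i]
                else:
                    unew[i] = u[i] + (g - u[i]) * dt + sqdt * xi[s, i]
        # positions advance with the pre-update velocities (synchronous step)
        for i in range(N):
            x[i] = (x[i] + v * u[i] * dt) % L
        ph = 0.0
        for i in range(N):
            u[i] = unew[i]
            ph += unew[i]
        phi_out[s] = ph / N


@njit(cache=True)
def _bode_block(x, u, pick_i, pick_k, v, dt, delta, r2, L, phi_out):
    """Asynchronous three-zone dynamics: N random sub-updates per step.

    ``pick_i`` and ``pick_k`` are uniform(0,1) draws of shape (n_steps, N)
    selecting the focal individual and, among its neighbours, the reference
    neighbour.
    """
    n_steps, N = pick_i.shape
    half = 0.5 * L
    for s in range(n_steps):
        for m in range(N):
            i = int(pick_i[s, m] * N)
            if i == N:
                i = N - 1
            cnt = 0
            for j in range(N):
                if j == i:
                    continue
                if _ring_dist(x[i], x[j], L, half) <= delta:
                    cnt += 1
            if cnt > 0:
                kidx = int(pick_k[s, m] * cnt)
                if kidx == cnt:
                    kidx = cnt - 1
                k = -1
                c2 = 0
                for j in range(N):
                    if j == i:
                        continue
                    if _ring_dist(x[i], x[j], L, half) <= delta:
                        if c2 == kidx:
                            k = j
                            break
                        c2 += 1
                disp = x[k] - x[i]
                disp = (disp + half) % L - half
                d = abs(disp)
                if d <= r2:
                    u[i] = _g(u[k])
                else:
                    w = (d - r2) / (delta - r2)
                    if disp > 0.0:
                        u[i] = _g(w)
                    elif disp < 0.0:
                        u[i] = _g(-w)
                    else:
                        u[i] = 0.0
            x[i] = (x[i] + v * u[i] * dt) % L
        ph = 0.0
        for i in range(N):
            ph += u[i]
        phi_out[s] = ph / N


@njit(cache=True)
def _png_block(x, u, moving, ev, ch, xi, v, dt, delta, L,
               p_stop, p_start0, p_start1, nc, a0, a1,
               phi_out, phi_mov_out, nmov_out):
    """Advance the pause-and-go model by ``ev.shape[0]`` synchronous steps.

    Event probabilities are pre-mapped from rates (1 - exp(-k dt)).  Within a
    step, all neighbour statistics are evaluated on the state at time t:
    walkers displace during the step and may stop at its end; standers may
    start (drawing a fresh heading with alignment probability a0 + a1*|m|)
    and begin displacing on the *next* step.
    ``ev`` gates stop/start events, ``ch`` the align-vs-retain choice.
    """
    n_steps, N = ev.shape
    half = 0.5 * L
    sqdt = math.sqrt(dt)
    unew = np.empty(N)
    mnew = np.empty(N, np.bool_)
    for s in range(n_steps):
        for i in range(N):
            acc = 0.0
            cnt = 0
            for j in range(N):
                if j == i or not moving[j]:
                    continue
                if _ring_dist(x[i], x[j], L, half) <= delta:
                    acc += u[j]
                    cnt += 1
            if moving[i]:
                unew[i] = u[i]
                mnew[i] = ev[s, i] >= p_stop
            else:
                p_start = p_start1 if cnt >= nc else p_start0
                if ev[s, i] < p_start:
                    mnew[i] = True
                    m = acc / cnt if cnt > 0 else 0.0
                    al = a0 + a1 * abs(m)
                    if al < 0.0:
                        al = 0.0
                    elif al > 1.0:
                        al = 1.0
                    if ch[s, i] < al:
                        unew[i] = u[i] + (_g(m) - u[i]) * dt + sqdt * xi[s, i]
                    else:
                        unew[i] = u[i] + sqdt * xi[s, i]
                else:
                    mnew[i] = False
                    unew[i] = u[i]
        for i in range(N):
            if moving[i]:
                x[i] = (x[i] + v * u[i] * dt) % L
        ph = 0.0
        phm = 0.0
        c = 0
        for i in range(N):
            u[i] = unew[i]
            moving[i] = mnew[i]
            ph += u[i]
            if moving[i]:
                phm += u[i]
                c += 1
        phi_out[s] = ph / N
        phi_mov_out[s] = phm / c if c > 0 else 0.0
        nmov_out[s] = c


# drift/diffusion codes for _sde_block
DRIFT_ZERO = 0
DRIFT_LINEAR = 1  # F = -a * phi
DRIFT_DOUBLE_WELL = 2  # F = a * phi - b * phi^3
DRIFT_CONST = 3  # F = a
DIFF_ZERO = 0
DIFF_CONST = 1  # D = a


@njit(cache=True)
def _sde_block(phi0, z, dt, drift_code, da, db, diff_code, ca, out):
    """Euler-Maruyama path of d(phi) = F dt + sqrt(2 D dt) * z."""
    n = z.shape[0]
    p = phi0
    sq = math.sqrt(dt)
    for s in range(n):
        if drift_code == DRIFT_ZERO:
            f = 0.0
        elif drift_code == DRIFT_LINEAR:
            f = -da * p
        elif drift_code == DRIFT_DOUBLE_WELL:
            f = da * p - db * p * p * p
        else:
            f = da
        if diff_code == DIFF_ZERO:
            d = 0.0
        else:
            d = ca
        p = p + f * dt + math.sqrt(2.0 * d) * sq * z[s]
        out[s] = p
    return p
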