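"""Ring geometry, the propulsion nonlinearity, and the alignment models."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from locustmarch.spp_core import (BodeParams, ModelParams, SwarmState,
                                  bode_target_u, g_function, local_mean_u,
                                  reference_params, ring_distance,
                                  run_simulation, signed_ring_displacement,
                                  step_bode, step_buhl, step_czirok,
                                  step_individual_choice)
from locustmarch import _kernels


def make_state(x, u, moving=None):
    x = np.asarray(x, dtype=float)
    if moving is None:
        moving = np.ones(x.size, dtype=bool)
    return SwarmState(0.0, x, np.asarray(u, dtype=float), moving)


# ---------------------------------------------------------------------------
# geometry

@pytest.mark.parametrize("x1,x2,L,expected", [
    (0.2, 9.9, 10.0, 0.3),   # wraps through the boundary
    (1.0, 4.0, 10.0, 3.0),   # interior pair
    (7.3, 7.3, 10.0, 0.0),   # identical positions
])
def test_ring_distance_examples(x1, x2, L, expected):
    assert ring_distance(x1, x2, L) == pytest.approx(expected)


def test_ring_distance_rejects_bad_length():
    with pytest.raises(ValueError):
        ring_distance(0.1, 0.2, 0.0)


@given(st.floats(0, 10, exclude_max=True), st.floats(0, 10, exclude_max=True))
def test_ring_distance_symmetric_and_bounded(a, b):
    d = ring_distance(a, b, 10.0)
    assert d == ring_distance(b, a, 10.0)
    assert 0.0 <= d <= 5.0


def test_signed_displacement_wraps_to_nearest_image():
    assert signed_ring_displacement(9.9, 0.2, 10.0) == pytest.approx(0.3)
    assert signed_ring_displacement(0.2, 9.9, 10.0) == pytest.approx(-0.3)


# ---------------------------------------------------------------------------
# propulsion function

@pytest.mark.parametrize("u,expected", [(0.0, 0.0), (1.0, 1.0),
                                        (-0.5, -0.75), (0.5, 0.75)])
def test_g_function_examples(u, expected):
    assert g_function(u) == pytest.approx(expected)


def test_g_function_odd():
    rng = np.random.default_rng(7)
    u = rng.uniform(-2, 2, 1000)
    np.testing.assert_array_equal(g_function(-u), -g_function(u))


# ---------------------------------------------------------------------------
# local averages

def test_local_mean_lone_particle():
    s = make_state([1.0], [0.4])
    assert local_mean_u(s, 0, delta=1.0, L=100.0, include_self=False) == 0.0
    assert local_mean_u(s, 0, delta=1.0, L=100.0, include_self=True) == 0.4


def test_local_mean_three_neighbors():
    s = make_state([0.0, 0.3, 0.6], [1.0, 1.0, -1.0])
    assert local_mean_u(s, 0, delta=1.0, L=10.0) == pytest.approx(1 / 3)


def test_local_mean_moving_only_excludes_standers():
    s = make_state([0.0, 0.3, 0.6], [1.0, 0.5, -1.0],
                   moving=[True, False, True])
    m = local_mean_u(s, 0, delta=1.0, L=10.0, moving_only=True)
    assert m == pytest.approx((1.0 - 1.0) / 2)


# ---------------------------------------------------------------------------
# parameter records

def test_params_derive_density_and_noise():
    p = ModelParams(N=100, rho=3.2, eta=2.0)
    assert p.L == pytest.approx(100 / 3.2)
    assert p.sigma == pytest.approx(2.0 / math.sqrt(12))
    q = ModelParams(N=10, L=5.0, sigma=0.1)
    assert q.rho == pytest.approx(2.0)
    assert q.eta == pytest.approx(0.1 * math.sqrt(12))


def test_params_reject_inconsistent_pairs():
    with pytest.raises(ValueError):
        ModelParams(N=10, L=5.0, rho=3.0, eta=2.0)
    with pytest.raises(ValueError):
        ModelParams(N=10, L=5.0)  # no noise amplitude
    with pytest.raises(ValueError):
        ModelParams(N=10, L=5.0, eta=1.0, alpha=1.5)
    with pytest.raises(ValueError):
        BodeParams(N=10, L=5.0, eta=1.0, delta=1.0, r2=1.5)


def test_params_replace_rederives_partner_field():
    p = reference_params(rho=3.2)
    q = p.replace(rho=0.1)
    assert q.L == pytest.approx(1000.0)
    r = p.replace(sigma=0.1)
    assert r.eta == pytest.approx(0.1 * math.sqrt(12))


# ---------------------------------------------------------------------------
# single steps

def test_czirok_consensus_is_fixed_point(rng):
    p = ModelParams(N=5, L=2.0, sigma=0.0, dt=1.0)
    s = make_state(np.linspace(0, 1.8, 5), np.ones(5))
    out = step_czirok(s, p, rng)
    np.testing.assert_allclose(out.u, 1.0)


def test_czirok_lone_particle_deterministic_step(rng):
    p = ModelParams(N=1, L=100.0, sigma=0.0, dt=0.1)
    s = make_state([50.0], [0.5])
    out = step_czirok(s, p, rng)
    assert out.u[0] == pytest.approx(0.5 + (0.75 - 0.5) * 0.1)
    assert out.x[0] == pytest.approx(50.0 + 0.1 * 0.5 * 0.1)


def test_czirok_rejects_unstable_step_size(rng):
    p = ModelParams(N=2, L=10.0, sigma=0.0, dt=2.5)
    s = make_state([0.0, 1.0], [0.5, 0.5])
    with pytest.raises(ValueError):
        step_czirok(s, p, rng)


def test_buhl_lone_particle_relaxes_by_alpha(rng):
    p = ModelParams(N=1, L=100.0, sigma=0.0, alpha=0.66)
    s = make_state([0.0], [1.0])
    out = step_buhl(s, p, rng)
    assert out.u[0] == pytest.approx(0.66)


def test_buhl_pair_consensus_is_fixed_point(rng):
    p = ModelParams(N=2, L=10.0, sigma=0.0, alpha=0.66)
    s = make_state([0.0, 0.5], [1.0, 1.0])
    out = step_buhl(s, p, rng)
    np.testing.assert_allclose(out.u, 1.0)


def test_individual_choice_alpha_one_is_noisy_persistence(rng):
    p = ModelParams(N=4, L=10.0, sigma=0.0, alpha=1.0)
    s = make_state([0.0, 1.0, 2.0, 3.0], [0.3, -0.2, 0.8, 0.1])
    out = step_individual_choice(s, p, rng)
    np.testing.assert_array_equal(out.u, s.u)


def test_individual_choice_retain_fraction_matches_bernoulli(rng):
    # isolated noise-free particles: retain keeps u, align jumps to G(u) != u
    N = 4000
    p = ModelParams(N=N, L=10.0 * N, sigma=0.0, alpha=0.5, delta=0.01)
    x = np.arange(N) * 10.0
    u = np.random.default_rng(5).uniform(0.2, 0.8, N)
    out = step_individual_choice(make_state(x, u), p, rng)
    frac = np.mean(out.u == u)
    # binomial oracle: 3 sigma around alpha
    assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / N)


def test_all_models_keep_positions_on_ring(rng):
    p = reference_params(rho=3.2, N=30)
    for model in ("czirok", "individual_choice", "buhl"):
        traj = run_simulation(model, p.replace(alpha=0.5), 200, seed=3,
                              store_states=True, sample_every=50)
        for s in traj.states:
            assert np.all((s.x >= 0) & (s.x < p.L))
    bp = BodeParams(N=30, rho=3.2, eta=2.0, r2=0.5)
    traj = run_simulation("bode", bp, 200, seed=3, store_states=True,
                          sample_every=50)
    for s in traj.states:
        assert np.all((s.x >= 0) & (s.x < bp.L))


# ---------------------------------------------------------------------------
# three-zone model

def test_bode_alignment_zone_copies_propulsion_of_neighbor():
    p = BodeParams(N=2, L=10.0, eta=0.0, r2=0.5)
    assert bode_target_u(1.0, 0.3, p) == pytest.approx(1.0)
    assert bode_target_u(-0.4, -0.2, p) == pytest.approx(g_function(-0.4))


def test_bode_attraction_zone_heads_toward_neighbor():
    p = BodeParams(N=2, L=10.0, eta=0.0, r2=0.5, delta=1.0)
    # neighbour on the positive side, midway through the attraction zone
    u = bode_target_u(-1.0, 0.75, p)
    assert u > 0
    assert u == pytest.approx(g_function(0.5))
    assert bode_target_u(-1.0, -0.75, p) == pytest.approx(-u)


def test_bode_isolated_particles_keep_velocity(rng):
    p = BodeParams(N=2, L=100.0, eta=0.0, r2=0.5, delta=1.0, v=0.1, dt=1.0)
    s = make_state([0.0, 50.0], [0.7, -0.3])
    out = step_bode(s, p, rng)
    np.testing.assert_array_equal(out.u, s.u)
    # each particle advances v*u*dt once per time it was picked (k >= 0)
    steps_taken = (out.x - s.x) / (p.v * s.u * p.dt)
    np.testing.assert_allclose(steps_taken, np.round(steps_taken), atol=1e-9)
    assert np.round(steps_taken).sum() == p.N


def test_bode_consensus_in_alignment_zone_is_fixed(rng):
    p = BodeParams(N=4, L=10.0, eta=0.0, r2=0.5, delta=1.0)
    s = make_state([0.0, 0.1, 0.2, 0.3], np.ones(4))
    out = step_bode(s, p, rng)
    np.testing.assert_allclose(out.u, 1.0)


# ---------------------------------------------------------------------------
# the driver

def test_run_simulation_rejects_unknown_model():
    p = reference_params()
    with pytest.raises(ValueError):
        run_simulation("flock2d", p, 10)


def test_run_simulation_is_reproducible():
    p = reference_params(N=20, rho=2.0)
    a = run_simulation("czirok", p, 300, seed=42, store_states=True,
                       sample_every=300)
    b = run_simulation("czirok", p, 300, seed=42, store_states=True,
                       sample_every=300)
    np.testing.assert_array_equal(a.phi, b.phi)
    np.testing.assert_array_equal(a.states[-1].x, b.states[-1].x)
    np.testing.assert_array_equal(a.states[-1].u, b.states[-1].u)


def test_kernel_matches_python_steps_czirok_and_buhl():
    """The compiled block update reproduces the reference single-step
    functions draw-for-draw when fed the same noise stream."""
    for model, step, kw in (("czirok", step_czirok, {}),
                            ("buhl", step_buhl, {"alpha": 0.66})):
        p = ModelParams(N=12, rho=2.0, eta=2.0, dt=1.0, **kw)
        root = np.random.default_rng(99)
        init_rng, choice_rng, noise_rng, event_rng = root.spawn(4)
        fast = run_simulation(model, p, 40, seed=99, store_states=True,
                              sample_every=40)
        state = SwarmState.random(p, init_rng)
        phis = [state.u.mean()]
        for _ in range(40):
            state = step(state, p, noise_rng)
            phis.append(state.u.mean())
        np.testing.assert_allclose(fast.phi, phis, rtol=0, atol=1e-12)
        np.testing.assert_allclose(fast.states[-1].u, state.u, atol=1e-12)
        np.testing.assert_allclose(fast.states[-1].x, state.x, atol=1e-12)


def test_kernel_matches_python_step_individual_choice(scripted_rng_cls):
    p = ModelParams(N=10, rho=2.0, eta=2.0, dt=1.0, alpha=0.4)
    rng = np.random.default_rng(11)
    x0 = rng.uniform(0, p.L, p.N)
    u0 = rng.uniform(-1, 1, p.N)
    n_steps = 30
    retain_u = rng.random((n_steps, p.N))
    xi = rng.uniform(-p.eta / 2, p.eta / 2, (n_steps, p.N))

    x, u = x0.copy(), u0.copy()
    phi = np.empty(n_steps)
    _kernels._align_block(x, u, xi, retain_u < p.alpha,
                          _kernels.MODE_INDIVIDUAL_CHOICE, p.alpha, p.v,
                          p.dt, p.delta, p.L, True, phi)

    state = make_state(x0, u0)
    for s in range(n_steps):
        state = step_individual_choice(
            state, p, scripted_rng_cls([retain_u[s], xi[s]]))
    np.testing.assert_allclose(state.u, u, atol=1e-12)
    np.testing.assert_allclose(state.x, x, atol=1e-12)
    assert phi[-1] == pytest.approx(state.u.mean(), abs=1e-12)


def test_individual_choice_alpha_zero_equals_base_model():
    """With retain probability zero the individual-choice model is
    step-for-step identical to the discrete base model (matched noise
    streams)."""
    p = reference_params(N=20, rho=2.0)
    a = run_simulation("czirok", p, 100, seed=7, store_states=True,
                       sample_every=100)
    b = run_simulation("individual_choice", p.replace(alpha=0.0), 100,
                       seed=7, store_states=True, sample_every=100)
    np.testing.assert_array_equal(a.phi, b.phi)
    np.testing.assert_array_equal(a.states[-1].x, b.states[-1].x)
    np.testing.assert_array_equal(a.states[-1].u, b.states[-1].u)


def test_async_and_single_neighbor_variants_run():
    p = reference_params(N=15, rho=2.0, update_mode="asynchronous")
    traj = run_simulation("czirok", p, 50, seed=1, store_states=True,
                          sample_every=50)
    assert np.all((traj.states[-1].x >= 0) & (traj.states[-1].x < p.L))
    q = reference_params(N=15, rho=2.0,
                         neighbor_mode="single_random_neighbor")
    traj = run_simulation("individual_choice", q.replace(alpha=0.3), 50,
                          seed=1)
    assert np.isfinite(traj.phi).all()


def test_lone_particle_ou_limits():
    """Self-inclusive averaging props the particle to +-1 with variance
    sigma^2; self-excluded averaging leaves it fluctuating around zero."""
    p = ModelParams(N=1, L=100.0, sigma=0.1, noise_kind="gaussian", dt=0.01)
    traj = run_simulation("czirok", p, 30_000, seed=2,
                          init=SwarmState(0.0, [50.0], [0.5], [True]))
    u = traj.phi[3000:]
    assert abs(u.mean() - 1.0) < 0.03
    assert abs(u.var() - 0.01) < 0.004
    q = p.replace(include_self=False)
    traj = run_simulation("czirok", q, 30_000, seed=2,
                          init=SwarmState(0.0, [50.0], [0.5], [True]))
    assert abs(traj.phi[3000:].mean()) < 0.03


def test_switching_slows_with_size_in_small_arena():
    """At fixed ring length the directional switching rate of the
    persistence-weighted model falls monotonically with N."""
    from locustmarch.experiments import ScanSpec, scan_N, summarize
    base = ModelParams(N=5, L=8.0, eta=2.0, alpha=0.66, dt=1.0)
    spec = ScanSpec(model="buhl", base=base, param="N", values=[5, 10, 20],
                    seeds=[1, 2], n_steps=40_000)
    rates = summarize(scan_N(spec, fixed="L"))["rate"].to_numpy()
    assert rates[0] > rates[1] > rates[2]
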