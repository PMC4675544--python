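"""Reproducible comparative experiments: density/size scans, model
comparison, and ensemble drift/diffusion profiles.

Every scan is driven by an explicit list of seeds and returns a tidy
per-replicate table (one row per grid point and seed) so standard errors
can be formed downstream; :func:`summarize` aggregates to mean +/- s.e.m.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coarse_grain import (DriftDiffusionEstimate, OrderSeries, estimate_FD,
                           mean_order, order_parameter, transitions)
from .spp_core import ModelParams, SwarmState, run_simulation

#: Column schema of the per-replicate scan tables.  ``rate`` is switches per
#: unit simulated time; ``mean_order`` is the time-average of |phi| after
#: burn-in.
SCAN_COLUMNS = ("model", "param", "value", "seed", "mean_order", "rate",
                "n_switches", "n_steps")


@dataclasses.dataclass
class ScanSpec:
    """A named parameter scan.

    ``param`` is swept over ``values`` (rho for density scans with N fixed
    and L adjusted; N for size scans).  Each grid point is replicated once
    per seed; seeds must be distinct.
    """

    model: str
    base: ModelParams
    param: str
    values: Sequence[float]
    seeds: Sequence[int]
    n_steps: int = 200_000
    burn_frac: float = 0.1
    p_cutoff: float = 0.7
    moving_only: bool = False

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError("value grid must be non-empty")
        if len(self.seeds) == 0:
            raise ValueError("need at least one seed")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be distinct")


def _replicate_row(model: str, params: ModelParams, n_steps: int, seed: int,
                   burn_frac: float, p: float, moving_only: bool) -> dict:
    traj = run_simulation(model, params, n_steps, seed=seed)
    series = order_parameter(traj, moving_only=moving_only)
    burn = burn_frac * (series.times[-1] - series.times[0])
    mo = mean_order(series, burn_in=burn)
    keep = series.times >= series.times[0] + burn
    sub = OrderSeries(series.times[keep], series.phi[keep],
                      undefined=None if series.undefined is None
                      else series.undefined[keep])
    stats = transitions(sub, p=p)
    return {"seed": seed, "mean_order": mo, "rate": stats.rate,
            "n_switches": stats.n_switches, "n_steps": n_steps}


def scan_density(spec: ScanSpec) -> pd.DataFrame:
    """Sweep the density rho at fixed N (ring length L = N / rho)."""
    if spec.param != "rho":
        raise ValueError("scan_density sweeps param 'rho'")
    rows = []
    for rho in spec.values:
        params = spec.base.replace(rho=float(rho))
        for seed in spec.seeds:
            row = _replicate_row(spec.model, params, spec.n_steps, seed,
                                 spec.burn_frac, spec.p_cutoff,
                                 spec.moving_only)
            rows.append({"model": spec.model, "param": "rho",
                         "value": float(rho), **row})
    return pd.DataFrame(rows, columns=list(SCAN_COLUMNS))


def scan_N(spec: ScanSpec, fixed: str = "L") -> pd.DataFrame:
    """Sweep the swarm size N.

    ``fixed = "L"`` keeps the ring length constant (the small-arena
    setting, where switching slows sharply as N grows); ``fixed = "rho"``
    keeps the density constant (the thermodynamic-limit setting).
    """
    if spec.param != "N":
        raise ValueError("scan_N sweeps param 'N'")
    if fixed not in ("L", "rho"):
        raise ValueError("fixed must be 'L' or 'rho'")
    rows = []
    for N in spec.values:
        if fixed == "L":
            params = spec.base.replace(N=int(N), L=spec.base.L, rho=None)
        else:
            params = spec.base.replace(N=int(N), rho=spec.base.rho, L=None)
        for seed in spec.seeds:
            row = _replicate_row(spec.model, params, spec.n_steps, seed,
                                 spec.burn_frac, spec.p_cutoff,
                                 spec.moving_only)
            rows.append({"model": spec.model, "param": "N",
                         "value": int(N), **row})
    return pd.DataFrame(rows, columns=list(SCAN_COLUMNS))


def compare_models(models: Sequence[str], params: ModelParams,
                   seeds: Sequence[int], n_steps: int = 200_000,
                   burn_frac: float = 0.1, p_cutoff: float = 0.7,
                   params_by_model: Optional[dict] = None) -> pd.DataFrame:
    """Run several models under identical seeds and geometry.

    Returns the per-replicate table; per-model parameter overrides (e.g. a
    BodeParams or PnGParams instance) may be supplied via
    ``params_by_model``.
    """
    if len(models) < 1:
        raise ValueError("need at least one model")
    rows = []
    for model in models:
        p = (params_by_model or {}).get(model, params)
        moving_only = model == "pause_and_go"
        for seed in seeds:
            row = _replicate_row(model, p, n_steps, seed, burn_frac,
                                 p_cutoff, moving_only)
            rows.append({"model": model, "param": "-", "value": np.nan,
                         **row})
    return pd.DataFrame(rows, columns=list(SCAN_COLUMNS))


def summarize(df: pd.DataFrame, by=("model", "param", "value")) -> pd.DataFrame:
    """Aggregate a per-replicate table to mean +/- s.e.m. per grid point."""
    g = df.groupby(list(by))
    out = g.agg(mean_order=("mean_order", "mean"),
                mean_order_sem=("mean_order", "sem"),
                rate=("rate", "mean"), rate_sem=("rate", "sem"),
                replicates=("seed", "count"))
    return out.reset_index()


def _spread_init(phi0: float, width: float = 0.3, moving_frac: float = 1.0):
    """Initial-condition factory with velocities centred on a target order.

    ``moving_frac`` sets the expected initial fraction of walkers (only
    meaningful for the pause-and-go model; alignment models ignore flags).
    """
    def make(rng: np.random.Generator, params: ModelParams) -> SwarmState:
        x = rng.uniform(0.0, params.L, params.N)
        u = phi0 + rng.uniform(-width, width, params.N)
        moving = rng.random(params.N) < moving_frac
        return SwarmState(0.0, x, u, moving)
    return make


def fd_profile(model: str, params: ModelParams, seed: int,
               n_runs: int = 200, run_steps: int = 400,
               dt_cg_steps: int = 1, n_bins: int = 25,
               min_count: int = 100, burn_steps: int = 0,
               moving_only: bool = False,
               phi0_range: tuple = (-1.05, 1.05),
               moving_frac_range: Optional[tuple] = None) -> DriftDiffusionEstimate:
    """Effective drift/diffusion profile from an ensemble of short runs.

    Long runs of an ordered swarm rarely visit intermediate order values, so
    the profile is sampled from ``n_runs`` short trajectories whose initial
    order parameter is spread uniformly over ``phi0_range`` — the
    many-short-trajectories sampling strategy.  Increments are pooled over
    the ensemble and binned by :func:`locustmarch.coarse_grain.estimate_FD`
    with coarse step ``dt_cg_steps`` sampling intervals.

    For the pause-and-go model, whose order dynamics depend on the swarm's
    activity as well as its order, ``moving_frac_range`` additionally
    spreads the initial fraction of walkers across the ensemble so both the
    low-activity (disordered) and high-activity branches are sampled.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_runs)
    phi0s = np.linspace(phi0_range[0], phi0_range[1], n_runs)
    if moving_frac_range is None:
        fracs = np.ones(n_runs)
    else:
        # cycle fast against the slow phi0 ramp to decorrelate the two
        fracs = np.resize(np.linspace(moving_frac_range[0],
                                      moving_frac_range[1], 17), n_runs)
    series = []
    for phi0, frac, child in zip(phi0s, fracs, children):
        traj = run_simulation(model, params, run_steps, seed=child,
                              init=_spread_init(float(phi0),
                                                moving_frac=float(frac)))
        s = order_parameter(traj, moving_only=moving_only)
        series.append(_drop_burn(s, burn_steps))
    dt = series[0].sampling_dt
    return estimate_FD(series, dt_cg=dt_cg_steps * dt, n_bins=n_bins,
                       min_count=min_count)


def _drop_burn(s: OrderSeries, burn_steps: int) -> OrderSeries:
    if not burn_steps:
        return s
    return OrderSeries(s.times[burn_steps:], s.phi[burn_steps:],
                       n_moving=None if s.n_moving is None
                       else s.n_moving[burn_steps:])


def png_fd_profile(params, seed: int, n_half: int = 150,
                   run_steps: int = 2000, burn_steps: int = 200,
                   dt_cg_steps: int = 5, n_bins: int = 17,
                   min_count: int = 500,
                   low_frac: float = 0.08, high_frac: float = 0.7,
                   phi0_range: tuple = (0.5, 1.1)) -> DriftDiffusionEstimate:
    """Drift/diffusion profile of the pause-and-go model.

    The order dynamics of an intermittent swarm couple order to *activity*:
    the disordered metastable state is the low-activity state (few movers,
    random-heading standing pool) and the ordered states are high-activity.
    The profile is therefore sampled from two ensembles of short runs
    initialised in and around the natural metastable states — ``n_half``
    runs from the low-activity disordered state (uniform random headings,
    initial walker fraction ``low_frac``) and ``n_half`` from ordered
    states with the pool order spread over ``+-phi0_range`` at walker
    fraction ``high_frac`` — and each branch's own fluctuations populate
    the phi axis.  Increments of the moving-only order parameter are pooled
    and binned as usual.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_half)
    phi0s = np.linspace(phi0_range[0], phi0_range[1], n_half)
    series = []

    def init_disordered(rng, prm):
        return SwarmState(0.0, rng.uniform(0.0, prm.L, prm.N),
                          rng.uniform(-1.0, 1.0, prm.N),
                          rng.random(prm.N) < low_frac)

    for k in range(n_half):
        traj = run_simulation("pause_and_go", params, run_steps,
                              seed=children[k], init=init_disordered)
        series.append(_drop_burn(order_parameter(traj, moving_only=True),
                                 burn_steps))
        phi0 = phi0s[k] * (1 if k % 2 else -1)
        traj = run_simulation("pause_and_go", params, run_steps,
                              seed=children[n_half + k],
                              init=_spread_init(float(phi0),
                                                moving_frac=high_frac))
        series.append(_drop_burn(order_parameter(traj, moving_only=True),
                                 burn_steps))
    dt = series[0].sampling_dt
    return estimate_FD(series, dt_cg=dt_cg_steps * dt, n_bins=n_bins,
                       min_count=min_count)
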