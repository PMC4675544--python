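"""Order-parameter statistics and effective drift/diffusion estimation.

When the swarm is ordered, the order parameter ``phi(t)`` (population mean
of the dimensionless velocities) dwells near +1 or -1 with rare switches —
metastability that admits two complementary coarse-grained descriptions:

* a two-state continuous-time Markov chain over the metastable sets
  ``A+ = {phi > p}`` and ``A- = {phi < -p}`` (default cutoff ``p = 0.7``),
  characterised by switching counts, rates and approximately exponential
  waiting times; and

* an effective 1D diffusion ``d(phi) = F(phi) dt + sqrt(2 D(phi)) dW``
  whose drift and diffusion are estimated from conditional increment
  moments on a grid of phi-bins:

      F(phi) = <phi_{t+dt} - phi_t | phi> / dt
      D(phi) = Var[phi_{t+dt} - phi_t | phi] / (2 dt)

  (optionally the raw second moment replaces the variance; the two agree as
  dt -> 0).  Stable zeros of F — sign changes from + to - — mark the
  metastable states.

The estimators apply equally to simulated series, the synthetic-SDE paths
generated here (which serve as an independent oracle for estimator tests),
or external series read from disk.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence, Union

import numpy as np
from statsmodels.stats.diagnostic import lilliefors

from . import _kernels
from .spp_core import Trajectory

LABEL_POS = 1  # A+
LABEL_NEG = -1  # A-
LABEL_DISORDERED = 0  # D


@dataclasses.dataclass
class OrderSeries:
    """A sampled order-parameter time series.

    ``undefined`` flags samples where the order parameter is not defined
    (no moving particles); flagged samples are skipped by every statistic.
    """

    times: np.ndarray
    phi: np.ndarray
    n_moving: Optional[np.ndarray] = None
    undefined: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.times.shape != self.phi.shape:
            raise ValueError("times and phi must have equal length")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.n_moving is not None:
            self.n_moving = np.asarray(self.n_moving)
            if self.n_moving.shape != self.phi.shape:
                raise ValueError("n_moving length mismatch")
            if self.undefined is None:
                self.undefined = self.n_moving == 0
        if self.undefined is not None:
            self.undefined = np.asarray(self.undefined, dtype=bool)
            if self.undefined.shape != self.phi.shape:
                raise ValueError("undefined length mismatch")

    @property
    def sampling_dt(self) -> float:
        if self.times.size < 2:
            raise ValueError("need at least two samples")
        steps = np.diff(self.times)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise ValueError("series is not uniformly sampled")
        return float(steps[0])

    def defined_mask(self) -> np.ndarray:
        if self.undefined is None:
            return np.ones(self.phi.size, dtype=bool)
        return ~self.undefined


@dataclasses.dataclass
class TransitionStats:
    """Metastable-state labelling and switching statistics of a series."""

    p_cutoff: float
    labels: np.ndarray  # int8 over {+1 (A+), -1 (A-), 0 (D)}
    n_switches: int
    total_time: float
    rate: float
    waits: np.ndarray


@dataclasses.dataclass
class ExponentialFit:
    """Maximum-likelihood exponential fit with a Lilliefors GOF test."""

    rate: float
    statistic: float
    pvalue: float
    n: int


@dataclasses.dataclass
class DriftDiffusionEstimate:
    """Binned estimates of the effective drift F(phi) and diffusion D(phi)."""

    bin_centers: np.ndarray
    F: np.ndarray
    D: np.ndarray
    counts: np.ndarray
    dt_cg: float
    method: str
    valid: np.ndarray


@dataclasses.dataclass
class FixedPoint:
    """A zero crossing of the estimated drift."""

    location: float
    stability: str  # "stable" | "unstable"


# ---------------------------------------------------------------------------

def order_parameter(traj: Trajectory, moving_only: bool = False) -> OrderSeries:
    """Extract the order-parameter series from a trajectory.

    Uses the per-step record made during the run; falls back to stored
    snapshots when only those are available.  With ``moving_only`` the
    moving-only order parameter is returned and samples with no movers are
    flagged undefined.
    """
    if traj.phi is not None and traj.phi.size:
        if moving_only and traj.phi_moving is not None:
            return OrderSeries(traj.times, traj.phi_moving.copy(),
                               n_moving=traj.n_moving.copy())
        return OrderSeries(traj.times, traj.phi.copy())
    if not traj.states:
        raise ValueError("trajectory stores neither a phi record nor states")
    times = np.array([s.t for s in traj.states])
    if moving_only:
        nm = np.array([s.n_moving for s in traj.states])
        phi = np.array([s.u[s.moving].mean() if s.moving.any() else 0.0
                        for s in traj.states])
        return OrderSeries(times, phi, n_moving=nm)
    phi = np.array([s.u.mean() for s in traj.states])
    return OrderSeries(times, phi)


def mean_order(series: OrderSeries, burn_in: Optional[float] = None) -> float:
    """Time-average of |phi| after discarding ``burn_in`` time units.

    Default burn-in: the first 10% of the observation window.
    """
    t = series.times
    if burn_in is None:
        burn_in = 0.1 * (t[-1] - t[0])
    keep = (t >= t[0] + burn_in) & series.defined_mask()
    if not keep.any():
        raise ValueError("burn_in leaves no samples")
    return float(np.abs(series.phi[keep]).mean())


def transitions(series: OrderSeries, p: float = 0.7) -> TransitionStats:
    """Label metastable states and count directional switches.

    Samples are labelled A+ (``phi > p``), A- (``phi < -p``) or D
    (disordered).  A switch is an entry into A+ or A- after most recently
    residing in the opposite labelled state; intermediate D samples do not
    reset the residence (hysteresis), so same-side re-entries are not
    counted.  Waiting times are the gaps between consecutive opposite-state
    entries; the rate is switches per unit observed time.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    keep = series.defined_mask()
    t = series.times[keep]
    phi = series.phi[keep]
    labels = np.zeros(phi.size, dtype=np.int8)
    labels[phi > p] = LABEL_POS
    labels[phi < -p] = LABEL_NEG
    idx = np.nonzero(labels)[0]
    total_time = float(t[-1] - t[0]) if t.size >= 2 else 0.0
    if idx.size == 0:
        return TransitionStats(p, labels, 0, total_time, 0.0,
                               np.empty(0))
    signs = labels[idx]
    change = np.nonzero(signs[1:] != signs[:-1])[0]
    entry_times = np.concatenate([[t[idx[0]]], t[idx[1:][change]]])
    waits = np.diff(entry_times)
    n_switches = int(change.size)
    rate = n_switches / total_time if total_time > 0 else 0.0
    return TransitionStats(p, labels, n_switches, total_time, rate, waits)


def fit_exponential_waits(waits: Sequence[float]) -> ExponentialFit:
    """MLE exponential fit of waiting times with a Lilliefors GOF test.

    The MLE rate is ``1 / mean(waits)``.  The goodness-of-fit statistic is
    the Lilliefors-corrected Kolmogorov-Smirnov distance against the
    exponential family (correct for the estimated scale); small p-values
    reject exponentiality.
    """
    waits = np.asarray(waits, dtype=float)
    if waits.size < 2:
        raise ValueError("need at least 2 waiting times")
    if np.any(waits <= 0):
        raise ValueError("waiting times must be positive")
    rate = 1.0 / waits.mean()
    if waits.size >= 3 and waits.std() > 0:
        stat, pval = lilliefors(waits, dist="exp")
    else:
        stat, pval = math.nan, math.nan
    return ExponentialFit(rate=float(rate), statistic=float(stat),
                          pvalue=float(pval), n=int(waits.size))


# ---------------------------------------------------------------------------

def _increments(series: OrderSeries, stride: int):
    phi = series.phi
    ok = series.defined_mask()
    start = phi[:-stride]
    inc = phi[stride:] - start
    good = ok[:-stride] & ok[stride:]
    return start[good], inc[good]


def estimate_FD(series: Union[OrderSeries, Sequence[OrderSeries]],
                dt_cg: Optional[float] = None,
                n_bins: int = 51,
                method: str = "variance",
                min_count: int = 100,
                bin_range: tuple = (-1.2, 1.2)) -> DriftDiffusionEstimate:
    """Binned drift/diffusion estimates from one or many series.

    Increments ``phi_{t+dt_cg} - phi_t`` are grouped by the starting value
    on a uniform grid over ``bin_range``; per bin, ``F`` is the mean
    increment over ``dt_cg`` and ``D`` the variance (or raw second moment)
    of increments over ``2 dt_cg``.  ``dt_cg`` must be an integer multiple
    of the sampling interval (default: one interval).  Bins with fewer than
    ``min_count`` increments are masked invalid rather than extrapolated.
    Passing several series pools their increments (many-short-runs
    sampling).
    """
    if method not in ("variance", "second_moment"):
        raise ValueError("method must be 'variance' or 'second_moment'")
    many = isinstance(series, (list, tuple))
    first = series[0] if many else series
    dt = first.sampling_dt
    if dt_cg is None:
        dt_cg = dt
    ratio = dt_cg / dt
    stride = int(round(ratio))
    if stride < 1 or abs(ratio - stride) > 1e-6:
        raise ValueError("dt_cg must be a positive integer multiple of the "
                         "sampling interval")
    starts, incs = [], []
    for s in (series if many else [series]):
        if abs(s.sampling_dt - dt) > 1e-9 * max(1.0, dt):
            raise ValueError("all series must share the sampling interval")
        if s.phi.size > stride:
            a, b = _increments(s, stride)
            starts.append(a)
            incs.append(b)
    if not starts:
        raise ValueError("no usable increments")
    start = np.concatenate(starts)
    inc = np.concatenate(incs)

    lo, hi = bin_range
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.digitize(start, edges) - 1
    inside = (which >= 0) & (which < n_bins)
    which = which[inside]
    inc = inc[inside]
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=inc, minlength=n_bins)
    sqsums = np.bincount(which, weights=inc * inc, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
        second = sqsums / counts
        var = second - mean ** 2
    F = mean / dt_cg
    D = (second if method == "second_moment" else var) / (2.0 * dt_cg)
    valid = counts >= min_count
    F = np.where(valid, F, np.nan)
    D = np.where(valid, np.maximum(D, 0.0), np.nan)
    return DriftDiffusionEstimate(bin_centers=centers, F=F, D=D,
                                  counts=counts, dt_cg=float(dt_cg),
                                  method=method, valid=valid)


def classify_fixed_points(est: DriftDiffusionEstimate) -> list:
    """Locate and classify zeros of the estimated drift.

    A fixed point sits at each sign change of F between consecutive valid
    bins (location by linear interpolation): + to - with increasing phi is
    stable, - to + unstable.  Bins where the estimate is exactly zero are
    bridged (the interpolated location then passes through them); gaps of
    *invalid* bins are not bridged.
    """
    idx = np.nonzero(est.valid & (est.F != 0.0))[0]
    out = []
    for a, b in zip(idx[:-1], idx[1:]):
        if not est.valid[a:b + 1].all():
            continue  # an invalid gap separates the two estimates
        fa, fb = est.F[a], est.F[b]
        if np.sign(fa) == np.sign(fb):
            continue
        xa, xb = est.bin_centers[a], est.bin_centers[b]
        loc = xa + (xb - xa) * fa / (fa - fb)
        out.append(FixedPoint(location=float(loc),
                              stability="stable" if fa > 0 else "unstable"))
    return out


# ---------------------------------------------------------------------------
# synthetic-SDE oracle

_DRIFT_CODES = {"zero": _kernels.DRIFT_ZERO, "linear": _kernels.DRIFT_LINEAR,
                "double_well": _kernels.DRIFT_DOUBLE_WELL,
                "const": _kernels.DRIFT_CONST}
_DIFF_CODES = {"zero": _kernels.DIFF_ZERO, "const": _kernels.DIFF_CONST}


def synth_sde(drift, diffusion, T: float, dt: float, seed: int,
              phi0: float = 0.0) -> OrderSeries:
    """Euler-Maruyama path of ``d(phi) = F(phi) dt + sqrt(2 D(phi)) dW``.

    ``drift`` is a descriptor tuple — ``("zero",)``, ``("const", c)``,
    ``("linear", theta)`` for ``F = -theta phi``, or
    ``("double_well", a, b)`` for ``F = a phi - b phi^3`` — or an arbitrary
    callable.  ``diffusion`` is ``("zero",)``, ``("const", D0)`` or a
    callable returning ``D(phi) >= 0``.  Descriptor forms run compiled;
    callables fall back to a Python loop (use small ``T`` there).
    Reproducible for fixed ``seed``.
    """
    if dt <= 0 or T <= 0:
        raise ValueError("T and dt must be > 0")
    n = int(round(T / dt))
    rng = np.random.default_rng(seed)
    times = dt * np.arange(n + 1)
    phi = np.empty(n + 1)
    phi[0] = phi0
    if callable(drift) or callable(diffusion):
        fdrift = drift if callable(drift) else _descriptor_fn(drift, _DRIFT_CODES)
        fdiff = diffusion if callable(diffusion) else _descriptor_fn(diffusion, _DIFF_CODES)
        sq = math.sqrt(dt)
        p = phi0
        z = rng.normal(size=n)
        for s in range(n):
            p = p + fdrift(p) * dt + math.sqrt(2.0 * max(fdiff(p), 0.0)) * sq * z[s]
            phi[s + 1] = p
        return OrderSeries(times, phi)
    dcode, da, db = _parse(drift, _DRIFT_CODES)
    ccode, ca, _ = _parse(diffusion, _DIFF_CODES)
    done = 0
    p = phi0
    while done < n:
        m = min(n - done, 1 << 20)
        z = rng.normal(size=m)
        p = _kernels._sde_block(p, z, dt, dcode, da, db, ccode, ca,
                                phi[done + 1:done + 1 + m])
        done += m
    return OrderSeries(times, phi)


def _parse(spec, codes):
    name, *args = spec
    if name not in codes:
        raise ValueError(f"unknown descriptor {name!r}")
    a = float(args[0]) if len(args) > 0 else 0.0
    b = float(args[1]) if len(args) > 1 else 0.0
    return codes[name], a, b


def _descriptor_fn(spec, codes):
    code, a, b = _parse(spec, codes)
    if codes is _DRIFT_CODES:
        return {_kernels.DRIFT_ZERO: lambda p: 0.0,
                _kernels.DRIFT_LINEAR: lambda p: -a * p,
                _kernels.DRIFT_DOUBLE_WELL: lambda p: a * p - b * p ** 3,
                _kernels.DRIFT_CONST: lambda p: a}[code]
    return {_kernels.DIFF_ZERO: lambda p: 0.0,
            _kernels.DIFF_CONST: lambda p: a}[code]
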