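"""Columnar text I/O for trajectories, order series and estimates.

All files are plain CSV with headers; floats carry 12 significant digits so
round trips preserve the values to double precision for practical purposes.
Every simulation output is accompanied by a JSON metadata sidecar (model id,
full parameter set, seed, package version) sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .coarse_grain import DriftDiffusionEstimate, OrderSeries
from .spp_core import Trajectory

_FLOAT_FMT = "%.12g"


def params_to_dict(params) -> dict:
    d = dataclasses.asdict(params)
    return {k: (v.item() if isinstance(v, np.generic) else v)
            for k, v in d.items()}


def write_metadata(path, model: str, params, seed: int,
                   extra: Optional[dict] = None) -> None:
    meta = {"model": model, "params": params_to_dict(params),
            "params_type": type(params).__name__, "seed": int(seed),
            "version": __version__}
    if extra:
        meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_metadata(path) -> dict:
    return json.loads(Path(path).read_text())


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    """Long-format snapshot table: t, particle, x, u, moving."""
    if not traj.states:
        raise ValueError("trajectory stores no snapshots; "
                         "run with store_states=True")
    rows = []
    for s in traj.states:
        rows.append(pd.DataFrame({"t": s.t, "particle": np.arange(s.N),
                                  "x": s.x, "u": s.u,
                                  "moving": s.moving.astype(int)}))
    return pd.concat(rows, ignore_index=True)


def write_trajectory(traj: Trajectory, path) -> None:
    trajectory_to_frame(traj).to_csv(path, index=False,
                                     float_format=_FLOAT_FMT)


def series_to_frame(series: OrderSeries) -> pd.DataFrame:
    df = pd.DataFrame({"t": series.times, "phi": series.phi})
    if series.n_moving is not None:
        df["n_moving"] = series.n_moving
    return df


def write_order_series(series: OrderSeries, path) -> None:
    series_to_frame(series).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_order_series(path) -> OrderSeries:
    df = pd.read_csv(path)
    nm = df["n_moving"].to_numpy() if "n_moving" in df.columns else None
    return OrderSeries(df["t"].to_numpy(), df["phi"].to_numpy(), n_moving=nm)


def fd_to_frame(est: DriftDiffusionEstimate) -> pd.DataFrame:
    return pd.DataFrame({"bin_center": est.bin_centers, "F": est.F,
                         "D": est.D, "count": est.counts,
                         "valid": est.valid.astype(int)})


def write_fd(est: DriftDiffusionEstimate, path) -> None:
    fd_to_frame(est).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_fixed_points(fixed_points, path) -> None:
    payload = [{"location": fp.location, "stability": fp.stability}
               for fp in fixed_points]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
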