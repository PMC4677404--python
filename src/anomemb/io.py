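"""Plain-text I/O: TSV trajectories/series/curves with JSON sidecars."""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from anomemb.tamsd import TamsdCurve, Trajectory
from anomemb.dichotomy import DichotomousSeries
from anomemb.spectra import PsdCurve

__all__ = [
    "write_trajectory", "read_trajectory",
    "write_series", "read_series",
    "write_curve", "read_curve",
    "write_psd", "write_json", "read_json",
]

_AXES = ("x", "y", "z")


def write_trajectory(path, traj: Trajectory, sidecar: dict | None = None) -> None:
    cols = {"t": traj.times}
    for i in range(traj.dim):
        cols[_AXES[i]] = traj.positions[:, i]
    if traj.reference is not None:
        for i in range(traj.dim):
            cols[f"ref_{_AXES[i]}"] = traj.reference[:, i]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    if sidecar is not None:
        write_json(Path(path).with_suffix(".json"), sidecar)


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path, sep="\t")
    axes = [a for a in _AXES if a in df.columns]
    ref_cols = [f"ref_{a}" for a in axes if f"ref_{a}" in df.columns]
    return Trajectory(
        times=df["t"].to_numpy(),
        positions=df[axes].to_numpy(),
        reference=df[ref_cols].to_numpy() if len(ref_cols) == len(axes) else None,
        label=Path(path).stem,
    )


def write_series(path, times, values, value_name: str = "value") -> None:
    pd.DataFrame({"t": np.asarray(times), value_name: np.asarray(values)}).to_csv(
        path, sep="\t", index=False
    )


def read_series(path):
    df = pd.read_csv(path, sep="\t")
    value_col = [c for c in df.columns if c != "t"][0]
    return df["t"].to_numpy(), df[value_col].to_numpy()


def write_curve(path, curve: TamsdCurve) -> None:
    pd.DataFrame({"lag": curve.lags, "value": curve.values}).to_csv(
        path, sep="\t", index=False
    )


def read_curve(path, T: float | None = None, dim: int = 2) -> TamsdCurve:
    df = pd.read_csv(path, sep="\t")
    lags = df["lag"].to_numpy()
    if T is None:
        T = float(lags[-1] * 10)
    return TamsdCurve(lags=lags, values=df["value"].to_numpy(), T=T, dim=dim)


def write_psd(path, psd: PsdCurve) -> None:
    pd.DataFrame({"f": psd.frequencies, "S": psd.values}).to_csv(
        path, sep="\t", index=False
    )


def _default(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return asdict(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_default,
                                     sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_dichotomous(path, series: DichotomousSeries) -> None:
    write_series(path, series.times, series.states, value_name="state")


def read_dichotomous(path) -> DichotomousSeries:
    t, v = read_series(path)
    return DichotomousSeries(times=t, states=v.astype(int))
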