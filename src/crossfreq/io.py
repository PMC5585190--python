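"""Readers and writers for trials, comodulograms, and test results.

Trial matrices travel either as delimited text (one row per trial, with a
comment header carrying the sampling rate and epoch metadata) or as an
HDF5 file holding a ``trials`` dataset with ``fs``/``t0``/``condition``/
``pad`` attributes. The two dialects round-trip to the same TrialSeries.

Comodulograms are written as a TSV matrix (phase centers as rows,
amplitude centers as columns) with a JSON sidecar recording the run
parameters, so any grid is reproducible from its sidecar plus seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .comodulogram import ComodulogramGrid
from .exceptions import ParseError
from .signals import TrialSeries
from .stats import ClusterTestResult

__all__ = [
    "read_trials",
    "write_trials",
    "read_trials_tsv",
    "write_trials_tsv",
    "read_trials_hdf5",
    "write_trials_hdf5",
    "write_comodulogram",
    "read_comodulogram",
    "write_cluster_result",
]

_TRIAL_META = ("fs", "t0", "condition", "pad")
_HDF5_SUFFIXES = {".h5", ".hdf5", ".hdf"}


def write_trials_tsv(series: TrialSeries, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs = {series.fs!r}\n")
        fh.write(f"# t0 = {series.t0!r}\n")
        fh.write(f"# condition = {series.condition}\n")
        fh.write(f"# pad = {series.pad!r}\n")
        np.savetxt(fh, series.data, delimiter="\t", fmt="%.10g")


def read_trials_tsv(path) -> TrialSeries:
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    for key in ("fs", "t0", "pad"):
        if key not in meta:
            raise ParseError(f"{path}: missing required header field '{key}'")
    try:
        fs = float(meta["fs"])
        t0 = float(meta["t0"])
        pad = float(meta["pad"])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric header field ({exc})") from None
    data = np.loadtxt(path, delimiter="\t", comments="#", ndmin=2)
    return TrialSeries(data=data, fs=fs, t0=t0,
                       condition=meta.get("condition", ""), pad=pad)


def write_trials_hdf5(series: TrialSeries, path) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("trials", data=series.data)
        ds.attrs["fs"] = series.fs
        ds.attrs["t0"] = series.t0
        ds.attrs["condition"] = series.condition
        ds.attrs["pad"] = series.pad


def read_trials_hdf5(path) -> TrialSeries:
    with h5py.File(path, "r") as fh:
        if "trials" not in fh:
            raise ParseError(f"{path}: missing 'trials' dataset")
        ds = fh["trials"]
        for key in ("fs", "t0", "pad"):
            if key not in ds.attrs:
                raise ParseError(f"{path}: missing required attribute '{key}'")
        cond = ds.attrs.get("condition", "")
        if isinstance(cond, bytes):
            cond = cond.decode()
        return TrialSeries(data=ds[...], fs=float(ds.attrs["fs"]),
                           t0=float(ds.attrs["t0"]), condition=str(cond),
                           pad=float(ds.attrs["pad"]))


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("tsv", "hdf5"):
            raise ValueError(f"format must be 'tsv' or 'hdf5', got {fmt!r}")
        return fmt
    return "hdf5" if Path(path).suffix.lower() in _HDF5_SUFFIXES else "tsv"


def read_trials(path, fmt: str | None = None) -> TrialSeries:
    """Read a TrialSeries; format inferred from the suffix unless given."""
    return (read_trials_hdf5 if _infer_format(path, fmt) == "hdf5"
            else read_trials_tsv)(path)


def write_trials(series: TrialSeries, path, fmt: str | None = None) -> None:
    (write_trials_hdf5 if _infer_format(path, fmt) == "hdf5"
     else write_trials_tsv)(series, path)


def _sidecar(path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" \
        else path


def write_comodulogram(grid: ComodulogramGrid, path, meta: dict | None = None) -> None:
    """TSV matrix (phase rows x amplitude columns) plus a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(grid.mi, index=grid.phase_centers, columns=grid.amp_centers)
    df.index.name = "phase_hz"
    df.to_csv(path, sep="\t", float_format="%.10g")
    side = {
        "method": grid.method,
        "n_trials": grid.n_trials,
        "condition": grid.condition,
        "normalized": grid.normalized,
        "phase_centers": grid.phase_centers.tolist(),
        "amp_centers": grid.amp_centers.tolist(),
    }
    if meta:
        side.update(meta)
    _sidecar(path).write_text(json.dumps(side, indent=2, default=str) + "\n")


def read_comodulogram(path) -> ComodulogramGrid:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    side_path = _sidecar(path)
    if not side_path.exists():
        raise ParseError(f"{path}: missing JSON sidecar {side_path.name}")
    side = json.loads(side_path.read_text())
    for key in ("method", "n_trials"):
        if key not in side:
            raise ParseError(f"{side_path}: missing required field '{key}'")
    return ComodulogramGrid(
        mi=df.to_numpy(dtype=float),
        phase_centers=df.index.to_numpy(dtype=float),
        amp_centers=np.array([float(c) for c in df.columns]),
        method=side["method"],
        n_trials=int(side["n_trials"]),
        condition=side.get("condition", ""),
        normalized=bool(side.get("normalized", False)),
    )


def write_cluster_result(result: ClusterTestResult, path,
                         meta: dict | None = None) -> None:
    """Cluster test result as JSON (clusters as cell-index lists)."""
    payload = {
        "statistic": result.statistic,
        "n_perm": result.n_perm,
        "alpha": result.alpha,
        "cluster_alpha": result.cluster_alpha,
        "t_critical": result.t_critical,
        "seed": result.seed,
        "clusters": [c.tolist() for c in result.clusters],
        "cluster_signs": result.cluster_signs.tolist(),
        "cluster_stats": result.cluster_stats.tolist(),
        "p_values": result.p_values.tolist(),
        "n_significant": int(np.sum(result.p_values < result.alpha))
        if result.p_values.size else 0,
        "t_map": result.t_map.tolist(),
        "sig_mask": result.sig_mask.astype(int).tolist(),
    }
    if meta:
        payload["meta"] = meta
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
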