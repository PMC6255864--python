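"""File I/O: traces and kymographs as HDF5 containers or CSV, plus
configuration round-tripping.

The HDF5 container is lossless and carries sampling metadata as
attributes; CSV mirrors exist for interoperability with small traces
(``time_s,height_nm`` with a mandatory header row).
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .analysis import DwellSet
from .trace import HeightTrace, Kymograph


class FormatError(ValueError):
    pass


def write_trace(trace: HeightTrace, path: str | Path) -> None:
    """Write a trace to ``.h5`` (lossless container) or ``.csv``."""
    path = Path(path)
    if path.suffix == ".csv":
        t = trace.times()
        pd.DataFrame({"time_s": t, "height_nm": trace.heights}).to_csv(
            path, index=False, float_format="%.9g")
        return
    with h5py.File(path, "w") as f:
        g = f.create_group("trace")
        g.create_dataset("heights", data=trace.heights)
        g.attrs["sampling_rate"] = trace.sampling_rate
        g.attrs["t0"] = trace.t0
        if trace.ground_truth is not None:
            g.create_dataset("ground_truth",
                             data=trace.ground_truth[["start", "end", "species"]]
                             .to_numpy(dtype=np.int64))
        if trace.states is not None:
            g.create_dataset("states", data=trace.states)
        serializable = {k: v for k, v in trace.meta.items()
                        if isinstance(v, (int, float, str, bool, list))}
        g.attrs["meta"] = json.dumps(serializable)


def read_trace(path: str | Path) -> HeightTrace:
    path = Path(path)
    if path.suffix == ".csv":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # malformed file
            raise FormatError(f"cannot parse {path}: {exc}") from exc
        if not {"time_s", "height_nm"} <= set(df.columns):
            raise FormatError("CSV trace needs 'time_s' and 'height_nm' columns")
        t = df["time_s"].to_numpy()
        if t.size < 2:
            raise FormatError("trace too short to infer a sampling rate")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise FormatError("non-uniform timestamps in CSV trace")
        return HeightTrace(sampling_rate=1.0 / dt[0],
                           heights=df["height_nm"].to_numpy(), t0=float(t[0]))
    with h5py.File(path, "r") as f:
        if "trace" not in f:
            raise FormatError("missing 'trace' group")
        g = f["trace"]
        if "sampling_rate" not in g.attrs:
            raise FormatError("missing sampling_rate metadata")
        gt = None
        if "ground_truth" in g:
            gt = pd.DataFrame(g["ground_truth"][()],
                              columns=["start", "end", "species"])
        states = g["states"][()] if "states" in g else None
        meta = json.loads(g.attrs.get("meta", "{}"))
        return HeightTrace(sampling_rate=float(g.attrs["sampling_rate"]),
                           heights=g["heights"][()], t0=float(g.attrs.get("t0", 0.0)),
                           ground_truth=gt, states=states, meta=meta)


def write_kymograph(kym: Kymograph, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.DataFrame(kym.data, index=kym.x_positions)
        df.index.name = f"x_nm;line_period_s={kym.line_period};x_step_nm={kym.x_step}"
        df.to_csv(path, float_format="%.9g")
        return
    with h5py.File(path, "w") as f:
        g = f.create_group("kymograph")
        g.create_dataset("data", data=kym.data)
        g.attrs["line_period"] = kym.line_period
        g.attrs["x_step"] = kym.x_step
        g.attrs["x0"] = kym.x0
        if kym.orientation is not None:
            g.create_dataset("orientation", data=kym.orientation)


def read_kymograph(path: str | Path) -> Kymograph:
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path, index_col=0)
        header = df.index.name or ""
        fields = dict(part.split("=") for part in header.split(";")[1:] if "=" in part)
        if "line_period_s" not in fields:
            raise FormatError("CSV kymograph lacks line_period_s metadata in header")
        x = df.index.to_numpy(dtype=float)
        return Kymograph(data=df.to_numpy(dtype=float),
                         line_period=float(fields["line_period_s"]),
                         x_step=float(fields.get("x_step_nm", x[1] - x[0])),
                         x0=float(x[0]))
    with h5py.File(path, "r") as f:
        if "kymograph" not in f:
            raise FormatError("missing 'kymograph' group")
        g = f["kymograph"]
        if "line_period" not in g.attrs:
            raise FormatError("missing line_period metadata")
        return Kymograph(data=g["data"][()], line_period=float(g.attrs["line_period"]),
                         x_step=float(g.attrs["x_step"]), x0=float(g.attrs.get("x0", 0.0)),
                         orientation=g["orientation"][()] if "orientation" in g else None)


def write_events(dwells: DwellSet, path: str | Path,
                 labels: np.ndarray | None = None) -> None:
    """Events table as CSV: start_s, dwell_s, peak_nm (+ species label)."""
    ev = dwells.events
    out = pd.DataFrame({"start_s": ev["start"] / dwells.sampling_rate,
                        "dwell_s": ev["dwell"], "peak_nm": ev["peak"]})
    if labels is not None:
        out["species"] = labels
    out.to_csv(path, index=False, float_format="%.9g")


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config, f, sort_keys=True)


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)
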