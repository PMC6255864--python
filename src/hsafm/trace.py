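"""In-memory containers for height/time traces and line-scan kymographs."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class HeightTrace:
    """A uniformly sampled height/time record -- the universal pipeline input.

    Attributes
    ----------
    sampling_rate : float
        Samples per second (Hz).
    heights : ndarray
        Height in nm, one value per sample.
    t0 : float
        Time of the first sample in seconds.
    ground_truth : DataFrame or None
        For simulated traces: occupancy intervals with integer columns
        ``start``/``end`` (sample indices, end exclusive) and ``species``.
    states : ndarray or None
        For simulated telegraph traces: per-sample ground-truth state
        index (0/1), with -1 marking samples inside a transition ramp.
    meta : dict
        Free-form provenance (seed, generator configuration, ...).
    """

    sampling_rate: float
    heights: np.ndarray
    t0: float = 0.0
    ground_truth: pd.DataFrame | None = None
    states: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.heights = np.asarray(self.heights)
        if self.heights.ndim != 1:
            raise ValueError("heights must be one-dimensional")

    @property
    def n_samples(self) -> int:
        return self.heights.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate


def concatenate_traces(traces: list[HeightTrace]) -> HeightTrace:
    """Join traces end-to-end (equal sampling rates required).

    Ground-truth interval indices are shifted so they stay valid in the
    joined trace; useful for building stepped-condition records.
    """
    if not traces:
        raise ValueError("need at least one trace")
    fs = traces[0].sampling_rate
    if any(t.sampling_rate != fs for t in traces):
        raise ValueError("sampling rates differ")
    heights = np.concatenate([t.heights for t in traces])
    gts = []
    offset = 0
    for t in traces:
        if t.ground_truth is not None:
            g = t.ground_truth.copy()
            g["start"] += offset
            g["end"] += offset
            gts.append(g)
        offset += t.n_samples
    gt = pd.concat(gts, ignore_index=True) if gts else None
    states = None
    if all(t.states is not None for t in traces):
        states = np.concatenate([t.states for t in traces])
    return HeightTrace(sampling_rate=fs, heights=heights, t0=traces[0].t0,
                       ground_truth=gt, states=states,
                       meta={"concatenated": len(traces)})


@dataclass
class Kymograph:
    """A line-scan record: height versus position (rows) and time (columns).

    Attributes
    ----------
    data : ndarray, shape (n_x, n_lines)
        Heights in nm; row i is the scan position ``x0 + i*x_step``.
    line_period : float
        Time per scan line in seconds.
    x_step : float
        Spatial step along the scan line in nm.
    x0 : float
        Position of the first row in nm.
    orientation : ndarray or None
        For simulated kymographs: ground-truth rotor orientation (deg,
        unwrapped) at each line's midpoint time.
    transitions : DataFrame or None
        Ground-truth transitions: ``line_start``, ``line_end`` (inclusive
        line span of the ramp), ``direction`` ('cw'/'ccw').
    """

    data: np.ndarray
    line_period: float
    x_step: float
    x0: float = 0.0
    orientation: np.ndarray | None = None
    transitions: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("kymograph data must be 2-D (positions x lines)")
        if self.line_period <= 0 or self.x_step <= 0:
            raise ValueError("line_period and x_step must be positive")

    @property
    def n_lines(self) -> int:
        return self.data.shape[1]

    @property
    def x_positions(self) -> np.ndarray:
        return self.x0 + np.arange(self.data.shape[0]) * self.x_step

    def line_times(self) -> np.ndarray:
        """Midpoint time of each line in seconds."""
        return (np.arange(self.n_lines) + 0.5) * self.line_period

    def row_at(self, x_nm: float) -> int:
        """Index of the row closest to position ``x_nm`` (error if outside)."""
        x = self.x_positions
        if not (x[0] - self.x_step / 2 <= x_nm <= x[-1] + self.x_step / 2):
            raise ValueError(f"x = {x_nm} nm outside the scanned range "
                             f"[{x[0]}, {x[-1]}] nm")
        return int(np.argmin(np.abs(x - x_nm)))
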