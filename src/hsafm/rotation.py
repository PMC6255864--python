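"""Two-state rotation analysis: trace idealization, kymograph state traces,
rotation-time measurement and energetics.

A trimer sitting on the six-fold axis of the surrounding lattice is only
weakly held and hops between two preferred orientations 60 deg apart.  On
a height trace this appears as a two-level telegraph signal; on a
line-scan kymograph as a lobe flickering between two positions ~3 nm
apart.  From the state dwell times and the duration of the rotational
transit itself, the orientational free-energy barrier follows as

    ΔG = -ln(tau_rotation / tau_state)  [k_BT],

and the rotational velocity as 60 deg / tau_rotation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, uniform_filter1d
from scipy.signal import find_peaks
from scipy.stats import pearsonr

from .trace import HeightTrace, Kymograph
from .units import per_s_to_rpm


class NotTwoStateError(ValueError):
    """The signal does not show two separated levels."""


@dataclass
class TwoStateIdealization:
    """Idealized two-state sequence of a filtered trace.

    ``segments`` has one row per dwell: ``state`` (0 = lower level,
    1 = upper level), ``start``/``end`` sample indices (end exclusive) and
    ``dwell`` in seconds.  States alternate and tile the trace.
    """

    segments: pd.DataFrame
    levels: tuple[float, float]
    filter_width: int
    sampling_rate: float

    def dwells(self, state: int | None = None) -> np.ndarray:
        seg = self.segments
        if state is not None:
            seg = seg[seg["state"] == state]
        return seg["dwell"].to_numpy()

    @property
    def state_sequence(self) -> np.ndarray:
        return self.segments["state"].to_numpy()

    def sample_states(self, n_samples: int) -> np.ndarray:
        out = np.empty(n_samples, dtype=np.int8)
        for _, row in self.segments.iterrows():
            out[int(row["start"]):int(row["end"])] = int(row["state"])
        return out


def _suppress_glitches(states: np.ndarray, min_run: int) -> np.ndarray:
    """Merge state runs shorter than ``min_run`` samples into the run before.

    Works on the run-length encoding (single left-to-right pass): a short
    run is absorbed by its predecessor; the leading run is always kept.
    """
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.r_[0, change]
    lengths = np.diff(np.r_[starts, states.size])
    vals = states[starts]
    merged: list[list] = []  # [state, length]
    for v, ln in zip(vals, lengths):
        if not merged:
            merged.append([v, ln])
        elif ln < min_run or v == merged[-1][0]:
            merged[-1][1] += ln
        else:
            merged.append([v, ln])
    # absorbing a glitch can make neighbours equal-state; compress again
    out = np.empty_like(states)
    pos = 0
    for v, ln in merged:
        out[pos:pos + ln] = v
        pos += ln
    return out


def _find_levels(x: np.ndarray) -> tuple[float, float]:
    """Two mode positions of a (filtered) signal histogram, or raise."""
    n_bins = int(min(200, max(30, np.sqrt(x.size))))
    counts, edges = np.histogram(x, bins=n_bins)
    smooth = gaussian_filter1d(counts.astype(float), 2.0)
    # zero-pad so modes in the outermost bins are still local maxima
    padded = np.r_[0.0, smooth, 0.0]
    peaks, props = find_peaks(padded, prominence=0.05 * smooth.max())
    if peaks.size < 2:
        raise NotTwoStateError("height histogram is not bimodal")
    top = peaks[np.argsort(props["prominences"])[-2:]] - 1
    centers = (edges[:-1] + edges[1:]) / 2.0
    lo, hi = sorted(centers[top])
    return float(lo), float(hi)


def idealize_two_state(trace: HeightTrace | np.ndarray,
                       sampling_rate: float | None = None,
                       filter_width: int = 30,
                       min_dwell_samples: int | None = None) -> TwoStateIdealization:
    """Idealize a two-level signal by filtering plus hysteresis thresholding.

    The trace is boxcar-filtered over ``filter_width`` samples; the two
    state levels are the modes of the filtered-height histogram; samples
    are assigned to the nearest level with a hysteresis band of half the
    level separation (a switch requires crossing to within a quarter
    separation of the other level).  Excursions shorter than
    ``min_dwell_samples`` (default: five filter widths, ~240 µs at the
    default filter and sampling rate) are treated as noise glitches and
    merged into the preceding state; dwells down to that floor remain
    resolvable.  A unimodal trace raises :class:`NotTwoStateError`.
    """
    if isinstance(trace, HeightTrace):
        x, fs = trace.heights, trace.sampling_rate
    else:
        x = np.asarray(trace, dtype=float)
        if sampling_rate is None:
            raise ValueError("sampling_rate required for a bare array")
        fs = sampling_rate
    if filter_width < 1:
        raise ValueError("filter_width must be >= 1")
    filt = uniform_filter1d(x, filter_width, mode="nearest") if filter_width > 1 else x

    lo, hi = _find_levels(filt)
    sep = hi - lo
    mid = (hi + lo) / 2.0
    # post-check against pseudo-modes of a broad unimodal histogram
    assign_near = filt > mid
    sd_lo = filt[~assign_near].std() if (~assign_near).any() else 0.0
    sd_hi = filt[assign_near].std() if assign_near.any() else 0.0
    if sep < 2.0 * max(sd_lo, sd_hi):
        raise NotTwoStateError("level separation is below the in-state spread")

    upper = filt > mid + sep / 4.0
    lower = filt < mid - sep / 4.0
    decided = upper | lower
    if not decided.any():
        raise NotTwoStateError("no sample reaches either level")
    # forward-fill the undecided samples with the last decided state
    idx = np.where(decided, np.arange(x.size), -1)
    idx = np.maximum.accumulate(idx)
    first = np.argmax(decided)
    idx[idx < 0] = first  # leading run adopts the first decided state
    states = upper[idx].astype(np.int8)

    min_run = 5 * filter_width if min_dwell_samples is None else min_dwell_samples
    if min_run > 1:
        states = _suppress_glitches(states, min_run)

    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.r_[0, change]
    ends = np.r_[change, x.size]
    seg = pd.DataFrame({"state": states[starts].astype(int), "start": starts,
                        "end": ends, "dwell": (ends - starts) / fs})
    return TwoStateIdealization(segments=seg, levels=(lo, hi),
                                filter_width=filter_width, sampling_rate=fs)


@dataclass
class DwellStats:
    """Per-state and pooled dwell statistics with an empirical survival curve."""

    mean: float
    sem: float
    n: int
    per_state: dict[int, tuple[float, float, int]]  # state -> (mean, sem, n)
    survival_t: np.ndarray
    survival_s: np.ndarray


def dwell_statistics(ideal: TwoStateIdealization, min_dwells: int = 10) -> DwellStats:
    """Dwell-time statistics of an idealization.

    The first and last segments are dropped (their dwells are censored by
    the trace edges).  Raises if fewer than ``min_dwells`` complete
    dwells remain.
    """
    seg = ideal.segments.iloc[1:-1]
    if len(seg) < min_dwells:
        raise ValueError(f"only {len(seg)} complete dwells; need >= {min_dwells}")
    d = seg["dwell"].to_numpy()
    per_state = {}
    for s in (0, 1):
        ds = seg[seg["state"] == s]["dwell"].to_numpy()
        if ds.size:
            per_state[s] = (float(ds.mean()),
                            float(ds.std(ddof=1) / np.sqrt(ds.size)) if ds.size > 1 else np.nan,
                            int(ds.size))
    t = np.sort(d)
    s = 1.0 - np.arange(d.size) / d.size  # P(dwell > t), right-continuous
    return DwellStats(mean=float(d.mean()),
                      sem=float(d.std(ddof=1) / np.sqrt(d.size)),
                      n=int(d.size), per_state=per_state,
                      survival_t=t, survival_s=s)


@dataclass
class KymographStateTraces:
    """Height/time traces at the two orientation positions of a kymograph."""

    trace0: np.ndarray
    trace60: np.ndarray
    difference: np.ndarray
    idealization: TwoStateIdealization
    line_period: float

    @property
    def anticorrelation(self) -> float:
        return float(pearsonr(self.trace0, self.trace60)[0])


def extract_position_traces(kym: Kymograph, x0: float, x60: float,
                            filter_width: int = 3) -> KymographStateTraces:
    """Extract the 0°/60° height traces and idealize their difference.

    Sampling one row per line at each orientation's position gives two
    anti-correlated traces; their difference doubles the signal and
    cancels correlated (common-mode) errors, and is idealized with the
    same two-state machinery used for direct height spectroscopy.
    """
    r0, r60 = kym.row_at(x0), kym.row_at(x60)
    t0 = kym.data[r0, :].astype(float)
    t60 = kym.data[r60, :].astype(float)
    diff = t0 - t60
    ideal = idealize_two_state(diff, sampling_rate=1.0 / kym.line_period,
                               filter_width=filter_width,
                               min_dwell_samples=max(2, filter_width))
    return KymographStateTraces(trace0=t0, trace60=t60, difference=diff,
                                idealization=ideal, line_period=kym.line_period)


def _lobe_positions(kym: Kymograph, x_window: tuple[float, float] | None) -> np.ndarray:
    """Sub-pixel position of the brightest lobe in each line (nm)."""
    x = kym.x_positions
    if x_window is None:
        span = x[-1] - x[0]
        x_window = (x[0] + 0.3 * span, x[-1] - 0.3 * span)
    sel = (x >= x_window[0]) & (x <= x_window[1])
    if sel.sum() < 3:
        raise ValueError("x_window selects fewer than 3 rows")
    sub = kym.data[sel, :]
    xs = x[sel]
    j = np.argmax(sub, axis=0)
    pos = xs[j].astype(float)
    # parabolic sub-pixel refinement where the maximum is interior
    inner = (j > 0) & (j < sub.shape[0] - 1)
    cols = np.arange(sub.shape[1])[inner]
    jm = j[inner]
    y0, y1, y2 = sub[jm - 1, cols], sub[jm, cols], sub[jm + 1, cols]
    denom = y0 - 2 * y1 + y2
    shift = np.where(denom != 0, 0.5 * (y0 - y2) / np.where(denom == 0, 1, denom), 0.0)
    pos[inner] += np.clip(shift, -0.5, 0.5) * kym.x_step
    return pos


@dataclass
class RotationTransitions:
    """Measured rotational transitions of a kymograph."""

    table: pd.DataFrame  # line_start, line_end, n_lines, duration, direction, resolvable
    n_discarded_edges: int
    positions: np.ndarray
    idealization: TwoStateIdealization

    @property
    def durations(self) -> np.ndarray:
        return self.table.loc[self.table["resolvable"], "duration"].to_numpy()

    @property
    def mean_duration(self) -> float:
        d = self.durations
        return float(d.mean()) if d.size else np.nan


def measure_rotation_transitions(kym: Kymograph,
                                 x_window: tuple[float, float] | None = None,
                                 band_fraction: float = 0.1,
                                 overshoot_fraction: float = 0.3,
                                 filter_width: int = 1) -> RotationTransitions:
    """Measure rotation (transition) times and directions from a kymograph.

    The per-line lobe position is idealized as a two-state signal; for
    each state change, the transition interval runs from the last line
    still within ``band_fraction`` of the separation around the departure
    level to the first line within the arrival band.  Duration is the
    strictly-between line count times the line period (quantization ±1
    line); transitions spanning <= 1 line are flagged unresolvable, those
    touching the trace edges are discarded and counted.

    Direction: one rotation sense carries the detected lobe across the
    scan line, sweeping its position *between* the two plateau levels; the
    opposite sense moves it away past its plateau (overshoot) while the
    next lobe enters from beyond the far plateau.  A transit whose
    interior positions stay inside the plateau interval is an
    inward sweep, one with a substantial overshooting fraction
    (> ``overshoot_fraction``) is a handover; combined with the
    displacement sign this yields the rotation sense in the generator's
    convention (0° state at the higher scan position).
    """
    pos = _lobe_positions(kym, x_window)
    ideal = idealize_two_state(pos, sampling_rate=1.0 / kym.line_period,
                               filter_width=filter_width, min_dwell_samples=2)
    lo, hi = ideal.levels
    band = band_fraction * (hi - lo)
    level = {0: lo, 1: hi}
    seg = ideal.segments
    rows = []
    discarded = 0
    for i in range(len(seg) - 1):
        s_from = int(seg.iloc[i]["state"])
        s_to = int(seg.iloc[i + 1]["state"])
        switch = int(seg.iloc[i + 1]["start"])
        # last line still at the departure level
        a = switch - 1
        while a >= 0 and abs(pos[a] - level[s_from]) > band:
            a -= 1
        b = switch
        while b < pos.size and abs(pos[b] - level[s_to]) > band:
            b += 1
        if a < 0 or b >= pos.size:
            discarded += 1
            continue
        n_lines = b - a - 1
        # the position spends band_fraction of the sweep inside each plateau
        # band, so the interior line count underestimates the ramp by
        # 2*band_fraction; correct for it (unbiased up to +-1 line).
        duration = n_lines * kym.line_period / (1.0 - 2.0 * band_fraction)
        interior = pos[a + 1:b]
        disp = level[s_to] - level[s_from]
        if interior.size >= 1:
            outside = (interior > hi + band) | (interior < lo - band)
            handover = outside.mean() > overshoot_fraction
            inward_is_ccw = disp < 0
            direction = ("ccw" if (inward_is_ccw != handover) else "cw")
        else:
            direction = "unresolved"
        rows.append((a + 1, b - 1, n_lines, duration, direction, n_lines >= 2))
    table = pd.DataFrame(rows, columns=["line_start", "line_end", "n_lines",
                                        "duration", "direction", "resolvable"])
    return RotationTransitions(table=table, n_discarded_edges=discarded,
                               positions=pos, idealization=ideal)


@dataclass(frozen=True)
class RotationStats:
    """Energetics and speed of the two-state rotation."""

    tau_state: float      # s
    tau_rotation: float   # s
    delta_g: float        # k_BT barrier between orientations
    angular_velocity: float  # deg / s
    rpm: float


def rotation_energetics(tau_state: float, tau_rotation: float,
                        step_deg: float = 60.0) -> RotationStats:
    """Barrier and rotational velocity from mean state and rotation times.

    ΔG = -ln(tau_rotation / tau_state) in k_BT; the angular velocity
    assumes each transit is a single ``step_deg`` rotation.
    """
    if tau_state <= 0 or tau_rotation <= 0:
        raise ValueError("both times must be positive")
    omega = step_deg / tau_rotation
    return RotationStats(tau_state=tau_state, tau_rotation=tau_rotation,
                         delta_g=float(-np.log(tau_rotation / tau_state)),
                         angular_velocity=omega, rpm=per_s_to_rpm(omega))
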