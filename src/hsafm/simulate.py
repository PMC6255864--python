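"""Physics-based synthetic data: diffusion traces, telegraph traces, kymographs.

Every generator returns ground truth alongside the signal so that each
downstream analysis stage can be validated without experimental data.

The diffusion simulator propagates hard-disk particles by free Brownian
motion on a periodic square membrane patch, point-samples their distance
to a fixed tip position at the acquisition rate, passes the resulting
ideal occupancy height signal through the single-pole z-feedback
surrogate, and adds Gaussian baseline noise.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import SpeciesGeometry
from .instrument import (DEFAULT_EVENT_HEIGHT, DEFAULT_SAMPLING_RATE,
                         FeedbackModel, NoiseModel)
from .trace import HeightTrace, Kymograph
from .units import NM_PER_UM

_CHUNK = 1 << 21  # samples per propagation chunk, keeps memory modest


@dataclass(frozen=True)
class SpeciesPopulation:
    """One diffusing species: geometry plus surface density and mobility."""

    geometry: SpeciesGeometry
    density: float                      # µm⁻²
    diffusion: float                    # µm² s⁻¹
    height: float = DEFAULT_EVENT_HEIGHT  # nm

    def __post_init__(self):
        if self.density < 0 or self.diffusion < 0:
            raise ValueError("density and diffusion coefficient must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a height-spectroscopy diffusion simulation."""

    box_side: float                     # µm, periodic square domain
    species: tuple[SpeciesPopulation, ...]
    duration: float                     # s
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    noise: NoiseModel | None = NoiseModel()
    feedback: FeedbackModel | None = None
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.box_side <= 0:
            raise ValueError("box_side must be positive")
        object.__setattr__(self, "species", tuple(self.species))
        if self.species:
            wmax = max(s.geometry.w for s in self.species) / NM_PER_UM
            if self.box_side < 10.0 * wmax:
                raise ValueError(
                    f"box_side {self.box_side} µm must be at least 10x the largest "
                    f"detection width ({wmax} µm)")

    def n_particles(self) -> list[int]:
        return [int(round(s.density * self.box_side ** 2)) for s in self.species]


def _intervals_from_bool(mask: np.ndarray) -> np.ndarray:
    """(start, end) index pairs (end exclusive) of True runs."""
    m = np.asarray(mask, dtype=bool)
    edges = np.diff(np.r_[np.int8(0), m.view(np.int8), np.int8(0)])
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return np.column_stack([starts, ends])


def simulate_diffusion_trace(config: SimulationConfig,
                             store_trajectories: bool = False,
                             initial_positions: list[np.ndarray | None] | None = None,
                             ) -> HeightTrace:
    """Simulate a height/time trace of particles diffusing under a fixed tip.

    Per sampling interval each particle takes an isotropic Gaussian step
    of per-axis s.d. sqrt(2 D dt) with periodic wrapping.  The tip sits at
    the box centre; a particle is detected when its centre is within w/2
    of the tip.  The ideal height is the maximum event height over all
    detected species (the tip reports topography, not occupancy counts),
    then feedback-filtered and noise-corrupted.

    Returns a :class:`HeightTrace` whose ``ground_truth`` lists the exact
    occupancy intervals per species.  With ``store_trajectories`` the full
    particle paths are kept in ``meta['trajectories']`` (one
    (n_particles, n_samples, 2) array per species, in µm) for use with
    :func:`occupancy_oracle`; only feasible for short runs.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    dt = 1.0 / fs
    n = int(round(config.duration * fs))
    box = config.box_side
    tip = np.array([box / 2.0, box / 2.0])
    feedback = config.feedback or FeedbackModel(sampling_rate=fs)

    counts = config.n_particles()
    occ = []      # per species bool arrays
    trajs = []
    for si, (spec, n_p) in enumerate(zip(config.species, counts)):
        mask = np.zeros(n, dtype=bool)
        if n_p > 0:
            w_um = spec.geometry.w / NM_PER_UM
            r2 = (w_um / 2.0) ** 2
            step_sd = np.sqrt(2.0 * spec.diffusion * dt)
            pos = rng.uniform(0.0, box, (n_p, 2))
            if initial_positions is not None and initial_positions[si] is not None:
                given = np.atleast_2d(np.asarray(initial_positions[si], dtype=float))
                pos[:given.shape[0]] = given
            traj = np.empty((n_p, n, 2)) if store_trajectories else None
            chunk = max(4096, _CHUNK // n_p)  # bound per-chunk memory
            for i0 in range(0, n, chunk):
                L = min(chunk, n - i0)
                steps = rng.normal(0.0, step_sd, (n_p, L, 2))
                steps[:, 0, :] += pos
                path = np.cumsum(steps, axis=1)
                pos = path[:, -1, :] % box
                if traj is not None:
                    traj[:, i0:i0 + L, :] = path % box
                d = (path - tip + box / 2.0) % box - box / 2.0
                inside = (d[..., 0] ** 2 + d[..., 1] ** 2) < r2
                mask[i0:i0 + L] = inside.any(axis=0)
            if traj is not None:
                trajs.append(traj)
        elif store_trajectories:
            trajs.append(np.empty((0, n, 2)))
        occ.append(mask)

    ideal = np.zeros(n)
    for spec, mask in zip(config.species, occ):
        np.maximum(ideal, np.where(mask, spec.height, 0.0), out=ideal)

    heights = feedback.filter(ideal)
    if config.noise is not None:
        heights += config.noise.sample(rng, n)

    rows = []
    for sid, mask in enumerate(occ):
        iv = _intervals_from_bool(mask)
        for s, e in iv:
            rows.append((int(s), int(e), sid))
    gt = pd.DataFrame(rows, columns=["start", "end", "species"]).sort_values(
        ["start", "species"]).reset_index(drop=True)

    meta = {"seed": config.seed, "box_side_um": box,
            "tau_fb_s": feedback.tau_fb,
            "n_particles": counts,
            "noise_sigma_nm": config.noise.sigma if config.noise else 0.0}
    if store_trajectories:
        meta["trajectories"] = trajs
        meta["tip_um"] = tip
    return HeightTrace(sampling_rate=fs, heights=heights, ground_truth=gt, meta=meta)


def occupancy_oracle(trajectories: np.ndarray, tip: np.ndarray, w_nm: float,
                     box_side: float) -> np.ndarray:
    """Brute-force occupancy intervals recomputed frame by frame.

    ``trajectories`` is an (n_particles, n_samples, 2) array of positions
    in µm.  Returns (start, end) sample-index pairs where any particle's
    minimum-image distance to ``tip`` is below ``w_nm / 2``.  This is the
    independent reference the simulator's stored ground truth -- and event
    detection on noise-free traces -- is checked against.
    """
    traj = np.asarray(trajectories, dtype=float)
    if traj.ndim != 3 or traj.shape[-1] != 2:
        raise ValueError("trajectories must have shape (n_particles, n_samples, 2)")
    if traj.shape[0] == 0:
        return np.empty((0, 2), dtype=int)
    lengths = {traj[i].shape[0] for i in range(traj.shape[0])}
    if len(lengths) != 1:
        raise ValueError("trajectories have mismatched lengths")
    r = (w_nm / NM_PER_UM) / 2.0
    d = (traj - np.asarray(tip) + box_side / 2.0) % box_side - box_side / 2.0
    inside = (d[..., 0] ** 2 + d[..., 1] ** 2) < r ** 2
    return _intervals_from_bool(inside.any(axis=0))


# --------------------------------------------------------------------------
# Two-state telegraph traces (rotating trimer seen by height spectroscopy)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TelegraphConfig:
    """Two-state rotation telegraph signal, as seen on one rotor protomer.

    The rotor dwells in each orientation for exponentially distributed
    times and moves between them along a linear height ramp of fixed
    duration (the rotation itself).  Each dwell's plateau height is drawn
    once per dwell around the state mean (per-state jitter), emulating the
    spread of apparent state heights.
    """

    heights: tuple[float, float] = (2.00, 1.72)       # nm
    mean_dwells: tuple[float, float] = (0.026, 0.026)  # s
    transition_duration: float = 0.018                 # s, the rotation time
    jitter: tuple[float, float] = (0.10, 0.07)         # nm, per-dwell
    noise: NoiseModel | None = NoiseModel()
    seed: int = 0

    def __post_init__(self):
        if self.heights[0] == self.heights[1]:
            raise ValueError("state heights must be distinct")
        if min(self.mean_dwells) <= 0:
            raise ValueError("mean dwells must be positive")
        if self.transition_duration < 0:
            raise ValueError("transition duration must be non-negative")


def simulate_telegraph_trace(config: TelegraphConfig, duration: float,
                             sampling_rate: float = DEFAULT_SAMPLING_RATE) -> HeightTrace:
    """Simulate a two-state telegraph height trace with ground-truth states.

    The returned trace's ``states`` array holds the state index (0/1) per
    sample and -1 inside transition ramps.
    """
    if duration <= 0 or sampling_rate <= 0:
        raise ValueError("duration and sampling_rate must be positive")
    rng = np.random.default_rng(config.seed)
    n = int(round(duration * sampling_rate))
    n_ramp = int(round(config.transition_duration * sampling_rate))

    heights = np.empty(n)
    states = np.empty(n, dtype=np.int8)
    pos = 0
    state = int(rng.integers(0, 2))
    level = config.heights[state] + rng.normal(0.0, config.jitter[state])
    while pos < n:
        dwell = rng.exponential(config.mean_dwells[state])
        k = max(1, int(round(dwell * sampling_rate)))
        k = min(k, n - pos)
        heights[pos:pos + k] = level
        states[pos:pos + k] = state
        pos += k
        if pos >= n:
            break
        state = 1 - state
        new_level = config.heights[state] + rng.normal(0.0, config.jitter[state])
        if n_ramp > 0:
            m = min(n_ramp, n - pos)
            ramp = level + (new_level - level) * (np.arange(1, m + 1) / n_ramp)
            heights[pos:pos + m] = ramp
            states[pos:pos + m] = -1
            pos += m
        level = new_level
    if config.noise is not None:
        heights = heights + config.noise.sample(rng, n)
    return HeightTrace(sampling_rate=sampling_rate, heights=heights, states=states,
                       meta={"seed": config.seed, "config": config})


# --------------------------------------------------------------------------
# Line-scan kymograph of a rotating trimer
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrimerProfile:
    """Three-lobed height model of a trimer rotating about its centre.

    Lobes sit at ``lobe_radius`` from the centre, 120 deg apart, each a 2-D
    Gaussian of s.d. ``lobe_sigma`` and peak ``lobe_height``; the reported
    height at a scan-line point is the maximum over lobes (tip topography).

    The scan line runs along x, offset from the rotor centre so that it is
    tangent to the lobe circle: in the two preferred orientations (rotor
    angle 0 and 60 deg) one lobe sits at azimuth 60 or 120 deg, i.e. at
    scan positions ``center_x ± lobe_radius/2`` (~3 nm apart).  During a
    rotation that carries the detected lobe across the top of the circle
    its scan position sweeps nearly linearly between the two state
    positions; a rotation of the opposite sense instead moves the lobe
    away past the plateau position while the next lobe enters from the far
    side -- the two senses therefore leave mirror-distinguishable streaks.
    Two stationary flanking ridges model the immobile lattice neighbours.
    """

    center_x: float = 10.0       # nm along the scan line
    lobe_radius: float = 3.0     # nm
    lobe_sigma: float = 1.6      # nm
    lobe_height: float = 2.0     # nm
    flank_positions: tuple[float, ...] = (4.0, 16.0)
    flank_height: float = 2.0
    flank_sigma: float = 1.2

    @property
    def y_offset(self) -> float:
        """Scan-line offset from the rotor centre (tangent geometry)."""
        return self.lobe_radius * math.sin(math.radians(60.0))

    def state_positions(self) -> tuple[float, float]:
        """Scan-line x of the detected lobe in the 0 deg and 60 deg states."""
        half = self.lobe_radius * math.cos(math.radians(60.0))
        return (self.center_x + half, self.center_x - half)

    def render_line(self, x: np.ndarray, angle_deg: float) -> np.ndarray:
        """Height profile along the scan line for rotor orientation ``angle_deg``."""
        a = np.deg2rad(angle_deg + np.array([60.0, 180.0, 300.0]))
        lx = self.center_x + self.lobe_radius * np.cos(a)
        ly = self.lobe_radius * np.sin(a)
        prof = np.zeros_like(x, dtype=float)
        for xi, yi in zip(lx, ly):
            d2 = (x - xi) ** 2 + (self.y_offset - yi) ** 2
            np.maximum(prof, self.lobe_height * np.exp(-d2 / (2 * self.lobe_sigma ** 2)),
                       out=prof)
        for xf in self.flank_positions:
            np.maximum(prof,
                       self.flank_height * np.exp(-(x - xf) ** 2 /
                                                  (2 * self.flank_sigma ** 2)),
                       out=prof)
        return prof


def simulate_rotation_kymograph(schedule: list[tuple[float, float]],
                                profile: TrimerProfile = TrimerProfile(),
                                line_period: float = 2.4e-3,
                                x_step: float = 0.5,
                                x_extent: float = 20.0,
                                transition_duration: float = 0.018,
                                noise: NoiseModel | None = NoiseModel(0.10),
                                seed: int = 0) -> Kymograph:
    """Render a line-scan kymograph of a rotor following an angle schedule.

    ``schedule`` is a list of ``(angle_deg, duration_s)`` plateaus with the
    angle *unwrapped*: successive entries differing by +60 rotate
    counter-clockwise, by -60 clockwise (orientations are physically
    periodic in 120 deg).  Between plateaus the rotor turns at constant
    angular velocity for ``transition_duration`` seconds.  Each output
    line samples the profile at the line's midpoint time.
    """
    if not schedule:
        raise ValueError("schedule must contain at least one plateau")
    if line_period <= 0 or x_step <= 0:
        raise ValueError("line_period and x_step must be positive")
    rng = np.random.default_rng(seed)

    # piecewise angle(t): plateaus joined by linear ramps
    seg_t, seg_a = [0.0], [float(schedule[0][0])]
    t = 0.0
    for i, (ang, dur) in enumerate(schedule):
        if dur < 0:
            raise ValueError("plateau durations must be non-negative")
        t += dur
        seg_t.append(t)
        seg_a.append(float(ang))
        if i < len(schedule) - 1:
            t += transition_duration
            seg_t.append(t)
            seg_a.append(float(schedule[i + 1][0]))
    total = t
    n_lines = int(round(total / line_period))
    times = (np.arange(n_lines) + 0.5) * line_period
    angle = np.interp(times, seg_t, seg_a)

    x = np.arange(0.0, x_extent + x_step / 2, x_step)
    data = np.empty((x.size, n_lines))
    for j in range(n_lines):
        data[:, j] = profile.render_line(x, angle[j])
    if noise is not None:
        data += noise.sample(rng, data.size).reshape(data.shape)

    # ground-truth transition table (line spans of each ramp)
    rows = []
    t_cursor = 0.0
    for i in range(len(schedule) - 1):
        t_cursor += schedule[i][1]
        t_a, t_b = t_cursor, t_cursor + transition_duration
        direction = "ccw" if schedule[i + 1][0] > schedule[i][0] else "cw"
        l0 = int(np.searchsorted(times, t_a))
        l1 = int(np.searchsorted(times, t_b)) - 1
        rows.append((l0, max(l0, l1), direction, t_a, t_b))
        t_cursor = t_b
    trans = pd.DataFrame(rows, columns=["line_start", "line_end", "direction",
                                        "t_start", "t_end"])
    return Kymograph(data=data, line_period=line_period, x_step=x_step,
                     orientation=angle, transitions=trans,
                     meta={"seed": seed, "profile": profile,
                           "transition_duration": transition_duration})
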