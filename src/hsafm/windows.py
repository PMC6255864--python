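"""Windowed (time-lapse) analysis of non-stationary traces.

Membrane binding and self-assembly are followed over time by cutting a
long trace into fixed windows (default 1 s), and reporting per window the
event rate, mean dwell, surface concentration and oligomer-class
fractions.  Windows are half-open ``[k*T, (k+1)*T)``; an event belongs to
the window containing its first sample.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import ThresholdSpec, detect_events
from .mixture import MixtureFit, classify_events, fit_dwell_mixture
from .trace import HeightTrace
from .units import NM_PER_UM


def windowed_analysis(trace: HeightTrace, spec: ThresholdSpec, d_p: float,
                      window: float = 1.0, mixture: MixtureFit | None = None,
                      n_max: int = 5, pool_from: int = 5) -> pd.DataFrame:
    """Per-window event statistics of a height trace.

    Events are detected once on the full trace; a dwell mixture is fitted
    globally (or supplied) and reused in every window so that oligomer
    class boundaries are consistent across time.  Returns a DataFrame
    with one row per window: ``t_start``, ``n_events``, ``event_rate``,
    ``mean_dwell``, ``concentration`` and unit fractions ``f1..f{k}``,
    ``f_o``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if trace.duration < 2 * window:
        raise ValueError("trace must span at least two windows")
    dwells = detect_events(trace, spec)
    if mixture is None and dwells.n_events > 0:
        mixture = fit_dwell_mixture(dwells, n_max=n_max)

    n_win = int(trace.duration // window)
    samples_per_win = int(round(window * trace.sampling_rate))
    ev = dwells.events
    win_idx = (ev["start"] // samples_per_win).to_numpy()
    labels = (classify_events(dwells, mixture, pool_from=pool_from)[0]
              if mixture is not None and dwells.n_events else
              np.empty(0, dtype=int))

    frac_cols = [f"f{i}" for i in range(1, pool_from)] + ["f_o"]
    rows = []
    for k in range(n_win):
        sel = win_idx == k
        nk = int(sel.sum())
        dw = ev["dwell"].to_numpy()[sel]
        t_above = dw.sum()
        conc = (t_above / window) / (d_p / NM_PER_UM) ** 2
        fr = np.zeros(pool_from)
        if nk and labels.size:
            lab = labels[sel]
            cls = np.minimum(lab, pool_from)
            for c in range(1, pool_from + 1):
                fr[c - 1] = lab[cls == c].sum()
            if fr.sum() > 0:
                fr /= fr.sum()
        rows.append([k * window, nk, nk / window,
                     dw.mean() if nk else np.nan, conc, *fr])
    return pd.DataFrame(rows, columns=["t_start", "n_events", "event_rate",
                                       "mean_dwell", "concentration", *frac_cols])
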