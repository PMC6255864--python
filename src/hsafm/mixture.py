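"""Gaussian deconvolution of dwell-time distributions.

Dwell-time histograms of a self-assembling species are multi-modal: each
oligomer size contributes a roughly Gaussian peak at its characteristic
dwell.  This module fits an n-component Gaussian mixture to the binned
dwell histogram by Poisson-weighted least squares, selects n by the
reduced chi-squared of the fits, and assigns individual events to
components by posterior responsibility.

Numerical conventions:

* components are Gaussians truncated to positive dwell times (dwells are
  durations), integrated over each bin rather than sampled at centres;
* binning defaults to the Freedman-Diaconis rule applied on the
  log-dwell axis, since dwell peaks of successive oligomers are
  geometrically spaced;
* the fit is deterministic: a fixed schedule of starts (quantile-spaced
  means, histogram-mode multiples, and greedy growth from the (n-1)-
  component solution) is tried for every n and the best kept;
* the selected n is the smallest whose chi-squared no larger candidate
  improves by more than ~2 per additional parameter -- fitting noise
  absorbs about one chi-squared unit per free parameter, so smaller
  gains do not justify extra components and the parsimonious model
  (lowest reduced chi-squared among significant candidates) wins.
  Solutions containing a component carrying under 2% of the events are
  not considered competitive (a dwell peak must be supported by a
  minimal event share) unless no solution without one exists.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .analysis import DwellSet

_CHISQ_PER_PARAM = 3.0
_MIN_COMPONENT_WEIGHT = 0.02


@dataclass(frozen=True)
class MixtureComponent:
    mean: float    # s
    sd: float      # s
    weight: float  # fraction of events


@dataclass
class MixtureFit:
    """An n-component Gaussian mixture over dwell times."""

    components: list[MixtureComponent]
    red_chisq: float
    red_chisq_by_n: dict[int, float]
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c.sd for c in self.components])

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def dominant(self) -> MixtureComponent:
        """Component carrying the largest event weight."""
        return self.components[int(np.argmax(self.weights))]

    def responsibilities(self, dwells: np.ndarray) -> np.ndarray:
        """Posterior component probabilities for each dwell, shape (n_events, n)."""
        d = np.asarray(dwells, dtype=float)[:, None]
        mu, sd, w = self.means[None, :], self.sds[None, :], self.weights[None, :]
        # truncated-at-zero normalisation cancels only per component
        dens = w * stats.norm.pdf(d, mu, sd) / stats.norm.sf(0.0, mu, sd)
        total = dens.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return dens / total


def _log_fd_edges(x: np.ndarray, max_bins: int | None = None,
                  min_bins: int = 10) -> np.ndarray:
    """Freedman-Diaconis binning on the log-dwell axis.

    The lower edge is the 0.2% quantile rather than the minimum so a
    single anomalously short dwell cannot stretch the range; the bin
    count is additionally capped at sqrt(N) to keep per-bin counts
    informative for the Poisson-weighted fit.
    """
    if max_bins is None:
        max_bins = int(np.clip(np.sqrt(x.size), min_bins, 120))
    lo = np.quantile(x, 0.002)
    lx = np.log10(x[x >= lo])
    span = lx.max() - lx.min()
    if span == 0:
        return np.array([x.min() * 0.9, x.max() * 1.1])
    iqr = np.subtract(*np.percentile(lx, [75, 25]))
    h = 2.0 * iqr / x.size ** (1.0 / 3.0)
    nb = int(np.ceil(span / h)) if h > 0 else 20
    nb = min(max_bins, max(min_bins, nb))
    return np.logspace(lx.min(), lx.max() + 1e-12, nb + 1)


def _model_counts(params: np.ndarray, n: int, edges: np.ndarray) -> np.ndarray:
    model = np.zeros(edges.size - 1)
    for mu, sd, amp in zip(params[:n], params[n:2 * n], params[2 * n:]):
        norm = stats.norm.sf(0.0, mu, sd)  # truncate to positive dwells
        model += amp * np.diff(stats.norm.cdf(edges, mu, sd)) / norm
    return model


def _fit_fixed_n(counts: np.ndarray, edges: np.ndarray, starts) -> tuple[float, np.ndarray]:
    weights = np.sqrt(np.maximum(counts, 1.0))
    n = len(starts[0][0])

    def residuals(p):
        return (_model_counts(p, n, edges) - counts) / weights

    widths = np.diff(edges)
    lo = np.r_[np.full(n, edges[0] * 0.5), np.full(n, widths.min() / 4), np.zeros(n)]
    hi = np.r_[np.full(n, edges[-1]), np.full(n, edges[-1] - edges[0]),
               np.full(n, 10.0 * counts.sum())]
    best = None
    for mu0, sd0, a0 in starts:
        p0 = np.clip(np.r_[mu0, sd0, a0], lo, hi)
        sol = least_squares(residuals, p0, bounds=(lo, hi), method="trf",
                            max_nfev=300 * p0.size)
        if best is None or sol.cost < best.cost:
            best = sol
    return 2.0 * best.cost, best.x


def fit_dwell_mixture(dwells: DwellSet | np.ndarray, n_max: int = 5,
                      bin_edges: np.ndarray | None = None,
                      min_events_multi: int = 50) -> MixtureFit:
    """Fit 1..n_max Gaussian components to the dwell histogram, select by
    reduced chi-squared.

    ``dwells`` is a :class:`~hsafm.analysis.DwellSet` or an array of dwell
    times in seconds.  Fewer than ``min_events_multi`` dwells fall back to
    a single component (with a warning); an empty set is an error.
    """
    tau = dwells.dwells if isinstance(dwells, DwellSet) else np.asarray(dwells, float)
    if tau.size == 0:
        raise ValueError("cannot fit a mixture to an empty dwell set")
    if np.any(tau <= 0):
        raise ValueError("dwell times must be positive")
    if tau.size < min_events_multi and n_max > 1:
        warnings.warn(f"only {tau.size} dwells: falling back to a single component")
        n_max = 1

    edges = _log_fd_edges(tau) if bin_edges is None else np.asarray(bin_edges, float)
    counts, _ = np.histogram(tau, edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    widths = np.diff(edges)
    density = counts / widths
    mode = centers[int(np.argmax(density))]
    total = float(counts.sum())
    span = tau.max() - tau.min()

    results: dict[int, tuple[float, np.ndarray]] = {}
    prev = None
    for n in range(1, n_max + 1):
        if counts.size < 3 * n + 2:
            break
        starts = []
        q = np.quantile(tau, (np.arange(n) + 0.5) / n)
        starts.append((q, np.full(n, max(span, mode) / (4.0 * n)), np.full(n, total / n)))
        starts.append((mode * np.arange(1, n + 1), np.full(n, mode / 2.0),
                       np.full(n, total / n)))
        if prev is not None:
            pm, ps, pa = prev
            resid = counts - _model_counts(np.r_[pm, ps, pa], n - 1, edges)
            j = int(np.argmax(resid / np.sqrt(np.maximum(counts, 1.0))))
            starts.append((np.r_[pm, centers[j]], np.r_[ps, widths[j]],
                           np.r_[pa * (1 - 1 / (n + 1)), total / (n + 1)]))
        chisq, params = _fit_fixed_n(counts, edges, starts)
        results[n] = (chisq, params)
        order = np.argsort(params[:n])
        prev = (params[:n][order], params[n:2 * n][order], params[2 * n:][order])

    def _solid(params: np.ndarray) -> bool:
        amp = params[2 * len(params) // 3:]
        return bool(np.all(amp >= _MIN_COMPONENT_WEIGHT * max(total, 1.0)))

    candidates = {n: c for n, (c, p) in results.items() if _solid(p)}
    if not candidates:
        candidates = {n: c for n, (c, _) in results.items()}
    ns = sorted(candidates)
    n_sel = ns[-1]
    for n in ns:
        if all(candidates[n] - candidates[m] <= _CHISQ_PER_PARAM * 3 * (m - n)
               for m in ns if m > n):
            n_sel = n
            break
    chisq, params = results[n_sel]
    red = chisq / max(1, counts.size - 3 * n_sel)
    order = np.argsort(params[:n_sel])
    mu = params[:n_sel][order]
    sd = params[n_sel:2 * n_sel][order]
    amp = params[2 * n_sel:][order]
    wsum = amp.sum() if amp.sum() > 0 else 1.0
    comps = [MixtureComponent(float(m), float(s), float(a / wsum))
             for m, s, a in zip(mu, sd, amp)]
    return MixtureFit(components=comps, red_chisq=red,
                      red_chisq_by_n={k: v[0] / max(1, counts.size - 3 * k)
                                      for k, v in results.items()},
                      bin_edges=edges, counts=counts)


def classify_events(dwells: DwellSet | np.ndarray, mixture: MixtureFit,
                    pool_from: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Assign each dwell to a mixture component; summarise unit fractions.

    Each event is labelled with the 1-based index of the component of
    maximal posterior responsibility (ties break to the smaller
    component).  Component i is interpreted as an oligomer of i base
    units for i < ``pool_from``; larger components are pooled into one
    higher-order class.

    Returns ``(labels, fractions)`` where ``fractions`` has
    ``pool_from`` entries: the unit-mass-weighted fraction of base units
    in 1-mers, 2-mers, ..., and the pooled class.
    """
    if mixture is None or mixture.n_components == 0:
        raise ValueError("mixture is not fitted")
    tau = dwells.dwells if isinstance(dwells, DwellSet) else np.asarray(dwells, float)
    if tau.size == 0:
        return np.empty(0, dtype=int), np.r_[1.0, np.zeros(pool_from - 1)]
    resp = mixture.responsibilities(tau)
    labels = np.argmax(resp, axis=1) + 1  # argmax takes the first (smaller) on ties
    units = labels.astype(float)
    classes = np.minimum(labels, pool_from)
    fractions = np.zeros(pool_from)
    for cls in range(1, pool_from + 1):
        fractions[cls - 1] = units[classes == cls].sum()
    total = fractions.sum()
    if total > 0:
        fractions /= total
    return labels, fractions
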