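"""2D oligomerization equilibria, dissociation constants and energetics.

Association of membrane-bound species is a two-dimensional reaction:
for A + B <-> AB at equilibrium, surface densities obey

    [AB] = [A][B] / K_d,

with K_d in µm⁻².  Binding curves follow

    fraction of B in complex = [A] / ([A] + K_d),

so K_d is measurable from titration data.  A stepwise (monomer-addition)
assembly model built from the monomer-row K_d values predicts the full
oligomer distribution at any total surface concentration; density ratios
convert to free-energy differences in units of k_BT, and surface/bulk
partitioning to a membrane-binding free energy.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from .units import molar_to_per_um3

_SPECIES_LABELS = ("monomer", "dimer", "trimer", "tetramer")


@dataclass
class KdMatrix:
    """Square matrix of 2D dissociation constants K_d[i][j] (µm⁻²).

    Entry (i, j) is the constant for association of an i-mer with a
    j-mer; the matrix need not be symmetric since the two species play
    asymmetric roles in the titration fits behind each entry.  Entries
    whose product exceeds 5 base units are flagged as reduced
    reliability (all aggregates above n = 4 are pooled in such fits).
    """

    values: pd.DataFrame
    errors: pd.DataFrame | None = None

    def __post_init__(self):
        v = self.values
        if v.shape[0] != v.shape[1]:
            raise ValueError("Kd matrix must be square")
        if (v.to_numpy() <= 0).any():
            raise ValueError("all Kd entries must be positive")

    @property
    def monomer_row(self) -> np.ndarray:
        """Stepwise constants: K_d for monomer + (n-1)-mer -> n-mer."""
        return self.values.iloc[0].to_numpy()

    def reduced_reliability(self) -> pd.DataFrame:
        n = self.values.shape[0]
        i, j = np.meshgrid(np.arange(1, n + 1), np.arange(1, n + 1), indexing="ij")
        return pd.DataFrame(i + j > 5, index=self.values.index,
                            columns=self.values.columns)

    def to_csv(self, path) -> None:
        self.values.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "KdMatrix":
        return cls(values=pd.read_csv(path, index_col=0))


def annexin_kd_matrix() -> KdMatrix:
    """Published 2D dissociation constants (µm⁻²) for annexin-V trimer
    oligomerization on supported membranes, monomer..tetramer by
    monomer..tetramer, with 95%-CI half-widths."""
    values = pd.DataFrame(
        [[220.0, 170.0, 650.0, 200.0],
         [152.0, 444.0, 210.0, 128.0],
         [260.0, 210.0, 180.0, 109.0],
         [170.0, 106.0, 91.0, 52.0]],
        index=_SPECIES_LABELS, columns=_SPECIES_LABELS)
    errors = pd.DataFrame(
        [[40.0, 20.0, 60.0, 10.0],
         [31.0, 60.0, 20.0, 8.0],
         [50.0, 20.0, 20.0, 10.0],
         [30.0, 21.0, 18.0, 10.0]],
        index=_SPECIES_LABELS, columns=_SPECIES_LABELS)
    return KdMatrix(values=values, errors=errors)


@dataclass(frozen=True)
class KdFit:
    kd: float
    stderr: float
    ci95: tuple[float, float]


def fit_kd_curve(concentrations: np.ndarray, fractions: np.ndarray) -> KdFit:
    """Fit a 2D binding curve ``f = [A] / ([A] + K_d)`` to titration data.

    ``concentrations`` are partner surface densities [A] (µm⁻²) and
    ``fractions`` the measured fraction of B in complex.  The confidence
    interval comes from the fit covariance.
    """
    a = np.asarray(concentrations, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if a.size != f.size:
        raise ValueError("concentrations and fractions must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 titration points")
    if np.any(a < 0) or np.any((f < 0) | (f > 1)):
        raise ValueError("concentrations must be >= 0 and fractions within [0, 1]")
    if np.all(f <= 0) or np.all(f >= 1):
        raise ValueError("degenerate titration (all fractions 0 or 1): Kd unidentifiable")

    p0 = a[np.argmin(np.abs(f - 0.5))]
    if p0 <= 0:
        p0 = np.median(a[a > 0])
    popt, pcov = curve_fit(lambda x, kd: x / (x + kd), a, f, p0=[p0],
                           bounds=(1e-12, np.inf), maxfev=10000)
    kd = float(popt[0])
    se = float(np.sqrt(pcov[0, 0]))
    return KdFit(kd=kd, stderr=se, ci95=(kd - 1.96 * se, kd + 1.96 * se))


@dataclass
class EquilibriumState:
    """Mass-conserving oligomer distribution at one total concentration.

    ``densities[n-1]`` is the number density (µm⁻²) of n-mers;
    ``mass_fractions`` are ``n * [A_n] / c_total``.
    """

    c_total: float
    densities: np.ndarray
    pool_from: int = 5

    @property
    def n_max(self) -> int:
        return self.densities.size

    @property
    def mass_fractions(self) -> np.ndarray:
        if self.c_total == 0:
            return np.r_[1.0, np.zeros(self.n_max - 1)]
        n = np.arange(1, self.n_max + 1)
        return n * self.densities / self.c_total

    def pooled_fractions(self) -> np.ndarray:
        """Unit fractions f_1..f_{pool_from-1} plus the pooled >= pool_from class."""
        f = self.mass_fractions
        k = self.pool_from
        return np.r_[f[:k - 1], f[k - 1:].sum()]


def _stepwise_densities(a1: float, kds: np.ndarray, n_max: int) -> np.ndarray:
    out = np.empty(n_max)
    out[0] = a1
    for n in range(2, n_max + 1):
        kd = kds[min(n - 2, kds.size - 1)]
        out[n - 1] = a1 * out[n - 2] / kd
    return out


def equilibrium_distribution(c_total: float, kds: KdMatrix | np.ndarray,
                             n_max: int = 10, pool_from: int = 5) -> EquilibriumState:
    """Solve the stepwise monomer-addition equilibrium at ``c_total``.

    The assembly pathway adds one base unit at a time using the
    monomer-row dissociation constants:
    ``[A_n] = [A_1] [A_{n-1}] / K_d(1, n-1)``; constants beyond the last
    supplied one are extended by repetition.  The free monomer density is
    found by root-finding on the (monotone) mass-conservation constraint
    ``sum_n n [A_n] = c_total``.
    """
    if c_total < 0:
        raise ValueError("c_total must be non-negative")
    kd_row = kds.monomer_row if isinstance(kds, KdMatrix) else np.asarray(kds, float)
    if kd_row.size == 0 or np.any(kd_row <= 0):
        raise ValueError("need positive stepwise Kd values")
    if c_total == 0:
        return EquilibriumState(0.0, np.zeros(n_max), pool_from)

    ns = np.arange(1, n_max + 1)

    def mass_excess(a1: float) -> float:
        return float((ns * _stepwise_densities(a1, kd_row, n_max)).sum()) - c_total

    a1 = brentq(mass_excess, 0.0, c_total, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    dens = _stepwise_densities(a1, kd_row, n_max)
    return EquilibriumState(c_total, dens, pool_from)


def equilibrium_sweep(c_totals: np.ndarray, kds: KdMatrix | np.ndarray,
                      n_max: int = 10, pool_from: int = 5) -> pd.DataFrame:
    """Oligomer mass fractions over a grid of total surface concentrations."""
    cols = [f"f{i}" for i in range(1, pool_from)] + ["f_o"]
    rows = [equilibrium_distribution(c, kds, n_max, pool_from).pooled_fractions()
            for c in c_totals]
    out = pd.DataFrame(rows, columns=cols)
    out.insert(0, "c_total", np.asarray(c_totals, dtype=float))
    return out


def oligomer_free_energy(c_n: float, c_m: float) -> float:
    """Free-energy difference (k_BT) between two oligomer states from their
    surface-density ratio: ΔG = ln(c_n / c_m)."""
    if c_n <= 0 or c_m <= 0:
        raise ValueError("densities must be positive")
    return float(np.log(c_n / c_m))


@dataclass(frozen=True)
class BindingEnergetics:
    """Membrane partitioning and the binding free energy it implies."""

    partition_coefficient: float
    slab_thickness: float  # nm used to volumize the surface density
    delta_g0: float        # k_BT


def membrane_binding_free_energy(c_surface: float, c_bulk_molar: float,
                                 slab_thickness: float = 2.0) -> BindingEnergetics:
    """Binding free energy from surface and bulk concentrations.

    The partition coefficient is ``P = [c_solution] / [c_surface]`` with
    both sides volumetric: the bulk molarity converts to molecules µm⁻³
    and the surface density (µm⁻²) is divided by a surface slab of
    ``slab_thickness`` nm (default 2.0, the bound molecule's height).
    ΔG0 = ln(P) in k_BT; negative values mean favourable binding.
    """
    if slab_thickness <= 0:
        raise ValueError("slab thickness must be positive")
    if c_surface <= 0 or c_bulk_molar <= 0:
        raise ValueError("concentrations must be positive")
    c_bulk_vol = molar_to_per_um3(c_bulk_molar)
    c_surf_vol = c_surface / (slab_thickness * 1e-3)
    p = c_bulk_vol / c_surf_vol
    return BindingEnergetics(partition_coefficient=p, slab_thickness=slab_thickness,
                             delta_g0=float(np.log(p)))


@dataclass
class SDFit:
    """Saffman-Delbrück-type fit D = a * ln(b / r) over species radii."""

    amplitude: float  # a, µm² s⁻¹
    length: float     # b, nm
    radii: np.ndarray
    d_observed: np.ndarray
    d_fitted: np.ndarray

    @property
    def residual_rms(self) -> float:
        return float(np.sqrt(np.mean((self.d_fitted - self.d_observed) ** 2)))


def fit_saffman_delbruck(radii: np.ndarray, diffusion: np.ndarray) -> SDFit:
    """Fit the logarithmic size dependence D = a ln(b / r_p).

    The model is linear in (a, a ln b), so the least-squares solution is
    exact.  ``radii`` in nm, ``diffusion`` in µm² s⁻¹.  An increasing D(r)
    series draws a warning (the model expects larger species to diffuse
    more slowly) but is still fitted.
    """
    r = np.asarray(radii, dtype=float)
    d = np.asarray(diffusion, dtype=float)
    if r.size != d.size:
        raise ValueError("radii and diffusion series must have equal length")
    if r.size < 3:
        raise ValueError("need at least 3 points for the 2-parameter fit")
    if np.any(r <= 0):
        raise ValueError("radii must be positive")
    if np.all(np.diff(d[np.argsort(r)]) >= 0):
        warnings.warn("diffusion increases with radius: fit returned but suspect")
    # D = p0 * (-ln r) + p1 with p0 = a, p1 = a ln b
    A = np.column_stack([-np.log(r), np.ones_like(r)])
    (p0, p1), *_ = np.linalg.lstsq(A, d, rcond=None)
    a = float(p0)
    b = float(np.exp(p1 / p0)) if p0 != 0 else np.inf
    fitted = a * np.log(b / r)
    return SDFit(amplitude=a, length=b, radii=r, d_observed=d, d_fitted=fitted)


@dataclass(frozen=True)
class CalciumFit:
    """Exponential growth of surface concentration with bulk calcium."""

    amplitude: float   # µm⁻² at zero calcium
    rate: float        # per µM
    ca_at_critical: float  # µM at which c reaches the critical density


def fit_critical_calcium(ca: np.ndarray, c_surface: np.ndarray,
                         c_critical: float = 500.0) -> CalciumFit:
    """Fit ``c = A exp(k Ca)`` and solve for the calcium concentration at
    which the critical surface density is reached.

    The fit is least squares in log-density (exact for noise-free
    exponential data, and appropriate for multiplicative scatter).
    """
    x = np.asarray(ca, dtype=float)
    y = np.asarray(c_surface, dtype=float)
    if x.size != y.size:
        raise ValueError("calcium and surface series must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.any(y <= 0) or c_critical <= 0:
        raise ValueError("surface concentrations must be positive")
    A = np.column_stack([x, np.ones_like(x)])
    (k, lna), *_ = np.linalg.lstsq(A, np.log(y), rcond=None)
    amp = float(np.exp(lna))
    if k == 0:
        raise ValueError("flat series: no exponential growth to fit")
    ca_star = float((np.log(c_critical) - lna) / k)
    return CalciumFit(amplitude=amp, rate=float(k), ca_at_critical=ca_star)
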