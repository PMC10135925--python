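"""Hydrodynamic-stress statistics from exported finite-volume turbulence fields.

A CFD run of a shaken flask or stirred vessel leaves behind a per-cell table
of control volumes and turbulence quantities (turbulent kinetic energy ``k``,
specific dissipation rate ``omega``, optionally the dissipation rate
``epsilon`` and the velocity-gradient tensor).  This module reduces such a
table to the quantities used to judge whether suspended animal cells are
exposed to damaging stress:

* the local energy dissipation rate ``epsilon = beta_star * k * omega``
  (the k-omega family of turbulence closures does not transport epsilon
  directly),
* the Kolmogorov length ``lambda_k = (nu**3 / epsilon) ** 0.25`` — the
  smallest eddy scale; eddies smaller than a cell or aggregate are the
  ones considered harmful,
* volume-weighted means and volume-related distributions of both,
* the specific power input ``P/V``, either from an impeller/flask torque
  (``2*pi*n*M/V``) or by volume-integrating ``rho * epsilon``,
* the hydrodynamic heterogeneity ``Phi = eps_max / eps_mean``,
* the Q-criterion (second invariant of the velocity gradient) for vortex
  identification.

All reductions are volume weighted: CFD meshes are unstructured, so cells
must be weighted by their control volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

__all__ = [
    "BETA_STAR",
    "WATER_310K",
    "FluidProperties",
    "FlowField",
    "LambdaDistribution",
    "VolumeBelow",
    "epsilon_from_k_omega",
    "fill_epsilon",
    "kolmogorov_length",
    "volume_weighted_mean",
    "volume_weighted_median",
    "power_per_volume_from_torque",
    "power_per_volume_from_dissipation",
    "heterogeneity",
    "lambda_volume_distribution",
    "volume_fraction_below",
    "q_criterion",
]

#: k-omega SST model constant relating epsilon to k*omega.
BETA_STAR = 0.09


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid properties in SI units.

    Parameters
    ----------
    density
        rho [kg/m^3].
    kinematic_viscosity
        nu [m^2/s].
    dynamic_viscosity
        eta [Pa s]; derived as ``rho * nu`` when omitted.  If supplied it
        must be consistent with ``rho * nu`` to 1e-12 relative.
    surface_tension
        sigma [N/m]; informational (free-surface solvers need it, the
        post-processing here does not).
    """

    density: float
    kinematic_viscosity: float
    dynamic_viscosity: float | None = None
    surface_tension: float | None = None

    def __post_init__(self) -> None:
        if self.density <= 0 or self.kinematic_viscosity <= 0:
            raise ValueError("density and kinematic_viscosity must be > 0")
        derived = self.density * self.kinematic_viscosity
        if self.dynamic_viscosity is None:
            object.__setattr__(self, "dynamic_viscosity", derived)
        else:
            if self.dynamic_viscosity <= 0:
                raise ValueError("dynamic_viscosity must be > 0")
            rel = abs(self.dynamic_viscosity - derived) / derived
            if rel > 1e-12:
                raise ValueError(
                    f"dynamic_viscosity inconsistent with rho*nu "
                    f"(relative error {rel:.3e} > 1e-12)"
                )
        if self.surface_tension is not None and self.surface_tension <= 0:
            raise ValueError("surface_tension must be > 0 when given")


#: Water at the 310.15 K (37 degC) cultivation temperature of mammalian cells.
WATER_310K = FluidProperties(
    density=993.37,
    kinematic_viscosity=0.6959e-6,
    surface_tension=71.968e-3,
)


def _as_1d(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        a = np.atleast_1d(a.squeeze())
    if a.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return a


@dataclass
class FlowField:
    """Per-cell export of a finite-volume turbulence field.

    Attributes
    ----------
    volume
        Control volumes V_i [m^3], all strictly positive.
    k
        Turbulent kinetic energy k_i [m^2/s^2], non-negative.
    omega
        Specific dissipation rate omega_i [1/s], non-negative.
    epsilon
        Dissipation rate eps_i [m^2/s^3]; optional.  When absent it is
        derived as ``beta_star * k * omega`` on demand.  A provided column
        always wins over (k, omega); per-record mixing is not supported.
    grad_v
        Velocity-gradient tensors, shape (n, 3, 3) [1/s]; optional.
    total_volume
        Declared total liquid volume V [m^3].  Exported subsets (e.g. the
        liquid phase of a two-phase field) routinely lose cells, so
        ``sum(volume)`` may fall short of V: within ``volume_rtol`` it is
        accepted silently, up to 1e-2 with a warning, beyond that it is an
        error.  All weighted reductions normalise by ``sum(volume)``.
    """

    volume: np.ndarray
    k: np.ndarray
    omega: np.ndarray
    total_volume: float | None = None
    epsilon: np.ndarray | None = None
    grad_v: np.ndarray | None = None
    volume_rtol: float = 1e-6

    def __post_init__(self) -> None:
        self.volume = _as_1d(self.volume, "volume")
        self.k = _as_1d(self.k, "k")
        self.omega = _as_1d(self.omega, "omega")
        n = self.volume.size
        if n == 0:
            raise ValueError("FlowField needs at least one cell")
        for name in ("k", "omega"):
            arr = getattr(self, name)
            if arr.size != n:
                raise ValueError(f"{name} has {arr.size} entries, expected {n}")
        if self.epsilon is not None:
            self.epsilon = _as_1d(self.epsilon, "epsilon")
            if self.epsilon.size != n:
                raise ValueError(
                    f"epsilon has {self.epsilon.size} entries, expected {n}"
                )
            bad = np.flatnonzero(self.epsilon < 0)
            if bad.size:
                raise ValueError(f"negative epsilon at record {bad[0]}")
        if self.grad_v is not None:
            self.grad_v = np.asarray(self.grad_v, dtype=float)
            if self.grad_v.shape != (n, 3, 3):
                raise ValueError("grad_v must have shape (n_cells, 3, 3)")
        bad = np.flatnonzero(self.volume <= 0)
        if bad.size:
            raise ValueError(f"non-positive cell volume at record {bad[0]}")
        for name in ("k", "omega"):
            bad = np.flatnonzero(getattr(self, name) < 0)
            if bad.size:
                raise ValueError(f"negative {name} at record {bad[0]}")
        vsum = float(self.volume.sum())
        if self.total_volume is None:
            self.total_volume = vsum
        else:
            rel = abs(vsum - self.total_volume) / self.total_volume
            if rel > 1e-2:
                raise ValueError(
                    f"sum of cell volumes deviates from total_volume by "
                    f"{rel:.3e} (> 1e-2)"
                )
            if rel > self.volume_rtol:
                warnings.warn(
                    f"sum of cell volumes deviates from total_volume by "
                    f"{rel:.3e}; weighted statistics normalise by the sum",
                    stacklevel=2,
                )

    @property
    def n_cells(self) -> int:
        return self.volume.size

    def dissipation(self, beta_star: float = BETA_STAR) -> np.ndarray:
        """Per-cell epsilon: the provided column, else beta_star*k*omega."""
        if self.epsilon is not None:
            return self.epsilon
        return epsilon_from_k_omega(self.k, self.omega, beta_star)


def epsilon_from_k_omega(k, omega, beta_star: float = BETA_STAR):
    """Energy dissipation rate ``beta_star * k * omega`` [m^2/s^3].

    Accepts scalars, arrays or a :class:`FlowField`.  For a field, returns
    a new field with the epsilon column filled in; an already-present
    column is kept unless ``force`` is used via :func:`fill_epsilon`.
    """
    if isinstance(k, FlowField):
        return fill_epsilon(k, beta_star=beta_star)
    k = np.asarray(k, dtype=float)
    omega = np.asarray(omega, dtype=float)
    for name, arr in (("k", k), ("omega", omega)):
        bad = np.flatnonzero(np.atleast_1d(arr) < 0)
        if bad.size:
            raise ValueError(f"negative {name} at record {bad[0]}")
    out = beta_star * k * omega
    return float(out) if out.ndim == 0 else out


def fill_epsilon(
    field: FlowField, beta_star: float = BETA_STAR, force: bool = False
) -> FlowField:
    """Return a copy of ``field`` with epsilon materialised from k, omega.

    A provided epsilon column is never overwritten unless ``force=True``.
    """
    if field.epsilon is not None and not force:
        return field
    eps = epsilon_from_k_omega(field.k, field.omega, beta_star)
    return FlowField(
        volume=field.volume.copy(),
        k=field.k.copy(),
        omega=field.omega.copy(),
        total_volume=field.total_volume,
        epsilon=np.atleast_1d(eps),
        grad_v=None if field.grad_v is None else field.grad_v.copy(),
        volume_rtol=field.volume_rtol,
    )


def kolmogorov_length(nu: float, epsilon, on_zero: str = "warn"):
    """Kolmogorov length ``(nu**3 / epsilon) ** 0.25`` [m].

    Strictly decreasing in epsilon.  Quiescent cells (epsilon == 0) have no
    finite eddy scale; they map to ``+inf`` with a warning (``on_zero="warn"``,
    the default) or raise (``on_zero="error"``).
    """
    if nu <= 0:
        raise ValueError("kinematic viscosity must be > 0")
    eps = np.asarray(epsilon, dtype=float)
    if np.any(np.atleast_1d(eps) < 0):
        raise ValueError("epsilon must be >= 0")
    zero = np.atleast_1d(eps) == 0
    if zero.any():
        if on_zero == "error":
            raise ValueError("epsilon == 0: Kolmogorov length undefined")
        warnings.warn(
            f"{int(zero.sum())} quiescent cell(s) with epsilon == 0 mapped "
            "to an infinite Kolmogorov length",
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        out = (nu**3 / eps) ** 0.25
    return float(out) if out.ndim == 0 else out


def volume_weighted_mean(values, field: FlowField) -> float:
    """Volume-weighted mean ``sum(q_i V_i) / sum(V_i)`` over the field."""
    q = _as_1d(values, "values")
    if q.size != field.n_cells:
        raise ValueError(
            f"values not aligned with field cells ({q.size} vs {field.n_cells})"
        )
    return float(np.dot(q, field.volume) / field.volume.sum())


def volume_weighted_median(values, field: FlowField) -> float:
    """Smallest value at which the cumulative volume fraction reaches 1/2."""
    q = _as_1d(values, "values")
    if q.size != field.n_cells:
        raise ValueError("values not aligned with field cells")
    order = np.argsort(q, kind="stable")
    cum = np.cumsum(field.volume[order])
    idx = int(np.searchsorted(cum, 0.5 * cum[-1]))
    return float(q[order][min(idx, q.size - 1)])


def power_per_volume_from_torque(n: float, torque: float, volume: float) -> float:
    """Specific power input ``2*pi*n*M/V`` [W/m^3] from a measured torque."""
    if volume <= 0:
        raise ValueError("volume must be > 0")
    return 2.0 * np.pi * n * torque / volume


def power_per_volume_from_dissipation(
    field: FlowField, fluid: FluidProperties, beta_star: float = BETA_STAR
) -> float:
    """Specific power input ``sum(eps_i V_i) * rho / sum(V_i)`` [W/m^3].

    Equals ``rho * volume_weighted_mean(epsilon)``.  Typically 30-50 % below
    the torque route because the resolved dissipation underestimates the
    true total.
    """
    eps = field.dissipation(beta_star)
    return fluid.density * volume_weighted_mean(eps, field)


def heterogeneity(
    field: FlowField,
    beta_star: float = BETA_STAR,
    percentile: float | None = None,
) -> float:
    """Hydrodynamic heterogeneity ``Phi = eps_max / eps_mean`` (>= 1).

    ``percentile`` replaces the raw cell-wise maximum by that percentile of
    epsilon (e.g. 99.9) — single-cell outliers dominate CFD maxima, so a
    trimmed variant is offered; the default is the raw maximum.
    """
    eps = field.dissipation(beta_star)
    mean = volume_weighted_mean(eps, field)
    if mean <= 0:
        raise ValueError("mean dissipation is zero; heterogeneity undefined")
    top = float(np.max(eps)) if percentile is None else float(
        np.percentile(eps, percentile)
    )
    return top / mean


@dataclass(frozen=True)
class LambdaDistribution:
    """Volume-related distribution of the Kolmogorov length.

    ``volume_fraction[j]`` is the fraction of liquid volume whose local
    Kolmogorov length falls in ``[bin_edges[j], bin_edges[j+1])``; the
    fractions sum to one.  ``mean`` and ``median`` are volume weighted and
    computed on the finite per-cell values; ``quiescent_volume`` is the
    absolute volume [m^3] of cells with zero dissipation, which is clamped
    into the topmost bin so no volume is dropped.
    """

    bin_edges: np.ndarray
    volume_fraction: np.ndarray
    mean: float
    median: float
    quiescent_volume: float = 0.0

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        frac = np.asarray(self.volume_fraction, dtype=float)
        if edges.ndim != 1 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if frac.size != edges.size - 1:
            raise ValueError("volume_fraction must have len(bin_edges) - 1 entries")
        if np.any(frac < 0):
            raise ValueError("volume fractions must be >= 0")
        if abs(frac.sum() - 1.0) > 1e-9:
            raise ValueError("volume fractions must sum to 1 within 1e-9")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "volume_fraction", frac)


def default_lambda_bins(lam: np.ndarray, n_bins: int = 200) -> np.ndarray:
    """200 logarithmic bins spanning [min/1.05, max*1.05] of the finite values."""
    finite = lam[np.isfinite(lam)]
    if finite.size == 0:
        raise ValueError("no finite Kolmogorov lengths in the field")
    lo, hi = finite.min() / 1.05, finite.max() * 1.05
    if lo == hi:  # uniform field: a point mass still needs a nonzero bin
        lo, hi = lo / 1.05, hi * 1.05
    return np.geomspace(lo, hi, n_bins + 1)


def lambda_volume_distribution(
    field: FlowField,
    fluid: FluidProperties,
    bin_edges: Sequence[float] | None = None,
    beta_star: float = BETA_STAR,
) -> LambdaDistribution:
    """Volume-related Kolmogorov-length distribution of a field.

    Values outside the supplied bins are clamped into the end bins with a
    warning (quiescent epsilon == 0 cells always land in the topmost bin);
    the per-bin fractions therefore sum to one exactly.
    """
    eps = field.dissipation(beta_star)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lam = np.atleast_1d(kolmogorov_length(fluid.kinematic_viscosity, eps))
    finite = np.isfinite(lam)
    quiescent_volume = float(field.volume[~finite].sum())
    if quiescent_volume > 0:
        warnings.warn(
            f"{quiescent_volume:.3e} m^3 of quiescent volume (epsilon == 0) "
            "clamped into the topmost Kolmogorov-length bin",
            stacklevel=2,
        )

    if bin_edges is None:
        edges = default_lambda_bins(lam)
    else:
        edges = np.asarray(bin_edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing with >= 2 edges")
        lam_f = lam[finite]
        if lam_f.size and (lam_f.min() < edges[0] or lam_f.max() > edges[-1]):
            warnings.warn(
                "Kolmogorov lengths outside the bin range were clamped into "
                "the end bins",
                stacklevel=2,
            )

    clamped = np.clip(lam, edges[0], np.nextafter(edges[-1], -np.inf))
    idx = np.clip(np.searchsorted(edges, clamped, side="right") - 1, 0, edges.size - 2)
    frac = np.bincount(idx, weights=field.volume, minlength=edges.size - 1)
    frac = frac / field.volume.sum()

    if finite.any():
        sub = FlowField(
            volume=field.volume[finite],
            k=field.k[finite],
            omega=field.omega[finite],
        )
        mean = volume_weighted_mean(lam[finite], sub)
        median = volume_weighted_median(lam[finite], sub)
    else:
        mean = median = np.inf
    return LambdaDistribution(
        bin_edges=edges,
        volume_fraction=frac,
        mean=mean,
        median=median,
        quiescent_volume=quiescent_volume,
    )


@dataclass(frozen=True)
class VolumeBelow:
    """Volume with a Kolmogorov length below a critical size."""

    fraction: float
    absolute_volume: float  # [m^3]


def volume_fraction_below(
    field: FlowField,
    fluid: FluidProperties,
    lambda_crit: float,
    beta_star: float = BETA_STAR,
) -> VolumeBelow:
    """Fraction (and absolute volume) where ``lambda_k < lambda_crit``.

    This is the CDF of the volume-related Kolmogorov-length distribution:
    monotone non-decreasing in ``lambda_crit``, 0 below the attained minimum
    and 1 above the maximum.  The absolute volume is the fraction times the
    declared total liquid volume.
    """
    if lambda_crit <= 0:
        raise ValueError("lambda_crit must be > 0")
    eps = field.dissipation(beta_star)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lam = np.atleast_1d(kolmogorov_length(fluid.kinematic_viscosity, eps))
    frac = float(field.volume[lam < lambda_crit].sum() / field.volume.sum())
    return VolumeBelow(fraction=frac, absolute_volume=frac * field.total_volume)


def q_criterion(grad_v) -> float | np.ndarray:
    """Q-criterion ``0.5 * ((tr G)^2 - tr(G @ G))`` of velocity gradients.

    Positive Q marks regions where vorticity dominates over strain (vortex
    cores); for solid-body rotation at rate w about any axis Q = w**2, for
    pure shear Q = 0, and for incompressible plane strain diag(a, -a, 0)
    Q = -a**2.  Accepts a single (3, 3) tensor or a stack (n, 3, 3).
    """
    g = np.asarray(grad_v, dtype=float)
    single = g.ndim == 2
    if single:
        g = g[None, ...]
    if g.ndim != 3 or g.shape[-2:] != (3, 3):
        raise ValueError("grad_v must be a (3, 3) tensor or an (n, 3, 3) stack")
    if not np.all(np.isfinite(g)):
        raise ValueError("grad_v entries must be finite")
    tr = np.trace(g, axis1=-2, axis2=-1)
    tr_gg = np.einsum("nij,nji->n", g, g)
    q = 0.5 * (tr**2 - tr_gg)
    return float(q[0]) if single else q
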