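"""Seeded generators emulating every input the analysis pipeline consumes.

CFD field exports, mesh-convergence series, cluster-size tables, growth
curves and cell-diameter samples are all reproducible pure functions of a
specification plus an integer seed, so the whole pipeline is testable
without CFD runs or instrument data.

The dissipation field generator states its world explicitly: per-cell
dissipation rates are log-normal — the standard positively skewed model for
turbulent dissipation in agitated vessels — rescaled so the volume-weighted
mean matches a prescribed value exactly and the max/mean heterogeneity Phi
matches a prescribed target within 5 % (by bisecting the log-normal shape
parameter on a fixed draw).  Turbulent kinetic energy is back-filled from a
nominal mixing length so that ``0.09 * k * omega`` reproduces the epsilon
field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .aggregates import ClusterCounts
from .gci import MeshSeries
from .growth import DiameterSample, GrowthSeries
from .hydro import BETA_STAR, FlowField

__all__ = [
    "FieldSpec",
    "gen_flowfield",
    "gen_clusters",
    "gen_mesh_series",
    "gen_growth",
    "gen_diameters",
]


@dataclass(frozen=True)
class FieldSpec:
    """Stated world of a synthetic dissipation field.

    ``n_cells`` finite-volume cells filling ``total_volume`` [m^3];
    volume-weighted mean dissipation ``mean_dissipation`` [m^2/s^3];
    ``heterogeneity`` the max/mean target Phi >= 1; cell volumes uniform or
    log-normal; ``mixing_length`` [m] sets the k back-fill scale (a tenth
    of a typical 85 mm impeller by default).
    """

    n_cells: int
    total_volume: float
    mean_dissipation: float
    heterogeneity: float = 1.0
    volume_distribution: str = "lognormal"
    seed: int = 0
    mixing_length: float = 8.5e-3

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.total_volume <= 0 or self.mean_dissipation <= 0:
            raise ValueError("total_volume and mean_dissipation must be > 0")
        if self.heterogeneity < 1:
            raise ValueError("heterogeneity target must be >= 1")
        if self.volume_distribution not in ("uniform", "lognormal"):
            raise ValueError("volume_distribution must be 'uniform' or 'lognormal'")


def _phi(eps: np.ndarray, vol: np.ndarray) -> float:
    return float(eps.max() / (np.dot(eps, vol) / vol.sum()))


def gen_flowfield(spec: FieldSpec, phi_rtol: float = 0.05) -> FlowField:
    """Synthetic flow field with prescribed mean dissipation and Phi.

    The volume-weighted mean dissipation is matched exactly (a global
    multiplicative rescale, to which Phi is invariant); Phi is matched
    within ``phi_rtol`` by bisection on the log-normal sigma of a fixed
    standard-normal draw (at most 100 iterations).  Raises when the target
    is unreachable for the drawn sample (e.g. Phi > 1 with a single cell).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells

    if spec.volume_distribution == "uniform":
        vol = np.full(n, 1.0)
    else:
        vol = rng.lognormal(mean=0.0, sigma=0.5, size=n)
    vol *= spec.total_volume / vol.sum()

    z = rng.standard_normal(n)
    if spec.heterogeneity == 1.0 or n == 1:
        if spec.heterogeneity > 1.0:
            raise ValueError("heterogeneity > 1 unreachable with a single cell")
        eps = np.full(n, spec.mean_dissipation)
    else:
        lo, hi = 0.0, 20.0
        if _phi(np.exp(hi * z), vol) < spec.heterogeneity:
            raise ValueError(
                "heterogeneity target unreachable for this draw; "
                "increase n_cells or lower the target"
            )
        sigma = 1.0
        for _ in range(100):
            sigma = 0.5 * (lo + hi)
            phi = _phi(np.exp(sigma * z), vol)
            if abs(phi - spec.heterogeneity) / spec.heterogeneity <= phi_rtol:
                break
            if phi < spec.heterogeneity:
                lo = sigma
            else:
                hi = sigma
        else:
            raise RuntimeError("Phi bisection did not converge in 100 iterations")
        eps = np.exp(sigma * z)
        eps *= spec.mean_dissipation / (np.dot(eps, vol) / vol.sum())

    # only the product k*omega is constrained; split it via a mixing length
    k = (eps * spec.mixing_length) ** (2.0 / 3.0)
    omega = eps / (BETA_STAR * k)
    return FlowField(volume=vol, k=k, omega=omega, total_volume=spec.total_volume)


def gen_clusters(n_clusters: int, p: float, seed: int = 0) -> ClusterCounts:
    """I.i.d. geometric cluster-size sample as a count table."""
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    rng = np.random.default_rng(seed)
    return ClusterCounts.from_samples(rng.geometric(p, size=n_clusters))


def gen_mesh_series(
    f_limit: float,
    coefficient: float,
    order: float,
    cell_counts,
    noise_sd: float = 0.0,
    seed: int | None = None,
    safety_factor: float = 1.25,
) -> MeshSeries:
    """Power-law mesh-convergence series ``f = f_limit + C * h**p``.

    ``h = cell_count**(-1/3)`` is the 3D characteristic spacing; optional
    additive Gaussian noise emulates iterative-solver scatter.
    """
    if order <= 0:
        raise ValueError("order must be > 0")
    nc = np.asarray(cell_counts, dtype=float)
    h = nc ** (-1.0 / 3.0)
    f = f_limit + coefficient * h**order
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=f.size)
    return MeshSeries(
        cell_counts=tuple(nc), qoi=tuple(f), safety_factor=safety_factor
    )


def gen_growth(
    v0: float = 0.3e6,
    mu: float = 0.025,
    t_peak: float = 120.0,
    decline_rate: float = 0.005,
    noise_cv: float = 0.0,
    seed: int = 0,
    t_end: float = 192.0,
    dt: float = 24.0,
) -> GrowthSeries:
    """Synthetic batch growth curve: exponential to a peak, then decline.

    Daily sampling over 0..``t_end`` h; VCD grows as ``v0*exp(mu*t)`` until
    ``t_peak`` and declines exponentially at ``decline_rate`` afterwards.
    Multiplicative log-normal noise with coefficient of variation
    ``noise_cv``; viability stays high (98 %) through the growth phase and
    decays after the peak.
    """
    if v0 <= 0 or mu <= 0 or t_peak <= 0 or decline_rate < 0:
        raise ValueError("growth parameters must be positive")
    t = np.arange(0.0, t_end + 0.5 * dt, dt)
    vcd = np.where(
        t <= t_peak,
        v0 * np.exp(mu * t),
        v0 * np.exp(mu * t_peak) * np.exp(-decline_rate * (t - t_peak)),
    )
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        vcd = vcd * rng.lognormal(-0.5 * sigma**2, sigma, size=t.size)
    viability = np.where(t <= t_peak, 98.0, 98.0 - 0.25 * (t - t_peak))
    viability = np.clip(viability, 0.0, 100.0)
    return GrowthSeries(time=t, vcd=vcd, viability=viability)


def gen_diameters(
    mean: float = 15.97, sd: float = 2.79, n: int = 10_000, seed: int = 0,
    instrument_range: tuple = (2.0, 40.0),
) -> DiameterSample:
    """Truncated-normal cell-diameter sample within the instrument range.

    Defaults match a typical HEK293 population at inoculation (mean
    15.97 um, SD 2.79 um); truncation to the 2-40 um window of an imaging
    cell counter.
    """
    if sd < 0 or n < 1:
        raise ValueError("need sd >= 0 and n >= 1")
    lo, hi = instrument_range
    if sd == 0:
        d = np.full(n, float(np.clip(mean, lo, hi)))
    else:
        rng = np.random.default_rng(seed)
        a, b = (lo - mean) / sd, (hi - mean) / sd
        d = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return DiameterSample(diameters=d, instrument_range=instrument_range)
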