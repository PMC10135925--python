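"""Grid-convergence-index (GCI) solution verification.

Richardson extrapolation with a safety factor: given a series of meshes of
increasing resolution and one scalar quantity of interest (QoI) per mesh —
here typically the volume-averaged Kolmogorov length — estimate the observed
order of accuracy and a conservative relative discretisation-error band for
each consecutive mesh triplet.

Conventions (pinned by reproducing published worked tables):

* refinement factor between meshes from cell counts,
  ``r = (nc_fine / nc_coarse) ** (1/3)`` for 3D meshes;
* relative error normalised by the *coarser* value,
  ``eps_mn = |f_coarse - f_fine| / |f_coarse|``;
* ``GCI [%] = 100 * Fs * eps_mn / (r**p - 1)`` with safety factor
  ``Fs = 1.25``;
* asymptotic-range check
  ``ratio = GCI_coarse_pair / (r_coarse_pair**p * GCI_fine_pair)``,
  close to one when the triplet sits in the asymptotic convergence region.

The observed order for non-constant refinement factors solves the standard
transcendental relation by a sign-corrected fixed-point iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from math import log
from typing import Sequence

import numpy as np

__all__ = [
    "MeshSeries",
    "OrderEstimate",
    "GciCase",
    "GciReport",
    "refinement_factor",
    "relative_error",
    "observed_order",
    "gci_value",
    "asymptotic_ratio",
    "analyze_series",
]


@dataclass(frozen=True)
class MeshSeries:
    """Ordered coarse-to-fine mesh study input.

    ``cell_counts`` strictly increasing; ``qoi`` the scalar quantity of
    interest per mesh (same units throughout); ``safety_factor`` > 1.
    """

    cell_counts: tuple
    qoi: tuple
    safety_factor: float = 1.25
    labels: tuple | None = None

    def __post_init__(self) -> None:
        nc = tuple(float(c) for c in self.cell_counts)
        f = tuple(float(v) for v in self.qoi)
        if len(nc) != len(f):
            raise ValueError("cell_counts and qoi must have the same length")
        if len(nc) < 3:
            raise ValueError("need at least 3 meshes for order estimation")
        if any(b <= a for a, b in zip(nc, nc[1:])):
            raise ValueError("cell counts must be strictly increasing")
        if any(c <= 0 for c in nc):
            raise ValueError("cell counts must be positive")
        if self.safety_factor <= 1:
            raise ValueError("safety_factor must be > 1")
        labels = self.labels or tuple(f"M{i + 1}" for i in range(len(nc)))
        if len(labels) != len(nc):
            raise ValueError("labels must match the number of meshes")
        object.__setattr__(self, "cell_counts", nc)
        object.__setattr__(self, "qoi", f)
        object.__setattr__(self, "labels", tuple(labels))

    def __len__(self) -> int:
        return len(self.cell_counts)


def refinement_factor(nc_coarse: float, nc_fine: float, dim: int = 3) -> float:
    """Mesh refinement factor ``(nc_fine / nc_coarse) ** (1/dim)``.

    ``dim=3`` (the default) is the volumetric convention; ``dim=2`` exists
    for planar meshes.
    """
    if nc_coarse <= 0 or nc_fine <= nc_coarse:
        raise ValueError("need nc_fine > nc_coarse > 0")
    if dim not in (2, 3):
        raise ValueError("dim must be 2 or 3")
    return (nc_fine / nc_coarse) ** (1.0 / dim)


def relative_error(f_coarse: float, f_fine: float) -> float:
    """Relative solution change ``|f_coarse - f_fine| / |f_coarse|``.

    Normalised by the coarser-mesh value (this convention reproduces the
    published worked tables; fine-normalisation does not).
    """
    if f_coarse == 0:
        raise ValueError("coarse-mesh QoI is zero; relative error undefined")
    return abs(f_coarse - f_fine) / abs(f_coarse)


#: upper bound for the observed-order search; far above any physical scheme
P_MAX = 40.0


@dataclass(frozen=True)
class OrderEstimate:
    """Observed order of accuracy, with an oscillatory-convergence flag."""

    value: float
    oscillatory: bool = False

    def __float__(self) -> float:
        return self.value


def observed_order(
    f_coarse: float,
    f_mid: float,
    f_fine: float,
    r_coarse: float,
    r_fine: float,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> OrderEstimate:
    """Observed order of accuracy from a coarse/mid/fine mesh triplet.

    ``r_coarse`` is the refinement factor between the coarse and mid mesh,
    ``r_fine`` between the mid and fine mesh.  Solves

        p * ln(r_fine) = | ln|d_c / d_f| + ln((r_fine**p - s)/(r_coarse**p - s)) |

    with ``d_c = f_coarse - f_mid``, ``d_f = f_mid - f_fine`` and
    ``s = sign(d_c / d_f)`` by fixed-point iteration.  On a noiseless
    power-law series ``f = f_inf + C * h**p`` this recovers ``p`` for any
    admissible refinement factors.  A negative difference ratio (oscillatory
    convergence) is flagged on the result, never returned as a silent NaN.
    """
    if r_coarse <= 1 or r_fine <= 1:
        raise ValueError("refinement factors must be > 1")
    d_c = f_coarse - f_mid
    d_f = f_mid - f_fine
    if d_c == 0 or d_f == 0:
        raise ValueError("successive QoI differences must be nonzero")
    ratio = d_c / d_f
    s = 1.0 if ratio > 0 else -1.0
    ln_ratio = log(abs(ratio))
    ln_rf = log(r_fine)

    def residual(p: float) -> float:
        return ln_ratio + log((r_fine**p - s) / (r_coarse**p - s)) - p * ln_rf

    # fixed point p <- |ln_ratio + q(p)| / ln(r_fine), damped; the map is not
    # contractive far from the root, so a bracketed solve backs it up
    p = 1.0
    for _ in range(max_iter):
        try:
            p_new = abs(ln_ratio + log((r_fine**p - s) / (r_coarse**p - s))) / ln_rf
        except (ValueError, OverflowError):
            break
        if not 0 < p_new < P_MAX:
            break
        if abs(p_new - p) < tol:
            return OrderEstimate(value=p_new, oscillatory=s < 0)
        p = 0.5 * (p + p_new)

    grid = np.linspace(1e-4, P_MAX, 800)
    vals = []
    for g in grid:
        try:
            vals.append(residual(g))
        except (ValueError, OverflowError):
            vals.append(np.nan)
    vals = np.asarray(vals)
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if np.isfinite(a) and np.isfinite(b) and a * b <= 0:
            from scipy.optimize import brentq

            root = brentq(residual, grid[i], grid[i + 1], xtol=tol)
            return OrderEstimate(value=float(root), oscillatory=s < 0)
    raise RuntimeError(
        "observed-order solve did not converge: no root of the order "
        f"relation found in (0, {P_MAX}]"
    )


def gci_value(
    eps_mn: float, r: float, p: float, safety_factor: float = 1.25
) -> float:
    """Grid convergence index ``100 * Fs * eps_mn / (r**p - 1)`` [%]."""
    if r <= 1 or p <= 0:
        raise ValueError("need r > 1 and p > 0")
    denom = r**p - 1.0
    if denom <= 0:
        raise ValueError("r**p - 1 must be positive")
    return 100.0 * safety_factor * eps_mn / denom


def asymptotic_ratio(
    gci_coarse_pair: float, gci_fine_pair: float, r_coarse_pair: float, p: float
) -> float:
    """Asymptotic-range indicator ``GCI_c / (r_c**p * GCI_f)`` (~1 is good)."""
    if gci_fine_pair <= 0:
        raise ValueError("fine-pair GCI must be > 0")
    return gci_coarse_pair / (r_coarse_pair**p * gci_fine_pair)


@dataclass(frozen=True)
class GciCase:
    """One consecutive mesh triplet of a GCI study.

    ``pair_labels``, ``refinement_factors``, ``relative_errors`` and ``gci``
    are (coarse-pair, fine-pair) tuples; ``gci`` is in percent.
    """

    pair_labels: tuple
    refinement_factors: tuple
    observed_order: float
    oscillatory: bool
    relative_errors: tuple
    gci: tuple
    asymptotic_ratio: float


@dataclass(frozen=True)
class GciReport:
    cases: tuple
    recommended_mesh: str | None
    error_threshold: float


def analyze_series(
    series: MeshSeries,
    dim: int = 3,
    error_threshold: float = 0.03,
) -> GciReport:
    """Full GCI analysis: one :class:`GciCase` per consecutive mesh triplet.

    Also reports the recommended mesh: the coarsest mesh whose relative
    error to the next finer mesh falls below ``error_threshold`` (further
    refinement buys less than that).
    """
    nc, f, labels = series.cell_counts, series.qoi, series.labels
    r_pairs = [
        refinement_factor(nc[i], nc[i + 1], dim=dim) for i in range(len(nc) - 1)
    ]
    eps_pairs = [relative_error(f[i], f[i + 1]) for i in range(len(nc) - 1)]

    cases = []
    for i in range(len(nc) - 2):
        if f[i] == f[i + 1] or f[i + 1] == f[i + 2]:
            # grid-converged (or stalled) triplet: no order is observable
            order = OrderEstimate(value=float("nan"), oscillatory=False)
            gci_c = gci_f = ratio = float("nan")
            if f[i] == f[i + 1] and f[i + 1] == f[i + 2]:
                gci_c = gci_f = 0.0
        else:
            order = observed_order(
                f[i], f[i + 1], f[i + 2], r_coarse=r_pairs[i], r_fine=r_pairs[i + 1]
            )
            gci_c = gci_value(
                eps_pairs[i], r_pairs[i], order.value, series.safety_factor
            )
            gci_f = gci_value(
                eps_pairs[i + 1], r_pairs[i + 1], order.value, series.safety_factor
            )
            ratio = asymptotic_ratio(gci_c, gci_f, r_pairs[i], order.value)
        cases.append(
            GciCase(
                pair_labels=(
                    f"{labels[i]}-{labels[i + 1]}",
                    f"{labels[i + 1]}-{labels[i + 2]}",
                ),
                refinement_factors=(r_pairs[i], r_pairs[i + 1]),
                observed_order=order.value,
                oscillatory=order.oscillatory,
                relative_errors=(eps_pairs[i], eps_pairs[i + 1]),
                gci=(gci_c, gci_f),
                asymptotic_ratio=ratio,
            )
        )

    recommended = None
    for i, eps in enumerate(eps_pairs):
        if eps < error_threshold:
            recommended = labels[i]
            break
    return GciReport(
        cases=tuple(cases),
        recommended_mesh=recommended,
        error_threshold=error_threshold,
    )
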