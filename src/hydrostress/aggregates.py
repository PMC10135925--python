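"""Geometric cluster-size distribution of suspension-cell aggregates.

Suspension cultures of aggregating cell lines (HEK293 prominently) show a
cluster-size distribution — how many clusters contain 1, 2, 3, ... cells —
that follows a geometric law

    f(n) = (1 - p)**(n - 1) * p,   n = 1, 2, ...

where ``p`` is simultaneously the probability of a size-1 cluster and, in
the per-cell reading used experimentally, the fraction of cells that are
not part of an aggregate.  The two readings differ on finite data, so this
module reports three estimators side by side:

* per-cell singles fraction: (cells in size-1 clusters) / (all cells),
* per-cluster singles fraction: (size-1 clusters) / (all clusters),
* maximum-likelihood estimate ``p_hat = n_clusters / n_cells``
  (the reciprocal mean cluster size — the geometric-distribution MLE).

Goodness of fit uses Pearson's chi-square and the G (log-likelihood-ratio)
test against the geometric expectations, with tail classes pooled so every
expected count reaches a floor (default 5).

Finally, ``p`` is linearly linked to the volume-averaged Kolmogorov length
of the vessel, so a CFD characterisation predicts the aggregate
distribution in silico: ``p = intercept + slope * lambda_mean``, default
coefficients ``(0.92, -4589 m^-1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import sqrt

import numpy as np
from scipy import stats

__all__ = [
    "ClusterCounts",
    "GeometricModel",
    "LambdaLink",
    "DEFAULT_LINK",
    "GofResult",
    "geometric_pmf",
    "singles_fraction",
    "mle_p",
    "gof_chi2",
    "gof_g_test",
    "fit_lambda_link",
    "predict_p",
    "predict_distribution",
    "chain_length",
    "close_packed_diameter_3",
]


@dataclass(frozen=True)
class ClusterCounts:
    """Counts of clusters per integer size.

    ``sizes`` are the distinct cluster sizes (n >= 1) and ``counts`` the
    number of clusters observed at each size.
    """

    sizes: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes, dtype=int)
        counts = np.asarray(self.counts, dtype=float)
        if sizes.ndim != 1 or counts.shape != sizes.shape:
            raise ValueError("sizes and counts must be aligned 1-D arrays")
        if sizes.size == 0:
            raise ValueError("empty cluster table")
        if np.any(sizes < 1):
            raise ValueError("cluster sizes must be >= 1")
        if np.unique(sizes).size != sizes.size:
            raise ValueError("duplicate cluster sizes")
        if np.any(counts < 0):
            raise ValueError("counts must be >= 0")
        if counts.sum() <= 0:
            raise ValueError("at least one nonzero count required")
        order = np.argsort(sizes)
        object.__setattr__(self, "sizes", sizes[order])
        object.__setattr__(self, "counts", counts[order])

    @classmethod
    def from_dict(cls, mapping: dict) -> "ClusterCounts":
        sizes = np.array(sorted(mapping), dtype=int)
        return cls(sizes=sizes, counts=np.array([mapping[s] for s in sizes], float))

    @classmethod
    def from_samples(cls, samples) -> "ClusterCounts":
        sizes, counts = np.unique(np.asarray(samples, dtype=int), return_counts=True)
        return cls(sizes=sizes, counts=counts.astype(float))

    @property
    def total_clusters(self) -> float:
        return float(self.counts.sum())

    @property
    def total_cells(self) -> float:
        return float(np.dot(self.sizes, self.counts))


@dataclass(frozen=True)
class GeometricModel:
    """Geometric cluster-size model with success parameter ``p`` in (0, 1]."""

    p: float

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError("p must lie in (0, 1]")

    def pmf(self, n) -> np.ndarray | float:
        return geometric_pmf(self.p, n)


def geometric_pmf(p: float, n) -> np.ndarray | float:
    """Geometric probability ``(1 - p)**(n - 1) * p`` for sizes ``n >= 1``."""
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    n_arr = np.asarray(n)
    if not np.issubdtype(n_arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(n_arr, 1), 0)):
            raise ValueError("cluster sizes must be integers")
        n_arr = n_arr.astype(int)
    if np.any(np.atleast_1d(n_arr) < 1):
        raise ValueError("cluster sizes must be >= 1")
    out = (1.0 - p) ** (n_arr - 1) * p
    return float(out) if out.ndim == 0 else out


def singles_fraction(counts: ClusterCounts, weighting: str = "per_cell") -> float:
    """Fraction of singles — the direct, model-free estimate of ``p``.

    ``per_cell`` (default): cells occurring as size-1 clusters over all
    cells, matching the experimental reading of ``p`` as the fraction of
    non-aggregated cells.  ``per_cluster``: size-1 clusters over all
    clusters, the empirical size-1 probability.
    """
    singles = float(counts.counts[counts.sizes == 1].sum())
    if weighting == "per_cell":
        return singles / counts.total_cells
    if weighting == "per_cluster":
        return singles / counts.total_clusters
    raise ValueError("weighting must be 'per_cell' or 'per_cluster'")


def mle_p(counts: ClusterCounts) -> float:
    """Geometric MLE ``p_hat = n_clusters / n_cells`` (1 / mean size)."""
    return counts.total_clusters / counts.total_cells


def _pooled_observed_expected(
    counts: ClusterCounts, p: float, min_expected: float
) -> tuple[np.ndarray, np.ndarray]:
    """Observed/expected class counts with the open tail pooled to E >= floor.

    Classes run n = 1, ..., n_max-1 plus an open class [n_max, inf) so the
    expectations sum exactly to the number of clusters; classes are then
    merged from the tail upward until every expected count reaches the
    floor.
    """
    n_total = counts.total_clusters
    n_max = int(counts.sizes.max())
    observed = np.zeros(n_max)
    observed[counts.sizes - 1] = counts.counts
    ns = np.arange(1, n_max + 1)
    expected = n_total * geometric_pmf(p, ns)
    expected[-1] = n_total * (1.0 - p) ** (n_max - 1)  # open tail P(n >= n_max)

    obs_list = list(observed)
    exp_list = list(expected)
    # geometric expectations decay with n (up to the open tail), so pooling
    # from the tail until the last two classes clear the floor is sufficient
    while len(exp_list) > 1 and (
        exp_list[-1] < min_expected or exp_list[-2] < min_expected
    ):
        tail_e = exp_list.pop()
        tail_o = obs_list.pop()
        exp_list[-1] += tail_e
        obs_list[-1] += tail_o
    return np.asarray(obs_list), np.asarray(exp_list)


@dataclass(frozen=True)
class GofResult:
    """Goodness-of-fit result after tail pooling."""

    statistic: float
    df: int
    p_value: float
    n_bins: int
    observed: np.ndarray
    expected: np.ndarray


def _gof(
    counts: ClusterCounts,
    model: GeometricModel | float,
    kind: str,
    p_estimated: bool,
    min_expected: float,
) -> GofResult:
    p = model.p if isinstance(model, GeometricModel) else float(model)
    if counts.total_clusters < 10:
        raise ValueError("goodness-of-fit needs at least 10 clusters")
    observed, expected = _pooled_observed_expected(counts, p, min_expected)
    if observed.size < 2:
        raise ValueError("fewer than 2 classes remain after pooling")
    df = observed.size - 1 - (1 if p_estimated else 0)
    if df < 1:
        raise ValueError("no degrees of freedom left after pooling")
    if kind == "chi2":
        stat = float(np.sum((observed - expected) ** 2 / expected))
    else:
        pos = observed > 0
        stat = float(2.0 * np.sum(observed[pos] * np.log(observed[pos] / expected[pos])))
    return GofResult(
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        n_bins=observed.size,
        observed=observed,
        expected=expected,
    )


def gof_chi2(
    counts: ClusterCounts,
    model: GeometricModel | float,
    p_estimated: bool = True,
    min_expected: float = 5.0,
) -> GofResult:
    """Pearson chi-square test of the geometric model.

    ``p_estimated=True`` (default) reduces the degrees of freedom by one
    because the parameter was fitted to the same data; pass ``False`` when
    testing an externally fixed ``p``.
    """
    return _gof(counts, model, "chi2", p_estimated, min_expected)


def gof_g_test(
    counts: ClusterCounts,
    model: GeometricModel | float,
    p_estimated: bool = True,
    min_expected: float = 5.0,
) -> GofResult:
    """G test (log-likelihood ratio), ``G = 2*sum(O*ln(O/E))``.

    Asymptotically equivalent to the chi-square test on well-populated
    classes; same pooling and degrees-of-freedom conventions.
    """
    return _gof(counts, model, "g", p_estimated, min_expected)


@dataclass(frozen=True)
class LambdaLink:
    """Linear map from mean Kolmogorov length to the geometric parameter.

    ``p = intercept + slope * lambda_mean`` with ``slope`` in 1/m; the
    prediction is clamped to [0, 1].
    """

    intercept: float
    slope: float
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.intercept) or not np.isfinite(self.slope):
            raise ValueError("link coefficients must be finite")


#: Published linear link fitted across shaken and stirred cultivations.
DEFAULT_LINK = LambdaLink(intercept=0.92, slope=-4589.0)


def fit_lambda_link(lambda_means, p_values) -> LambdaLink:
    """Ordinary least squares of ``p`` on the mean Kolmogorov length."""
    lam = np.asarray(lambda_means, dtype=float)
    p = np.asarray(p_values, dtype=float)
    if lam.shape != p.shape or lam.ndim != 1 or lam.size < 2:
        raise ValueError("need >= 2 aligned (lambda_mean, p) points")
    if np.ptp(lam) == 0:
        raise ValueError("lambda values are degenerate (no spread)")
    fit = stats.linregress(lam, p)
    return LambdaLink(
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        r_squared=float(fit.rvalue**2),
    )


def predict_p(lambda_mean: float, link: LambdaLink = DEFAULT_LINK) -> float:
    """Predicted geometric parameter at a mean Kolmogorov length [m].

    Clamped to [0, 1] with a warning — the linear link is unphysical for
    very large lambda (p would go negative around 2e-4 m under the default
    coefficients).
    """
    if lambda_mean < 0:
        raise ValueError("lambda_mean must be >= 0")
    p = link.intercept + link.slope * lambda_mean
    if p < 0 or p > 1:
        warnings.warn(
            f"predicted p = {p:.4f} outside [0, 1]; clamped (linear link "
            "extrapolated beyond its physical range)",
            stacklevel=2,
        )
        p = min(max(p, 0.0), 1.0)
    return p


def predict_distribution(
    lambda_mean: float, link: LambdaLink = DEFAULT_LINK, n_max: int = 10
) -> np.ndarray:
    """Predicted cluster-size pmf over n = 1..n_max from the lambda link.

    Composition of :func:`predict_p` and :func:`geometric_pmf`; the partial
    sums reach ``1 - (1 - p)**n_max``.
    """
    p = predict_p(lambda_mean, link)
    if p == 0:
        raise ValueError("predicted p = 0: degenerate distribution")
    return geometric_pmf(p, np.arange(1, n_max + 1))


def chain_length(n: int, d_cell: float) -> float:
    """End-to-end length of an ``n``-cell linear chain, ``n * d_cell`` [m]."""
    if n < 1 or d_cell <= 0:
        raise ValueError("need n >= 1 and d_cell > 0")
    return n * d_cell


def close_packed_diameter_3(d_cell: float) -> float:
    """Circumscribing diameter of three coplanar mutually tangent spheres.

    ``d * (1 + 2/sqrt(3))``: the centres form an equilateral triangle of
    side ``d`` whose circumradius is ``d/sqrt(3)``, plus one cell radius on
    either side.  This is the compact extreme of a 3-cell aggregate; the
    chain (``3*d``) is the elongated extreme.
    """
    if d_cell < 0:
        raise ValueError("d_cell must be >= 0")
    return d_cell * (1.0 + 2.0 / sqrt(3.0))
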