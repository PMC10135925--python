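"""Growth-curve and cell-size reductions for batch cultivations.

Maximum specific growth rate (sliding-window log-linear fit), maximum viable
cell density with a viability gate, headline percent comparisons, and cell
diameter statistics in the 1-micrometre classes that imaging cell counters
report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GrowthSeries",
    "DiameterSample",
    "MuMaxResult",
    "VcdMaxResult",
    "DiameterStats",
    "mu_max",
    "vcd_max",
    "percent_increase",
    "diameter_stats",
]


@dataclass(frozen=True)
class GrowthSeries:
    """Batch growth time series: time [h], VCD [cells/mL], viability [%]."""

    time: np.ndarray
    vcd: np.ndarray
    viability: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.vcd, dtype=float)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("time and vcd must be aligned 1-D arrays")
        if t.size < 2:
            raise ValueError("need at least 2 time points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v <= 0):
            raise ValueError("VCD values must be > 0")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "vcd", v)
        if self.viability is not None:
            via = np.asarray(self.viability, dtype=float)
            if via.shape != t.shape:
                raise ValueError("viability must align with time")
            if np.any((via < 0) | (via > 100)):
                raise ValueError("viability must lie in [0, 100] %")
            object.__setattr__(self, "viability", via)


@dataclass(frozen=True)
class MuMaxResult:
    mu_max: float  # [1/h]
    window: tuple  # (t_start, t_end) [h]


def mu_max(series: GrowthSeries, window: float = 48.0) -> MuMaxResult:
    """Maximum specific growth rate [1/h] over sliding time windows.

    For every window anchored at an observed sample time and spanning at
    most ``window`` hours (default 48 h — the early exponential phase of a
    typical batch), the slope of an ordinary least-squares fit of
    ``ln(VCD)`` against time is computed; the maximum slope and its window
    are returned.  OLS on the log values is used instead of two-point
    ratios for noise robustness.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    t, log_v = series.time, np.log(series.vcd)
    best = -np.inf
    best_window = (t[0], t[-1])
    for i in range(t.size - 1):
        j = int(np.searchsorted(t, t[i] + window, side="right"))
        j = max(j, i + 2)  # degenerate window: fall back to the next point
        sub_t, sub_v = t[i:j], log_v[i:j]
        if sub_t.size == 2:
            slope = (sub_v[1] - sub_v[0]) / (sub_t[1] - sub_t[0])
        else:
            slope = float(stats.linregress(sub_t, sub_v).slope)
        if slope > best:
            best = slope
            best_window = (float(sub_t[0]), float(sub_t[-1]))
    return MuMaxResult(mu_max=float(best), window=best_window)


@dataclass(frozen=True)
class VcdMaxResult:
    vcd_max: float  # [cells/mL]
    time: float  # [h]
    gated: bool  # whether the viability floor was applied


def vcd_max(series: GrowthSeries, viability_floor: float = 95.0) -> VcdMaxResult:
    """Maximum VCD among points whose viability passes the floor.

    Late-process VCD artefacts tend to coincide with dropping viability, so
    the peak is taken over points with viability above ``viability_floor``
    (default 95 %).  Without viability data, or when no point passes, the
    unconditional maximum is returned with a warning.
    """
    mask = None
    if series.viability is not None:
        mask = series.viability > viability_floor
        if not mask.any():
            warnings.warn(
                f"no point passes the {viability_floor} % viability floor; "
                "falling back to the unconditional maximum",
                stacklevel=2,
            )
            mask = None
    if mask is None:
        idx = int(np.argmax(series.vcd))
        return VcdMaxResult(
            vcd_max=float(series.vcd[idx]), time=float(series.time[idx]), gated=False
        )
    sub_v, sub_t = series.vcd[mask], series.time[mask]
    idx = int(np.argmax(sub_v))
    return VcdMaxResult(vcd_max=float(sub_v[idx]), time=float(sub_t[idx]), gated=True)


def percent_increase(value: float, reference: float) -> float:
    """Percent change of ``value`` relative to ``reference``: 100*(a-b)/b."""
    if reference <= 0:
        raise ValueError("reference must be > 0")
    return 100.0 * (value - reference) / reference


@dataclass(frozen=True)
class DiameterSample:
    """Cell diameters [um] with the instrument's class width and range."""

    diameters: np.ndarray
    bin_width: float = 1.0
    instrument_range: tuple = (2.0, 40.0)

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        if d.ndim != 1 or d.size == 0:
            raise ValueError("diameters must be a nonempty 1-D array")
        lo, hi = self.instrument_range
        if np.any((d < lo) | (d > hi)):
            raise ValueError(
                f"diameters outside the declared instrument range [{lo}, {hi}] um"
            )
        object.__setattr__(self, "diameters", d)


@dataclass(frozen=True)
class DiameterStats:
    mean: float  # [um]
    sd: float  # [um]
    classes: np.ndarray  # integer class floors [um]
    counts: np.ndarray


def diameter_stats(sample: DiameterSample) -> DiameterStats:
    """Mean, standard deviation and 1-um-class histogram of cell diameters.

    The histogram floors each diameter to its left-closed class
    ``[m, m + bin_width)`` labelled by the class floor ``m``, mirroring
    imaging counters that only resolve integer size classes; binning an
    already class-valued sample is therefore a no-op.  The SD is the sample
    standard deviation (ddof = 1; 0 for a single value).
    """
    d = sample.diameters
    floors = (np.floor(d / sample.bin_width) * sample.bin_width).astype(float)
    classes, counts = np.unique(floors, return_counts=True)
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return DiameterStats(
        mean=float(np.mean(d)), sd=sd, classes=classes, counts=counts
    )
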