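"""Readers, writers and the end-to-end analysis pipeline.

All tabular formats are plain CSV/TSV with fixed SI-unit columns (CFD
exports are chronically ambiguous about units, so nothing is inferred):

* flow fields: ``volume,k,omega[,epsilon][,dudx,dudy,dudz,dvdx,dvdy,dvdz,
  dwdx,dwdy,dwdz]`` — [m^3], [m^2/s^2], [1/s], [m^2/s^3], [1/s];
* mesh series: ``mesh,cells,qoi``;
* cluster counts: ``size,count``;
* growth series: ``time_h,vcd[,viability]``.

Compressed (``.gz``) inputs are accepted transparently.  The pipeline
orchestrates field statistics, mesh verification, operating-point
correlations, aggregate-model fitting and the Kolmogorov-length prediction
into one JSON-serialisable report with provenance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregates import (
    ClusterCounts,
    DEFAULT_LINK,
    GeometricModel,
    LambdaLink,
    gof_chi2,
    gof_g_test,
    mle_p,
    predict_distribution,
    predict_p,
    singles_fraction,
)
from .gci import MeshSeries, analyze_series
from .growth import GrowthSeries, mu_max, vcd_max
from .hydro import (
    FlowField,
    FluidProperties,
    heterogeneity,
    lambda_volume_distribution,
    power_per_volume_from_dissipation,
    power_per_volume_from_torque,
    volume_fraction_below,
)

__all__ = [
    "read_flowfield",
    "write_flowfield",
    "read_mesh_series",
    "write_mesh_series",
    "read_cluster_counts",
    "write_cluster_counts",
    "read_growth",
    "write_growth",
    "PipelineConfig",
    "run_pipeline",
    "write_report",
]

_GRAD_COLUMNS = [
    "dudx", "dudy", "dudz",
    "dvdx", "dvdy", "dvdz",
    "dwdx", "dwdy", "dwdz",
]


def _read_table(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if ".tsv" in path.suffixes or path.suffix == ".tsv" else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    bad = df[required].apply(pd.to_numeric, errors="coerce").isna()
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        raise ValueError(f"{path.name}: non-numeric value in data row {row}")
    return df


def read_flowfield(
    path, total_volume: float | None = None, units_check: bool = True
) -> FlowField:
    """Read a per-cell turbulence field export (CSV/TSV, SI units).

    ``total_volume`` defaults to the sum of the cell volumes.  With
    ``units_check`` a coarse sanity warning is emitted when the implied
    dissipation would put Kolmogorov lengths far outside the 1e-6..1e-2 m
    band typical of lab-scale water systems (a common symptom of
    wrong-unit exports).
    """
    df = _read_table(path, ["volume", "k", "omega"])
    epsilon = df["epsilon"].to_numpy(float) if "epsilon" in df.columns else None
    grad_v = None
    if all(c in df.columns for c in _GRAD_COLUMNS):
        grad_v = df[_GRAD_COLUMNS].to_numpy(float).reshape(-1, 3, 3)
    field = FlowField(
        volume=df["volume"].to_numpy(float),
        k=df["k"].to_numpy(float),
        omega=df["omega"].to_numpy(float),
        total_volume=total_volume,
        epsilon=epsilon,
        grad_v=grad_v,
    )
    if units_check:
        eps = field.dissipation()
        pos = eps[eps > 0]
        if pos.size:
            lam = (0.6959e-6**3 / pos) ** 0.25  # nominal water viscosity
            if lam.min() < 1e-6 or lam.max() > 1e-2:
                warnings.warn(
                    "implied Kolmogorov lengths fall outside 1e-6..1e-2 m; "
                    "check that the export really is in SI units",
                    stacklevel=2,
                )
    return field


def write_flowfield(field: FlowField, path) -> None:
    data = {"volume": field.volume, "k": field.k, "omega": field.omega}
    if field.epsilon is not None:
        data["epsilon"] = field.epsilon
    if field.grad_v is not None:
        flat = field.grad_v.reshape(-1, 9)
        data.update({c: flat[:, i] for i, c in enumerate(_GRAD_COLUMNS)})
    pd.DataFrame(data).to_csv(path, index=False)


def read_mesh_series(path, safety_factor: float = 1.25) -> MeshSeries:
    df = _read_table(path, ["cells", "qoi"])
    labels = (
        tuple(str(m) for m in df["mesh"]) if "mesh" in df.columns else None
    )
    return MeshSeries(
        cell_counts=tuple(df["cells"].astype(float)),
        qoi=tuple(df["qoi"].astype(float)),
        safety_factor=safety_factor,
        labels=labels,
    )


def write_mesh_series(series: MeshSeries, path) -> None:
    pd.DataFrame(
        {"mesh": series.labels, "cells": series.cell_counts, "qoi": series.qoi}
    ).to_csv(path, index=False)


def read_cluster_counts(path) -> ClusterCounts:
    df = _read_table(path, ["size", "count"])
    return ClusterCounts(
        sizes=df["size"].to_numpy(int), counts=df["count"].to_numpy(float)
    )


def write_cluster_counts(counts: ClusterCounts, path) -> None:
    pd.DataFrame({"size": counts.sizes, "count": counts.counts}).to_csv(
        path, index=False
    )


def read_growth(path) -> GrowthSeries:
    df = _read_table(path, ["time_h", "vcd"])
    viability = (
        df["viability"].to_numpy(float) if "viability" in df.columns else None
    )
    return GrowthSeries(
        time=df["time_h"].to_numpy(float),
        vcd=df["vcd"].to_numpy(float),
        viability=viability,
    )


def write_growth(series: GrowthSeries, path) -> None:
    data = {"time_h": series.time, "vcd": series.vcd}
    if series.viability is not None:
        data["viability"] = series.viability
    pd.DataFrame(data).to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """End-to-end analysis configuration.

    Any of the input paths may be omitted; the corresponding stage is
    skipped.  ``fluid`` holds the liquid properties; ``lambda_thresholds``
    [m] are the critical eddy sizes for volume-fraction reporting (cell
    diameter and 3-cell cluster sizes by default); the lambda link predicts
    the aggregate distribution from the field's mean Kolmogorov length.
    """

    flowfield: str | None = None
    mesh_series: str | None = None
    cluster_counts: str | None = None
    growth: str | None = None
    fluid: FluidProperties | None = None
    torque: float | None = None  # [N m], enables the torque P/V route
    frequency: float | None = None  # [1/s], rotation/shaking frequency
    lambda_thresholds: tuple = (15.5e-6, 33.4e-6, 46.5e-6)
    safety_factor: float = 1.25
    gof_alpha: float = 0.05
    link: LambdaLink = dc_field(default_factory=lambda: DEFAULT_LINK)
    predict_n_max: int = 10
    seed: int | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.gof_alpha < 1:
            raise ValueError("gof_alpha must lie in (0, 1)")
        if self.safety_factor <= 1:
            raise ValueError("safety_factor must be > 1")
        for name in ("flowfield", "mesh_series", "cluster_counts", "growth"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} input not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "fluid" in raw and raw["fluid"] is not None:
            raw["fluid"] = FluidProperties(**raw["fluid"])
        if "link" in raw and raw["link"] is not None:
            raw["link"] = LambdaLink(**raw["link"])
        if "lambda_thresholds" in raw and raw["lambda_thresholds"] is not None:
            raw["lambda_thresholds"] = tuple(raw["lambda_thresholds"])
        return cls(**raw)


def _hydro_stage(config: PipelineConfig) -> dict:
    fluid = config.fluid
    if fluid is None:
        raise ValueError("hydrodynamics stage requires fluid properties")
    field = read_flowfield(config.flowfield)
    dist = lambda_volume_distribution(field, fluid)
    out = {
        "power_per_volume_dissipation": power_per_volume_from_dissipation(
            field, fluid
        ),
        "mean_dissipation": power_per_volume_from_dissipation(field, fluid)
        / fluid.density,
        "heterogeneity": heterogeneity(field),
        "lambda_mean": dist.mean,
        "lambda_median": dist.median,
        "quiescent_volume": dist.quiescent_volume,
        "volume_fraction_below": {
            f"{thr:.3e}": {
                "fraction": (vb := volume_fraction_below(field, fluid, thr)).fraction,
                "absolute_volume": vb.absolute_volume,
            }
            for thr in config.lambda_thresholds
        },
        "lambda_histogram": {
            "bin_edges": dist.bin_edges.tolist(),
            "volume_fraction": dist.volume_fraction.tolist(),
        },
    }
    if config.torque is not None and config.frequency is not None:
        out["power_per_volume_torque"] = power_per_volume_from_torque(
            config.frequency, config.torque, field.total_volume
        )
    return out


def _gci_stage(config: PipelineConfig) -> dict:
    series = read_mesh_series(config.mesh_series, config.safety_factor)
    report = analyze_series(series)
    return {
        "cases": [
            {
                "pairs": c.pair_labels,
                "refinement_factors": c.refinement_factors,
                "observed_order": c.observed_order,
                "oscillatory": c.oscillatory,
                "relative_errors": c.relative_errors,
                "gci_percent": c.gci,
                "asymptotic_ratio": c.asymptotic_ratio,
                "asymptotic": bool(abs(c.asymptotic_ratio - 1.0) < 0.15),
            }
            for c in report.cases
        ],
        "recommended_mesh": report.recommended_mesh,
    }


def _aggregates_stage(config: PipelineConfig, lambda_mean: float | None) -> dict:
    counts = read_cluster_counts(config.cluster_counts)
    p_cell = singles_fraction(counts, "per_cell")
    p_cluster = singles_fraction(counts, "per_cluster")
    p_hat = mle_p(counts)
    chi2 = gof_chi2(counts, GeometricModel(p_cell))
    g = gof_g_test(counts, GeometricModel(p_cell))
    out = {
        "p_singles_cell": p_cell,
        "p_singles_cluster": p_cluster,
        "p_mle": p_hat,
        "chi2": {"statistic": chi2.statistic, "df": chi2.df, "p_value": chi2.p_value},
        "g_test": {"statistic": g.statistic, "df": g.df, "p_value": g.p_value},
        "geometric_rejected": bool(chi2.p_value < config.gof_alpha),
    }
    if lambda_mean is not None and np.isfinite(lambda_mean):
        out["predicted_p"] = predict_p(lambda_mean, config.link)
        out["predicted_pmf"] = predict_distribution(
            lambda_mean, config.link, config.predict_n_max
        ).tolist()
    return out


def _growth_stage(config: PipelineConfig) -> dict:
    series = read_growth(config.growth)
    mu = mu_max(series)
    peak = vcd_max(series)
    return {
        "mu_max": mu.mu_max,
        "mu_max_window": mu.window,
        "vcd_max": peak.vcd_max,
        "vcd_max_time": peak.time,
        "viability_gated": peak.gated,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage and return one JSON-serialisable report.

    Stage order mirrors the physical causality: field statistics first (the
    mean Kolmogorov length feeds the aggregate prediction), then mesh
    verification, aggregate-model fitting and growth metrics.  Failures
    abort with the stage name attached.  The report is deterministic for a
    fixed configuration.
    """
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "inputs": {
                name: getattr(config, name)
                for name in ("flowfield", "mesh_series", "cluster_counts", "growth")
                if getattr(config, name) is not None
            },
        }
    }
    lambda_mean = None
    stages = [
        ("hydrodynamics", config.flowfield, _hydro_stage),
        ("gci", config.mesh_series, _gci_stage),
        ("aggregates", config.cluster_counts, None),
        ("growth", config.growth, _growth_stage),
    ]
    for name, enabled, fn in stages:
        if enabled is None:
            continue
        try:
            if name == "aggregates":
                report[name] = _aggregates_stage(config, lambda_mean)
            else:
                report[name] = fn(config)
            if name == "hydrodynamics":
                lambda_mean = report[name]["lambda_mean"]
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    return report


def write_report(report: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
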