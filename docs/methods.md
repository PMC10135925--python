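# Methods

This note documents the models implemented in `hydrostress`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic generators do and do not emulate, and the numerical choices made
where the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Hydrodynamic field statistics (`hydro`)

**Model.** A CFD export is a set of finite-volume cells with control volume
V_i, turbulent kinetic energy k_i and specific dissipation rate ω_i. Under
k–ω-family closures the dissipation rate is not transported directly, so it
is reconstructed as ε_i = β\*·k_i·ω_i with the standard model constant
β\* = 0.09. All statistics are volume weighted because CFD meshes are
unstructured: q̄ = Σq_i·V_i / ΣV_i. The specific power input follows either
from a torque, P/V = 2πnM/V, or from the field, P/V = ρ·ε̄; the two differ
in practice (the resolved-dissipation route is typically 30–50 % low
because numerical dissipation is unresolved), so both are exposed and both
are reported by the pipeline when a torque is available.

**ε-source precedence.** A provided ε column always wins over (k, ω);
per-record mixing is rejected. `fill_epsilon(force=True)` is the only way
to overwrite a provided column.

**Quiescent cells.** ε = 0 yields an infinite Kolmogorov length. Such cells
keep their volume: they are clamped into the topmost histogram bin and
reported as a `quiescent_volume` diagnostic (silently dropping them would
break the sum-to-one invariant of the volume fractions). The volume-weighted
mean and median λ̄_k are computed over the finite values only. A warning is
emitted whenever quiescent volume exists.

**Volume bookkeeping.** Exported subsets (e.g. the liquid phase of a
two-phase field) routinely lose cells, so ΣV_i may undershoot the declared
total volume V. Within 10⁻⁶ relative this is silent; up to 10⁻² it warns;
beyond that it is an error. All weighted reductions normalise by ΣV_i; only
`volume_fraction_below` converts its fraction to an absolute volume using
the declared V.

**Binning.** The default λ histogram uses 200 logarithmic bins spanning
[min λ/1.05, max λ·1.05] — dissipation spans decades, so log bins resolve
both tails; no published binning exists to copy. The heterogeneity
Φ = ε_max/ε̄ uses the raw cell-wise maximum by default; since single-cell
outliers dominate CFD maxima, a percentile variant (e.g. 99.9) is available
behind a keyword.

## Mesh verification (`gci`)

Refinement factors come from cell counts as r = (n_fine/n_coarse)^{1/3}
(volumetric meshes; a `dim=2` mode exists). The relative error is
normalised by the **coarser** value, ε_mn = |f_c − f_f|/|f_c| — this
convention, not the fine-normalised alternative, reproduces the published
worked tables the test suite pins. The index is
GCI = 100·F_s·ε_mn/(r^p − 1) with F_s = 1.25, and the asymptotic-range
check is GCI_coarse/(r_coarse^p·GCI_fine) ≈ 1.

**Observed order.** For non-constant r the order solves
ln|d_c/d_f| + ln((r_f^p − s)/(r_c^p − s)) = p·ln r_f, with s the sign of
the difference ratio (oscillatory convergence is flagged on the result, not
returned as NaN). A damped fixed-point iteration is tried first; because
that map is not contractive far from the root, a bracketed root scan with
Brent's method over p ∈ (0, 40] backs it up. On noiseless power-law series
f = f_∞ + C·h^p the solve recovers p to 10⁻⁶ for any r ∈ [1.1, 1.3]; this
synthetic recovery is the tested contract, since published observed-order
entries are generally not reproducible from rounded table values.

**Recommended mesh.** The coarsest mesh whose relative error to the next
refinement falls below a threshold (default 3 %): beyond it, refinement
buys less than the threshold while costing substantially more.

Grid-converged triplets (zero successive differences) yield a case with
zero errors and an undefined (NaN) order rather than an exception.

## Operating-point correlations (`correlations`)

**In-phase criteria.** An orbitally shaken flask only receives the nominal
power while its liquid sickle rotates in phase with the table. The axial
Froude number is implemented as Fra = (2πn)²·(d₀/2)/g (threshold 0.4) and
the phase number as Ph = (d₀/d)·(1 + 3·log₁₀ Re_film) (threshold 1.26)
with Re_film = (ρnd²/η)·[1 − √(1 − (4/π)(V^{1/3}/d)²)]². The +3 sign is
pinned by the requirement that the reference flask operating point be
comfortably in phase (the minus variant yields negative Ph). g defaults to
9.80665 m/s² and is configurable; the reference two-decimal Froude value is
insensitive to g within [9.78, 9.83].

**Flask power.** The unbaffled correlation P/V = Ne′·ρ·n³·d⁴/V^{2/3},
Ne′ = 70 Re⁻¹ + 25 Re⁻⁰·⁶ + 1.5 Re⁻⁰·², valid in phase (a warning is
emitted otherwise). No correlation exists for baffled flasks and none is
offered. At high Re the scaling approaches n^2.8.

**Stirred tank.** Re_m = ρNd_s²/η, Ne = P/(ρN³d_s⁵), v_tip = πd_sN, and a
tip-speed power fit P/V = a·v_tip^b with defaults (131.79, 2.7670) for a
3-blade segment impeller, d_s = 85 mm, at 4 L.

**Oxygen ceiling.** Equating transfer k_La(c\*₀₂ − c₀₂) and uptake c_x·q₀₂
bounds the viable cell density. Solubility uses the Tromans thermodynamic
correlation (valid 273–373 K), linear in the oxygen partial pressure. The
default gas phase is dry air at 1 atm (p₀₂ = 0.2095 atm); incubator
humidity and CO₂ enrichment can be switched on as multiplicative dilution
of the oxygen mole fraction (Buck equation for the water vapour pressure),
but are off by default — the result is then an upper-end estimate, and the
computed ceiling is an order-of-magnitude screen, not a prediction.

## Aggregate-size model (`aggregates`)

**Model.** Cluster sizes follow f(n) = (1−p)^{n−1}·p, n ≥ 1. The parameter
p is read both as the probability of a size-1 cluster and as the fraction
of cells not in aggregates; on finite data these differ, so three
estimators are always distinguishable:

* per-cell singles fraction (default reading; matches the experimental
  "fraction of non-aggregated cells"),
* per-cluster singles fraction (the empirical size-1 probability),
* MLE p̂ = n_clusters/n_cells = 1/mean size.

**Goodness of fit.** Pearson χ² and the G statistic
(2ΣO·ln(O/E)) against the geometric expectations over classes
n = 1, …, n_max−1 plus an open tail [n_max, ∞), so expectations sum exactly
to the cluster count. Classes are pooled from the tail until the last two
expected counts reach a floor (default 5 — standard practice; geometric
expectations decay in n, so tail pooling suffices). Degrees of freedom are
classes − 1, reduced by one more when p was estimated from the same data
(the default assumption). Calibration is verified by simulation: the
empirical type-I error at nominal α = 0.05 stays within [0.03, 0.07] over
2000 replicates of 500 clusters.

**λ link.** p is modelled as a linear function of the volume-averaged
Kolmogorov length, p = intercept + slope·λ̄_k, default (0.92, −4589 m⁻¹) —
the published cross-vessel fit. `fit_lambda_link` refits by ordinary least
squares. Predictions are clamped to [0, 1] with a warning: the linear link
is an interpolation over roughly λ̄_k ∈ [5·10⁻⁵, 1.2·10⁻⁴] m and turns
unphysical near 2·10⁻⁴ m.

**Cluster geometry.** For the 3-cell aggregate, the compact extreme is the
circumscribing diameter of three coplanar tangent spheres, d·(1 + 2/√3),
and the elongated extreme is the chain, n·d. Close packing is defined only
for n = 3 (the case used to set critical eddy sizes); general-n packings
are out of scope.

## Growth metrics (`growth`)

μ_max is the maximum, over windows anchored at each sample time and
spanning at most 48 h (the typical early exponential phase), of the OLS
slope of ln(VCD) versus time; OLS rather than two-point ratios for noise
robustness, and a window that degenerates to fewer than two points falls
back to the adjacent pair. VCD_max is taken over points with viability
above 95 % (late VCD artefacts ride on dying cultures); without passing
points the unconditional maximum is returned with a warning. Cell
diameters are summarised by mean, sample SD, and a histogram of left-closed
1 µm classes labelled by their integer floor — imaging counters report
integer classes, and flooring makes re-binning idempotent.

## Synthetic data (`synthetic`)

Every generator is a pure function of its spec plus a seed (byte-identical
outputs), so tests need no external data. What they emulate, and what not:

* `gen_flowfield` — log-normal per-cell dissipation, the standard
  positively skewed model for agitated vessels. The volume-weighted mean is
  matched exactly (global rescale); the max/mean heterogeneity Φ is matched
  within 5 % by bisecting the log-normal shape parameter on a fixed
  standard-normal draw (Φ is monotone in the shape parameter; ≤100
  iterations). k is back-filled from a nominal mixing length L (default
  8.5 mm/10) as k = (εL)^{2/3}, ω = ε/(β\*k) — only the product k·ω is
  constrained, the split is a documented convention. The generator imposes
  two moments of the dissipation field and nothing else: no spatial
  correlation, no impeller-jet structure, no free surface. A green test on
  synthetic fields therefore establishes the correctness of the weighted
  reductions, not the realism of any particular vessel.
* `gen_clusters` — i.i.d. geometric draws; real samples may mix vessels or
  time points (the mixture-rejection test exploits exactly this).
* `gen_mesh_series` — f = f_∞ + C·h^p with h = n_c^{-1/3}, optional
  Gaussian noise; emulates a solver in its asymptotic range only.
* `gen_growth` — exponential to a peak (default μ = 0.025 h⁻¹, peak at
  120 h, sampled daily to 192 h, matching typical HEK293 batch kinetics),
  exponential decline after, multiplicative log-normal noise, viability
  decaying past the peak. No lag phase, no metabolite coupling.
* `gen_diameters` — truncated normal within the 2–40 µm instrument window
  (defaults 15.97 ± 2.79 µm); real size distributions have slightly heavy
  tails that this deliberately omits.

## Numerical choices and degenerate inputs

* Weighted-reduction identities are tested against explicit-loop oracles to
  10⁻¹² relative on 1000-cell random fields.
* Kolmogorov length at ε = 0 returns +∞ with a warning (configurable to
  raise); heterogeneity of an all-zero field raises.
* The observed-order solve uses tolerance 10⁻¹⁰ and at most 200 fixed-point
  iterations before the bracketed fallback; no silent NaNs anywhere in the
  GCI path.
* GOF tests require ≥10 clusters, ≥2 classes and ≥1 degree of freedom after
  pooling, and raise otherwise.
* The pipeline report is plain JSON with provenance (inputs, seed,
  version); identical configurations produce identical reports.

## Known limitations

* The package post-processes exported fields; it does not solve any flow
  equations, reconstruct free surfaces, or process PIV imagery.
* The λ → p link is a two-coefficient empirical law; extrapolation beyond
  the fitted λ̄_k range is clamped, not trusted.
* Published absolute CFD quantities (per-vessel power inputs, λ̄_k values,
  heterogeneities) cannot be recomputed without the original meshes and
  fields; the test suite covers them with property substitutes (oracle
  equalities, estimator consistency, calibration) rather than asserting
  absolute values it cannot derive.
* Time-resolved shaking-period averaging is reduced to equal-weight
  snapshot averaging of per-snapshot volume-weighted means; the alternative
  volume-and-time weighting is indistinguishable for the fields considered
  and is not implemented.
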