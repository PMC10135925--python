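# hydrostress

Bioreactor hydrodynamic-stress statistics and cell-aggregate size-distribution
modelling for suspension cell cultures.

## The problem

Aggregating suspension cell lines (HEK293 being the canonical case) are grown
in shaken flasks and stirred benchtop bioreactors. Two questions decide how
hard a vessel may be driven: does the turbulence damage cells, and how much
does it break up aggregates? Both are governed by the turbulent energy
dissipation rate ε and the Kolmogorov length

    λ_k = (ν³ / ε)^{1/4},

the smallest eddy scale — only eddies smaller than a cell or aggregate can
harm it. CFD supplies ε per finite-volume cell; this package does everything
downstream of the solver:

* **hydro** — volume-weighted field statistics: ε from k–ω fields
  (ε = β\*·k·ω, β\* = 0.09), specific power input P/V via torque (2πnM/V) or
  via ∫ρε dV, heterogeneity Φ = ε_max/ε̄, volume-related λ_k distributions
  and the volume fraction below a critical eddy size, Q-criterion vortex
  fields.
* **gci** — Richardson-extrapolation / grid-convergence-index mesh
  verification: refinement factors r = (n_fine/n_coarse)^{1/3}, observed
  order, GCI = 100·F_s·ε_rel/(r^p − 1), asymptotic-range ratios.
* **correlations** — shaken-flask in-phase criteria (phase number Ph > 1.26,
  axial Froude Fra = (2πn)²(d₀/2)/g > 0.4), the Büchs unbaffled-flask power
  correlation, stirred-tank Re_m, Newton number Ne = P/(ρN³d_s⁵), tip speed,
  tip-speed power fits, and the oxygen-transfer ceiling on cell density
  (c_x = k_La·(c*₀₂ − c₀₂)/q₀₂ with Tromans solubility).
* **aggregates** — the headline model: cluster sizes follow a geometric law
  f(n) = (1−p)^{n−1}·p where p is the fraction of non-aggregated cells;
  estimators (singles fractions, MLE p̂ = 1/mean size), χ² and G
  goodness-of-fit with tail pooling, and the linear link
  p = 0.92 − 4589 m⁻¹·λ̄_k that predicts the whole aggregate distribution
  from a CFD characterisation alone.
* **growth** — μ_max by sliding-window log-linear fits, viability-gated
  VCD_max, percent comparisons, 1 µm-class cell-diameter statistics.
* **synthetic** — seeded generators for every input (log-normal dissipation
  fields with prescribed mean and Φ, geometric cluster samples, power-law
  mesh series, batch growth curves, truncated-normal diameters).
* **io** — fixed-SI-unit CSV readers/writers and a one-call pipeline
  producing a single JSON report.

## Worked example

```python
import hydrostress as hs

water = hs.WATER_310K                      # 993.37 kg/m^3, 0.6959e-6 m^2/s
field = hs.gen_flowfield(hs.FieldSpec(
    n_cells=20_000, total_volume=4e-3,     # a 4 L stirred vessel
    mean_dissipation=63.0 / water.density, # 63 W/m^3 operating point
    heterogeneity=72.4, seed=1,
))
print(hs.power_per_volume_from_dissipation(field, water))  # 63.0  [W/m^3]
print(hs.heterogeneity(field))                             # 72.8  [-]
dist = hs.lambda_volume_distribution(field, water)
print(dist.mean * 1e6)                                     # 58.3  [um]
print(hs.predict_p(dist.mean))                             # 0.652
```

The last line is the point of the package: a mean Kolmogorov length of
58 µm predicts that ~65 % of viable cells will be single cells at peak
density, via the linear λ̄_k → p link and the geometric distribution. The
`examples/` directory holds one narrative script per capability
(`python examples/01_flowfield_statistics.py`, ...), each printing the
quantities it computes with a line on what they mean.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline worked-example quantity from scratch (the
axial Froude number of the reference shaken-flask operating point, evaluated
by running the `correlations` module) and writes it as JSON keyed by target
id.

## Layout

```
src/hydrostress/   hydro, gci, correlations, aggregates, growth, synthetic, io
tests/             unit + property tests, acceptance checks
examples/          one runnable narrative script per capability
docs/methods.md    models, assumptions, numerical choices, limitations
```
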