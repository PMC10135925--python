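"""Geometric cluster-size model: fitting, testing and in-silico prediction.

Draws a synthetic aggregate-size sample, fits the geometric model three
ways, tests the fit, and predicts the full distribution from the mean
Kolmogorov length of a vessel via the linear link.
"""

import numpy as np

import hydrostress as hs

# a baffled-flask-like sample: 65 % of cells non-aggregated
counts = hs.gen_clusters(n_clusters=8000, p=0.655, seed=7)

print(f"clusters: {counts.total_clusters:.0f}, cells: {counts.total_cells:.0f}")
print(f"p (per-cell singles fraction):    {hs.singles_fraction(counts):.3f}")
print(f"p (per-cluster singles fraction): "
      f"{hs.singles_fraction(counts, 'per_cluster'):.3f}")
print(f"p (maximum likelihood):           {hs.mle_p(counts):.3f}")

model = hs.GeometricModel(hs.mle_p(counts))
chi2 = hs.gof_chi2(counts, model)
g = hs.gof_g_test(counts, model)
print(f"chi-square: {chi2.statistic:6.2f} on {chi2.df} df, p = {chi2.p_value:.3f}")
print(f"G test:     {g.statistic:6.2f} on {g.df} df, p = {g.p_value:.3f}")
# With thousands of clusters even tiny departures become "significant";
# the p-values are reported, practical relevance is a separate judgement.

# in-silico prediction from CFD: mean Kolmogorov length -> p -> distribution
for lam, label in [(6.123e-5, "baffled flask"), (1.025e-4, "unbaffled flask")]:
    p_pred = hs.predict_p(lam)
    pmf = hs.predict_distribution(lam, n_max=5)
    print(
        f"\n{label}: lambda_mean = {lam * 1e6:.1f} um -> p = {p_pred:.3f}"
        f"\n  predicted cluster-size pmf (n=1..5): "
        + " ".join(f"{x:.3f}" for x in pmf)
    )
# Smaller mean eddies (higher power input) shear aggregates apart, raising
# the fraction p of single cells.
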