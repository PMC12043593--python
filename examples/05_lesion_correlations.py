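"""Vascular-territory covariance of regional lesion patterns.

Regions fed by the same vascular territory are lesioned together, which
makes their lesion-load columns correlate.  Such collinearity is why
mass-univariate lesion-symptom mapping struggles and a multivariate
attribution is needed; the correlation matrix documents it.
"""

from lesionmsa import SyntheticSpec, compute_lesion_correlations, generate

dataset, _ = generate(SyntheticSpec(n_patients=400, rho=0.7, seed=11))
corr = compute_lesion_correlations(dataset)

long = corr.to_long_frame().dropna()
strong = long[long.r.abs() > 0.3].sort_values("r", ascending=False)
print(f"pairs with |r| > 0.3: {len(strong)}")
print(strong.head(10).to_string(index=False))
# The strongest pairs are same-block (same territory) regions; the
# two-sided p-values come from the t distribution with n-2 df.
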