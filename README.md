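# tvegfuse

Collocation-based error estimation and MSE-optimal merging of gridded
vegetation transpiration (T) products, with a water-use-efficiency
partitioning benchmark for flux-tower validation.

## The problem

Global transpiration estimates from land-surface models and satellite-driven
schemes (GLDAS, GLEAM, PMLv2, ...) disagree substantially, and no gridded
ground truth exists to arbitrate.  Collocation analysis estimates each
product's *random error variance* without a reference, provided several
products observe the same latent signal.  Classic triple collocation (TC)
assumes all product errors are mutually uncorrelated — an assumption broken
when products share forcing data, which induces **error cross-correlation
(ECC)** and biases both the error estimates and any merging weights built
from them.

`tvegfuse` implements the ECC-aware tool chain:

1. **Error estimation.**  For products
   `x_i = α_i + β_i Θ + ε_i` observing a latent signal Θ:
   - classic TC (3 products, zero ECC):
     `σ²_εX = σ²_X − σ_XY σ_XZ / σ_YZ` and cyclic permutations;
   - extended collocation (4 products, declared non-zero ECC pairs,
     least-squares moment system);
   - **EIVD** (3 products + lag-1 instrumental variables): each product's
     lag-1 shifted series serves as its own instrument.  With serially white
     errors the lag-1 autocovariances satisfy `L_ii ∝ β_i²`, so
     `√(L_ii/L_jj) = β_i/β_j`; these ratios scale the cross-covariances into
     a 10-equation linear system solved by least squares for the
     sensitivities `β_i² σ²_Θ`, the error variances `σ²_εi`, and the error
     covariance `σ_εXεY` of the declared pair.
2. **Optimal merging.**  Given the error covariance matrix Σ, the weights
   minimising the merged error variance subject to `Σ ω_i = 1` are
   `W = Σ⁻¹1 / (1ᵀΣ⁻¹1)` with merged variance `(1ᵀΣ⁻¹1)⁻¹`; closed forms
   for the two-product and the three-product/one-correlated-pair cases are
   provided.  Products are rescaled to a common data space before weighting,
   and invalid estimates trigger explicit, recorded fallbacks.
3. **Benchmark partitioning.**  At flux towers, T/ET is estimated from
   underlying water-use efficiency `uWUE = GPP·√VPD / ET`: the *potential*
   value is an annual 95th-percentile through-origin regression slope, the
   *apparent* value a moving-window slope, and `T/ET = uWUE_a / uWUE_p`.
4. **Evaluation.**  RMSE, ubRMSE, MAE, relative bias, Pearson R and the
   modified Kling–Gupta efficiency; grouping by plant functional type;
   Theil–Sen trends with Mann–Kendall significance; latitudinal profiles.

A synthetic-data module generates truth signals, biased noisy products with
a prescribed error covariance (including ECC pairs), gridded netCDF fixtures
and flux-site records with known T/ET, so the whole chain is verifiable
end-to-end with no downloads.

## Worked example

```python
import numpy as np
from tvegfuse import synthetic, collocation, merging

truth = synthetic.simulate_truth(synthetic.TruthConfig(n_steps=20000, seed=42))
cov = np.array([[0.36, 0.10, 0.0], [0.10, 0.29, 0.0], [0.0, 0.0, 0.13]])
series = synthetic.simulate_products(
    truth, synthetic.ProductConfig(error_cov=cov, seed=43))

em = collocation.eivd_estimate(series, ("prod1", "prod2"))
print("error variances: ", em.error_variance.round(3))
print("ECC(prod1,prod2): %.3f" % em.ecc[("prod1", "prod2")])

ref = merging.choose_reference(em)
wcov = merging.rescale_covariance(em, ref)
w = merging.sanitize_weights(
    merging.optimal_weights(wcov, product_ids=em.product_ids),
    em, covariance=wcov)
print("weights:", {p: round(x, 3) for p, x in zip(w.product_ids, w.weights)})
print("predicted merged error variance: %.4f" % w.predicted_error_variance)
```

prints

```
error variances:  [0.355 0.287 0.132]
ECC(prod1,prod2): 0.312
weights: {'prod1': 0.152, 'prod2': 0.109, 'prod3': 0.739}
predicted merged error variance: 0.0975
```

The estimator recovers the prescribed error variances (0.36, 0.29, 0.13)
and the error cross-correlation (0.31) from the data alone; the weights
favour the most accurate product and the predicted merged error variance
(0.0975) is below the best single product's (0.13·(1.2)² in the reference
data space).  The measured MSE of the merged series against the truth in
that run is 0.0945 — within 3% of the prediction.

The gridded pipeline chains everything (`tvegfuse run config.yaml`) and
writes yearly files in the `Merged.Tveg.<year>.nc` convention with
variables `lat`, `lon`, `day`, `Ec`, alongside weight maps, a
dominant-product map and a JSON run report.  A CLI is included
(`tvegfuse simulate|estimate|weights|merge|partition|evaluate|run`).

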