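# miskit

Missing-data mechanism diagnosis and imputation benchmarking for numeric
tables.

Incomplete data are everywhere in biostatistics and epidemiology — dropped
follow-up visits, assay failures, skipped survey items. Whether an analysis
on such data is trustworthy depends on *why* the values are missing:

- **MCAR** (missing completely at random): missingness is independent of
  everything; complete-case analyses stay unbiased.
- **MAR** (missing at random): missingness depends only on *observed*
  values; model-based imputation can correct the bias.
- **MNAR** (missing not at random): missingness depends on the unobserved
  value itself; no purely data-driven fix exists, and knowing you are in
  this regime is essential.

`miskit` helps an analyst place a dataset in this taxonomy and pick an
imputation strategy, using three building blocks:

1. **Diagnosis.** Little's MCAR test: with the EM algorithm, fit the mean
   μ and covariance Σ of a multivariate normal to the incomplete data, then
   compare each missingness pattern's observed means against μ:

       d² = Σⱼ mⱼ (ȳ_obs,j − μ_obs,j)ᵀ (Σ_obs,j)⁻¹ (ȳ_obs,j − μ_obs,j)

   which is asymptotically χ² with df = Σⱼ pⱼ − p under MCAR. A
   Henze-Zirkler multivariate-normality check gates the test (warning only).
   If MCAR is rejected, each incomplete feature gets a MAR-vs-MNAR
   likelihood-ratio test on nested logistic models of its observedness
   indicator D: the MAR model uses the other features, the MNAR model adds
   the outcome Y (if present) or the feature itself; 2(l_MNAR − l_MAR) is
   referred to χ²(1).
2. **Imputation.** Mean/median/mode, KNN (nan-Euclidean distances), a
   round-robin iterative imputer with pluggable learners (OLS, lasso-CV,
   random forest, gradient boosting), and MICE with Rubin's pooling rules.
3. **Assessment.** Plausibility checks (range violations, observed-vs-imputed
   KS tests) and a mask-and-score protocol: hide 10–20% of the observed
   cells, re-impute with every candidate method, and rank methods by RMSE on
   the identical probe set, with a paired t-test for systematic bias.

## Worked example

Generate a dataset whose missingness depends on the values themselves
(10 correlated Gaussian features, ~30% self-dependent missingness), then
diagnose and benchmark it:

```python
from miskit import scenario_fixtures, combined_test, compare_methods, missing_summary

ds = scenario_fixtures(1)["mnar"]          # incomplete data + ground truth
s = missing_summary(ds.data)
print(f"total missing: {s.total_pct:.1f}%  patterns: {len(s.pattern_table)}")

rep = combined_test(ds.data, alpha=0.05, seed=1)
print(rep.overall_comment)
print(rep.to_frame().head(3).to_string(index=False))

cmp = compare_methods(ds.data, ["mean", "knn", "iterative"],
                      mask_fraction=0.15, seed=1)
print(cmp.to_frame().to_string(index=False))
```

Output:

```
total missing: 29.8%  patterns: 418
Little's test: mcar_rejected (p=0.00208). Feature-wise LRTs on 10 features: 0 MAR, 10 MNAR, 0 skipped.
feature  lrt_stat      p_value   p_adjusted conclusion skip_reason
     x1 99.653060 1.815741e-23 6.052471e-23       mnar        None
     x2 84.431048 3.978507e-20 4.420564e-20       mnar        None
     x3 61.862282 3.683378e-15 3.683378e-15       mnar        None
           method     rmse  bias_p_value  rank error
     simple(mean) 0.841110  3.829183e-01     3  None
 knn(k=5,uniform) 0.711137  1.452210e-18     2  None
iterative(linear) 0.596939  4.552106e-02     1  None
```

Reading it: Little's test rejects MCAR (p ≈ 0.002) and the feature-wise
LRTs flag all 10 features as MNAR — the correct verdict for this generator.
The comparison masks 15% of the observed cells; the iterative linear
imputer recovers them best (RMSE 0.60 vs 0.84 for mean imputation), as
expected with correlated features. Note the diagnosis matters: under MNAR
even the best-ranked imputer remains biased toward the observed part of
each distribution.

The same steps are available from the shell:

```sh
miskit simulate --mechanism mnar --n 1000 --p 10 --rate 0.30 --seed 1 -o sim.csv
miskit diagnose mechanism sim.csv --seed 1 --out mechanism.json
miskit compare sim.csv --methods mean,knn,iterative --seed 1
miskit impute sim.csv --method iterative -o completed.csv
```

## Documentation

`docs/methods.md` describes the statistical model behind each component,
the synthetic-data generators and their preset parameters, numerical
choices, and known limitations — including why the MNAR test's self
regressor uses a constant fill and what that implies for interpretation.
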