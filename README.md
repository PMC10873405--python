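# bofs — Bayesian-optimized feature selection

`bofs` is a benchmarking toolkit for a question that comes up constantly in
the analysis of high-dimensional molecular data (gene expression, methylation,
any samples × features matrix with p ≫ n): **does tuning a feature selector's
hyper-parameters with Bayesian optimization recover more of the truly relevant
features than AIC, cross-validation, or the package defaults?**

It provides, as a plain Python library:

- **Synthetic data with known ground truth.** Covariates `X ~ N(0, I_p)`;
  linear outcomes `Y = Xw + ε` with effect sizes
  `w_i = (−1)^{U_i} (5·ln(n)/√n + |Z_i|)` (every signal above the classical
  detectability floor), and non-linear outcomes
  `Y = Σ_{j≤p1} sin(X_j) + 1.8 Σ_{j>p0−p1} cos(X_j) + ε` with `p1 = p0/2`.
  Binary phenotypes are made by dichotomizing at the median.
- **A GP-UCB Bayesian optimizer** over box-bounded hyper-parameter spaces:
  uniform candidate sampling, a squared-exponential Gaussian-process
  surrogate, and the acquisition `AC(x) = μ(x) + κ·σ(x)`.
- **Six selectors** returning ranked feature lists: lasso and elastic net
  (objective `f_w + λρ‖w‖₁ + λ(1−ρ)/2‖w‖₂²`, λ and ρ tunable by BO / AIC /
  CV / defaults), gradient-boosting total-gain ranking (XGBoost), sure
  independence screening (marginal correlation), minimum-redundancy-
  maximum-relevance (`MI(y,x_i) − mean_{j∈S} MI(x_i,x_j)`), and sparse PLS
  discriminant analysis with 50-category response discretization.
- **A benchmark layer**: recall rate `|selected ∩ causal| / |causal|` swept
  over causal-set sizes, selection sizes and repetitions, plus a repeated
  70/30 train/test prediction stage (SVM / lasso / random forest / GBM
  scored by Pearson r and MSE) for matrices without ground truth.

## Worked example

```python
from bofs import SimulationConfig, simulate_dataset, select, recall_rate

ds = simulate_dataset(SimulationConfig(n=300, p=500, p0=20,
                                       effect_model="linear", seed=7))
for method, tuner in [("lasso", "CV"), ("sis", "none"), ("mrmr", "none")]:
    res = select(method, tuner, ds.X, ds.y, n_s=20, seed=0)
    print(method, tuner, recall_rate(res.top(20), ds.causal_indices))
```

prints

```
lasso CV 1.0
sis none 0.8
mrmr none 0.2
```

i.e. the CV-tuned lasso recovers all 20 causal features in its top 20, plain
correlation screening recovers 16, and MRMR — whose mutual-information
estimates are noisy for weak linear signals — recovers 4. The scripts in
`examples/` walk through each capability the same way (simulation, the
optimizer, selector comparison, BO-tuned selection, the recall study, the
prediction pipeline); each prints the numbers it computes and what they mean.

A thin CLI mirrors the library for shell use:

```bash
bofs simulate --n 1000 --p 5000 --p0 100 --model linear --seed 1 --out sim
bofs select --method lasso --tuner bo --n-select 100 --x sim_X.tsv --y sim_y.tsv --out sel.json
bofs benchmark --config study.yaml --out results/
```

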