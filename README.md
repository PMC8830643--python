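# caresim

Machine-learning surrogate modelling and sensitivity analysis for an
agent-based simulation of informal social care.

Agent-based models (ABMs) of social policy are expensive to analyse:
their input–output relationships are non-linear, sometimes jagged, and a
single run can take minutes, so Monte-Carlo-scale sensitivity analysis is
often impractical. A *surrogate model* — a fast regression trained on
simulator input/output pairs — makes detailed analyses affordable.
`caresim` packages that whole workflow as a reproducible pipeline:

1. **`caresim.abm`** — a deterministic-given-seed demographic simulator of
   care need and informal care supply. Ten swept policy parameters θ
   (care-need probabilities and age gradients, weekly care-hour supplies
   by employment status, the retirement age, kin-provision rates) drive a
   population simulated in yearly steps from 1860 to 2050; the scalar
   output is the per-capita annual cost of unmet care,
   `y = Σ unmet hours × 52 × price / population`.
2. **`caresim.design`** — space-filling designs over the ten parameter
   ranges: the Sobol low-discrepancy sequence (LP-tau) and a maximin
   Latin hypercube.
3. **`caresim.surrogates`** — nine regression methods (linear regression,
   decision tree, random forest, gradient-boosted trees, KNN, Gaussian
   process, linear/RBF SVM, and a deep tanh neural network) trained under
   a fixed protocol: 20% of runs held out for testing, 20% of the
   remainder for validation-based hyperparameter selection, and test MSE
   `(1/n) Σ (ŷᵢ − yᵢ)²` reported once per method.
4. **`caresim.analysis`** — z-score PCA with Kaiser + 70% retention and
   |loading| > 0.5 significance, and quasi-Monte-Carlo main effects: the
   main effect of input i is `E[ŷ | θᵢ = v]` over the other inputs, and
   `Sᵢ = Var(main effect) / Var(ŷ)` is its first-order variance share
   (validated against the analytic Sobol g-function).

It is aimed at simulation modellers who want to benchmark surrogate
methods on a controlled, fully specified testbed, and at anyone needing a
compact reference implementation of the design → simulate → fit → analyze
loop.

## Worked example

```python
import numpy as np
from caresim import CareParams, DemographyConfig, run_simulation, default_space
from caresim.design import lptau_design
from caresim.abm.engine import batch_run
from caresim.surrogates import SurrogateSpec, benchmark_all
from caresim.analysis import zscore, pca_with_retention

rec = run_simulation(CareParams(), DemographyConfig(), seed=1)
print(f"single run: cost = {rec.output:.1f} per person-year, "
      f"final population = {rec.finalPopulation}")

design = lptau_design(200)                       # 200-point LP-tau design
runs = batch_run(design, DemographyConfig(), seeds=0)

board = benchmark_all(runs, [
    SurrogateSpec("linear_regression"),
    SurrogateSpec("gradient_boosted_trees"),
    SurrogateSpec("svm_rbf"),
], split_seed=0)
for row in board.rows:
    print(f"{row.method:24s} test MSE = {row.mse_test:.3e}")

pca = pca_with_retention(zscore(runs.frame[list(default_space().names) + ["output"]]))
print(f"PCA: retained {pca.retained} components; "
      f"PC1 explains {pca.explained_pct[0]:.1f}%")
```

Output:

```
single run: cost = 1602.2 per person-year, final population = 437
linear_regression        test MSE = 6.467e+06
gradient_boosted_trees   test MSE = 5.515e+06
svm_rbf                  test MSE = 3.135e+06
PCA: retained 7 components; PC1 explains 17.6%
```

The single run prices unmet care at the default parameters. On the
200-run table the nonlinear surrogates already beat least squares (MSE is
in squared cost units; the cost scale is thousands, so an MSE of 3×10⁶
is an RMS error of ≈ 1,770 against an output spread of ≈ 0–30,000). The
PCA of inputs-plus-output needs seven components at this sample size —
no single direction dominates a quasi-random design with a complex
output — whereas a table driven by one latent direction collapses to a
single component (see the tests).

The same pipeline is scriptable from the shell:

```bash
caresim design --method lptau --n 200 --seed 1 --out design.csv
caresim simulate --design design.csv --seed 0 --out runs.csv
caresim fit --runs runs.csv --methods linear_regression,svm_rbf --seed 0 --out board.json
caresim analyze --runs runs.csv --method gradient_boosted_trees --seed 0 --out analysis.json
caresim pipeline --out study/          # the full four-batch study
```

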