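# Methods

## Overview

`caresim` is a self-contained testbed for surrogate modelling of
agent-based simulations. It couples a stylised demographic simulator of
informal social care (the data generator) with quasi-random experimental
design, a nine-method regression benchmark, and two variance analyses:
z-score PCA with component-retention rules, and quasi-Monte-Carlo main
effects with first-order variance shares. Everything downstream of the
simulator treats it as a black box `f(θ, seed) → cost`, where θ is the
ten-dimensional vector of swept care-policy parameters and the output is
the per-capita annual cost of *unmet* care need in the simulation's final
year.

## The simulator

### State and scheduling

Agents are stored column-wise in flat numpy arrays (id = array index, ids
never reused; births append). One simulated year applies, in a fixed
order: ageing; mortality; births; partnership formation; partnership
dissolution; home-leaving; household migration; employment transitions;
care-need progression; elderly parents moving in with adult children; care
allocation; cost accounting. All demographic draws come from a single
generator seeded by the run seed, and ties are broken by ascending agent
id, so a run is a pure function of (parameters, configuration, seed).

Care allocation draws from a second generator seeded by (run seed, year).
Allocation has no feedback on the demography — met care hours affect only
the cost output — so with its own stream the end-year cost is identical
whether or not intermediate years are allocated. Run drivers exploit this:
by default only the final year is allocated, roughly halving run time;
requesting the yearly cost series allocates every year and produces
bit-identical outputs.

### Demography

Mortality follows a Makeham–Gompertz annual hazard
`A + B·e^(C·age)` (defaults `A = 1e-4`, `B = 8e-6`, `C = 0.095`),
amplified by 5% per care-need level and capped at 1. Partnered women aged
17–42 give birth with probability 0.13/yr. Adults form partnerships via a
yearly matching pool (entry 0.12/yr, same-town matches first), dissolve
them at 0.015/yr (the male partner leaves to a new household), and single
adults leave the parental home at 0.3/yr. Households relocate at 0.04/yr
to towns drawn from a fixed 8×8 density surface peaked at the grid centre
(a stylised city-size gradient). Employment is a four-state process
(minor, employed, unemployed, retired) with entry at 16 (p = 0.75), job
loss 0.05/yr, re-employment 0.35/yr, and deterministic retirement at the
swept retirement age.

These constants are deliberately stylised rather than calibrated to any
national statistics; they were chosen (and fertility adjusted once, from
0.11 to 0.13) so that the default 400-agent population of 1860 is
near-stationary through 2050 — final populations across seeds fall within
0.5–1.5× the initial size. They live in `DemographyConfig` so tests can
pin or vary them.

### Care need, supply and allocation

Care need is a five-level absorbing ladder (weekly hours required: 0, 8,
16, 30, 80). From age 16, an agent's need rises one level per year with
probability `min(1, personCareProb · e^(age/S))`, where `S` is the
sex-specific age-scaling parameter (years): larger `S` means slower onset,
and the male default (18) below the female default (19) encodes earlier
male morbidity. Supply capacity depends on employment status (retired /
unemployed / employed adults offer `retiredHours` / `homeAdultHours` /
`workingAdultHours`; children 10–15 living with a parent offer
`childHours`), discounted by own need (level 1 halves capacity, level ≥ 2
removes it).

Allocation is two-pass. Within a household, carers' capacities are pooled
and assigned to needy members, highest need level first, until need or
capacity is exhausted. Then each parent/adult-child pair spanning two
households may provide care: with annual probability
`min(1, κ · baseCareProb)` (κ = 400 same town, 80 otherwise — defaults
give ≈ 0.08/yr within a town) the kin carer contributes half of their
remaining capacity, capped by remaining need. Met hours never exceed
required hours and no carer exceeds capacity (asserted property).
The yearly cost is `Σ unmet weekly hours × 52 × price (16.7/h) ÷ alive`,
i.e. unmet need priced, not total care expenditure.

Out-of-range swept parameters warn rather than fail: outside the sweep
ranges the population can collapse or explode, which is a legitimate
(if unhelpful) regime to explore.

### Known simplifications

No recovery from care need; no formal (paid) care channel; the economy is
reduced to employment states; parents-move-in matching uses a within-year
snapshot of kin links, so two merges in the same year can interact only
through their pre-merge households. The population is synthetic: passing
tests demonstrate the pipeline's correctness and the simulator's
contracts, not empirical validity for any real care system.

## Experimental design

Quasi-random designs use the Sobol sequence (scipy's standard direction
numbers) with the initial all-zero point skipped; batches of different
sizes take disjoint segments of the sequence so no two runs in a study
share a parameter vector. Points are scaled affinely onto the parameter
ranges; the retirement age is rounded to integer years after scaling.
A maximin Latin hypercube alternative starts from a random LHS and
hill-climbs with within-column swaps, accepting a swap only if the
minimum pairwise distance does not decrease (deterministic per seed).
Bitwise agreement with any external LP-tau implementation is not a goal;
the designs are equivalent in role, not in bit pattern.

## Surrogate benchmark

The split protocol holds the split fixed across all methods: 20% of rows
(floor) are the test set, 20% of the remainder (floor) the validation
set, the rest training. Hyperparameters are selected by validation MSE
only; the test set is touched once per method, for the reported MSE.

Defaults where a choice had to be made: decision tree with minimum leaf
size 5; random forest with 500 trees and 4 features per split; gradient
boosting with 500 depth-3 trees at shrinkage 0.05; KNN with k selected
from {3, 5, 7, 10}; SVMs (linear and RBF) over small logarithmic grids of
(C, ε[, γ]) with features and target standardised; Gaussian process with
an anisotropic squared-exponential kernel plus nugget, hyperparameters by
marginal-likelihood maximisation. The neural network is a tanh multilayer
perceptron — 10 inputs, k hidden layers of 50 units with k ∈ {1,…,12}
selected on validation, scalar output — trained with Adam at learning
rate 3e-4, L2 penalty 0.03, for up to 15,000 epochs. Feature and target
standardisation replaces the batch-normalisation layers of the reference
architecture; with standardised inputs the two play the same
conditioning role for a small fully-connected net, and scikit-learn's
trainer (used because it is the environment's MLP implementation) has no
internal batch-norm layer. Training times are wall-clock, informational
only.

Scale choices: tests and the acceptance script exercise the network at
3,000 epochs with a {2, 4}-layer grid. That is a problem-size reduction
for the qualitative ordering checks (where the observed margins are wide);
the 15,000-epoch, 1..12-layer protocol remains the default and is asserted
structurally.

## Variance analyses

**PCA.** Columns are z-scored with the sample (n−1) standard deviation
(a constant column is an error naming the column). The correlation matrix
is eigendecomposed; every component with eigenvalue > 1 is retained
(Kaiser), extending in order until cumulative explained variance reaches
70%. Loadings are reported as variable–component correlations
(eigenvector × √eigenvalue); a variable is significant on a component when
|loading| > 0.5, strictly. By default PCA runs on inputs plus output;
an inputs-only mode is available since either convention is defensible.

**Main effects.** For a fitted surrogate (any of the nine methods — the
estimator only needs `predict`), the main effect of parameter i at value v
is the mean prediction over a scrambled-Sobol sample of the other
parameters, uniform on their ranges (default 2¹³ draws). Grid values sit
at midpoints of equal-width bins so the curve's empirical variance is a
nearly unbiased estimate (bias factor 1 − 1/g² for g grid points) of the
main-effect variance; dividing by the prediction variance over the full
sample gives the first-order share. Shares are variance ratios and hence
invariant to affine rescaling of the output. The implementation is
validated against the Sobol g-function, whose first-order indices have
the closed form `V_i = (1/3)/(1+a_i)²`, `V = Π(1+V_i) − 1`,
`S_i = V_i/V`; at 2¹³ draws the maximum absolute index error is ≈ 0.003,
well inside the ±0.05 tolerance used in tests.

## Numerical and degenerate-input conventions

- Empty population: a year step is a no-op and the cost is 0 with a
  logged warning.
- Hazard and probability caps: all composed probabilities are clipped to 1.
- GP interpolation tests fix the nugget at 1e-8 with noise estimation off;
  the default GP estimates a noise level (simulator outputs are
  deterministic given the seed, but the seed varies across design rows, so
  the surrogate sees seed-to-seed variation as noise).
- CSV I/O writes floats at %.17g and reads with round-trip parsing, so
  design and run tables survive write/read bit-exactly.
- Splits require n ≥ 3; the validation set may be empty only if a caller
  bypasses the protocol deliberately.

## Problem sizes used in the test suite

The acceptance-level tests execute the full four-batch study (3,000
simulator runs at the default 1860–2050 horizon, ≈ 0.1 s per run), a
three-split surrogate comparison on the 800-run batch, 20-seed paired
monotonicity suites, and 100-table PCA oracle comparisons. Unit tests use
a 30-couple, 40-year configuration for run-level checks.
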