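# hetmix

Bayesian inference of cell-to-cell expression heterogeneity from
single-cell, pooled *k*-cell, or joint measurements, under an explicit model
of imperfect detection.

## The problem

Single-cell qPCR (and related assays) of a gene across a cell population
typically shows a bimodal picture: a fraction of cells express the gene
("ON" cells) while the rest are silent, and the ON cells themselves vary.
Three parameters summarize this heterogeneity per condition:

- **π** — the fraction of ON cells,
- **μ** — the mean log₂ expression of ON cells (Et units, Et = 40 − Ct),
- **σ** — the standard deviation of log₂ expression among ON cells.

Two obstacles make these hard to estimate. First, assays miss weakly
expressed transcripts: an observed zero may be a truly OFF cell *or* an ON
cell that escaped detection. Second, many designs measure random pools of
*k* cells ("stochastic profiling"), which convolves the single-cell signal.

## The model

True single-cell expression is a zero-inflated base-2 log-normal:
G = I·X with I ~ Bernoulli(π) and log₂X ~ Normal(μ, σ). The assay detects a
true amount g with logistic probability

    DP(g) = 1 / (1 + exp(−(log₂ g − c) / m)),

so the measured value is H = J(G)·G with J(G) ~ Bernoulli(DP(G)); a
non-detect is recorded as 0. A *k*-cell sample sums k independent cells
before detection; its positive part is a Binomial(k, π) mixture over the
number of ON cells in the pool, with each component's log-normal sum
approximated by a moment-matched log-normal (Fenton–Wilkinson). Single- and
k-cell log-likelihoods add, as do the two conditions of a comparative
design (which share the detection parameters c, m).

Inference is by random-walk Metropolis with truncated-Gaussian proposals
(all parameters live in a box; the truncation carries an explicit Hastings
correction), in three phases: scale adaptation, burn-in, and sampling.
Posteriors are summarized by the mean and the shortest 90% credible
interval. Fitted models are screened by posterior-predictive checks: data
simulated from 100 posterior draws must be statistically indistinguishable
(two-sample Anderson–Darling P ≥ 0.1) from the observed single- and k-cell
data for more than 75% of draws, and the posterior mean σ must not exceed 5.
Between-condition differences in any function of (π, μ, σ) — including the
population-average expression log₂E(G) = log₂π + μ + σ²ln2/2 and the
ON-fraction entropy — are reduced to half-space p-values and
Benjamini–Hochberg adjusted across genes. A deterministic grid-based
posterior scan (with detection fixed at known values) provides an MCMC-free
inference route used by the simulation benchmarks.

## Worked example

```python
import numpy as np
from hetmix import (CHParams, DetectionParams, GeneModel, MCMCConfig,
                    simulate_dataset, fit_single_condition, summarize,
                    assess_default)

truth = GeneModel(CHParams(pi=0.6, mu=10.0, sigma=1.0),
                  DetectionParams(c=9.0, m=0.25))
data = simulate_dataset(truth, n_single=200, n_kcell=200, k=10,
                        rng=np.random.default_rng(78))

cfg = MCMCConfig(adapt_max_iters=8000, burnin_iters=1000,
                 sample_iters=10_000, seed=4)
chain = fit_single_condition(data, cfg)
s = summarize(chain)
for i, name in enumerate(chain.param_names):
    print(f"{name:>5}: {s.mean[i]:6.3f}  90% CrI [{s.cri_lo[i]:.3f}, {s.cri_hi[i]:.3f}]")
print("assessment:", assess_default(chain, data, rng=11).passed)
```

Output:

```
   pi:  0.594  90% CrI [0.516, 0.648]
   mu: 10.009  90% CrI [9.794, 10.293]
sigma:  1.021  90% CrI [0.863, 1.151]
    c:  8.829  90% CrI [8.327, 9.232]
    m:  0.166  90% CrI [0.088, 0.271]
assessment: True
```

The posterior recovers the generating parameters (π = 0.6, μ = 10, σ = 1)
within the credible intervals. Note the inferred ON fraction (0.59) sits
above the raw single-cell detect fraction (0.51): the model attributes part
of the observed zeros to detection failures, since the fitted logistic
midpoint c ≈ 8.8 lies inside the ON-cell expression range. The
posterior-predictive assessment confirms the fitted model regenerates data
indistinguishable from the input.

A command-line surface wraps the same functionality:

```bash
hetmix simulate --difficulty medium --sensitivity good --n 1000 --seed 1 --out data.csv
hetmix fit --data data.csv --seed 1 --out fits/
hetmix assess --data data.csv --chains fits/ --seed 1 --out reports/
hetmix gridscan --difficulty low,medium,high --n 1000 --reps 10 --seed 0 --out bench/
```

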