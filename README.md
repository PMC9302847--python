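# ddrkit

Reliable estimation of neural population coding accuracy when trials are
scarce, via **decoding-based dimensionality reduction (dDR)**.

## The problem

Linear decoding analyses ask how well a population of N neurons
discriminates two experimental conditions. The standard discriminability
statistic is the squared d-prime, the discrete analog of Fisher
information:

    d'² = Δμᵀ w_opt,    w_opt = Σ⁻¹ Δμ,    Δμ = μ_a − μ_b

where μ_a, μ_b are the condition-mean response vectors and
Σ = ½(Σ_a + Σ_b) is the pooled trial-to-trial (noise) covariance.
Estimating w_opt requires estimating Σ — N(N+1)/2 parameters — and with
the 10–100 trials per condition typical of awake, behaving-animal
experiments the estimate is unreliable: full-rank decoders overfit badly
and validation d'² collapses.

dDR exploits the observation that shared neural variability is
low-dimensional. Instead of the full N-dimensional space, decoding is done
in a small subspace built from the quantities that matter for decoding and
that *can* be estimated from few trials:

* the **signal axis** Δμ/‖Δμ‖, and
* one or more **noise axes**: the leading eigenvector(s) e₁, e₂, … of the
  per-condition mean-centered covariance, orthogonalized against the
  signal axis (Gram–Schmidt; additional axes by deflation).

The leading eigenvector of a low-rank covariance is recoverable from far
fewer trials than the individual covariance entries, so d'² measured in
the dDR space is accurate and stable at sample sizes where full-rank
decoding has already broken down.

The package provides the dDR construction, the d'² decoding framework with
train/validation cross-validation, trial-averaged and single-trial PCA
baselines (taPCA / stPCA), a Gaussian population simulator with controlled
covariance eigenspectra (rank-1, rank-m, 1/n power law, independent), and
permutation / bootstrap resampling procedures — plus a CLI and four
packaged simulation experiments.

## Worked example

Simulate a 100-neuron population with a 1/n noise eigenspectrum and a
modest mean separation, then compare cross-validated d'² with and without
dDR at 25 trials per condition:

```python
import numpy as np
from ddrkit import (CovarianceSpec, make_population_model, sample_population,
                    ConditionPair, cross_validated_dprime, analytic_dprime_squared)

spec = CovarianceSpec(family="power_law", n_neurons=100,
                      total_shared_variance=20.0, eigenvector_seed=0)
model = make_population_model(spec, delta_mu_magnitude=4.0,
                              alignments=(0.3,), eps_indep=0.45, seed=0)
rs = sample_population(model, k=25, seed=1)

pair = ConditionPair("a", "b")
for reducer, kwargs in [("ddr", {"n_noise_dims": 1}), ("fullrank", {})]:
    res = cross_validated_dprime(rs, pair, reducer=reducer, seed=2, **kwargs)
    print(f"{reducer:9s} train d'2 = {res.dprime_sq_train:7.2f}   "
          f"validation d'2 = {res.dprime_sq_test:7.2f}")
print(f"ground-truth d'2 = {analytic_dprime_squared(model):.2f}")
```

Output:

```
ddr       train d'2 =   52.32   validation d'2 =   15.87
fullrank  train d'2 =    3.72   validation d'2 =    0.58
ground-truth d'2 = 26.38
```

Both decoders overfit (train > validation), but with only 25 trials the
full-rank decoder retains almost none of the true discriminability of
26.4 on held-out data, while the two-dimensional dDR space retains most
of it. At larger k the dDR validation value converges to the truth.

The same analyses are available from the shell:

```sh
ddrkit simulate --family power_law --n-neurons 100 --k 50 --seed 1 --out rs.csv
ddrkit decode --input rs.csv --label-a a --label-b b --reducer ddr
ddrkit bootstrap-compare --input rs.csv --label-a a --label-b b --comparison tapca
ddrkit experiment convergence --seed 1 --out results/
```

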