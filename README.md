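# espamarkov

Supervised classification of **noisy, time-ordered data** in the small-data
regime, by entropic learning with a Markov smoothness prior (the
**eSPA-Markov** method): the package jointly learns

* a fuzzy discretization of feature space into `K` clusters, each with
  per-dimension Gaussian emission parameters `(μ_{d,k}, σ_{d,k})`,
* an entropy-regularized probability vector `W` over the `D` features
  (built-in, supervised feature selection),
* a column-stochastic Bayesian classifier `Λ ∈ [0,1]^{M×K}` mapping clusters
  to the `M` labels, and
* a column-stochastic affiliation matrix `Γ ∈ [0,1]^{K×T}` whose evolution
  along the time axis is penalized for deviating from a Markov transition
  prior `P` (identity `P` enforces persistence / metastability).

Given a data matrix `X ∈ R^{D×T}` (columns are time points) and label
probabilities `Π ∈ [0,1]^{M×T}` (columns sum to 1; one-hot is a special
case), fitting minimizes, subject to simplex constraints on the columns of
`Γ` and `Λ` and on `W`,

```
ε_L/T · Σ_{d,k,t} W_d Γ_{k,t} ℓ(X_{d,t}; μ_{d,k}, σ_{d,k})     Gaussian likelihood
+ ε_E · Σ_d W_d log W_d                                        entropy of W
− ε_CL/T · Σ_{m,t} Π_{m,t} Σ_k log(Λ_{m,k}) Γ_{k,t}            classification (KL)
+ 1/T · Σ_{t<T} Σ_{k} (Γ_{k,t+1} − Σ_{k'} P_{k,k'} Γ_{k',t})²   Markov smoothness
```

where `ℓ` is the univariate Gaussian negative log-likelihood.  Because each
cluster carries a variance as well as a mean, the method separates regimes
with **overlapping means and different variances** — the case where
distance-based clustering fails.  Three of the four blocks have closed-form
conditional minimizers; the `Γ` block is a convex QP over a product of
per-time-point simplices, solved with a spectral projected gradient method
(SPG-QP).  When clusters and labels are in bijection (`K = M`) the entire
model is learned in **one shot**, without outer iteration.

Typical users: anyone segmenting noisy instrument traces with persistent
latent regimes — the bundled toy benchmark emulates raw nanopore sequencing
current, where each k-mer in the pore emits samples from its own current
distribution for a k-mer-specific dwell time.

## Worked example

One-shot learning on the nanopore-style toy: train on a trace simulated from
one random 40-base sequence, reconstruct the per-sample k-mer labels of a
trace from a *different* sequence.

```python
import numpy as np
from espamarkov import NanoporeToySpec, fit_oneshot, gen_nanopore_toy, predict

Xtr, Pitr, _ = gen_nanopore_toy(NanoporeToySpec(n_bases=40, seed=11))
Xte, Pite, _ = gen_nanopore_toy(NanoporeToySpec(n_bases=40, seed=22))

model, (eps_E, eps_L) = fit_oneshot(Xtr, Pitr)
pi_hat, gamma = predict(model, Xte, seed=0)

acc = np.mean(np.argmax(pi_hat, 0) == np.argmax(Pite, 0))
print(f"selected eps_L = {eps_L}, test accuracy = {acc:.3f}")
```

This prints

```
selected eps_L = 1, test accuracy = 0.978
```

97.8% of the ~1000 current samples in the unseen trace are assigned the
correct k-mer: the selected likelihood weight `eps_L = 1` balances the
Gaussian evidence for each current level against the Markov penalty, which
suppresses spurious single-sample label flips inside a dwell.

The same workflow is available from the shell:

```sh
espa-markov simulate nanopore --n-bases 40 --seed 11 --out train/
espa-markov oneshot --x train/X.tsv --pi train/Pi.tsv --out run/
espa-markov simulate example1 --sigma-ratio 3 --d 10 --t 3000 --seed 1 --out data/
espa-markov gridsearch --x data/X.tsv --pi data/Pi.tsv --k-grid 2 --out search/
```

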