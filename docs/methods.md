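# Methods

## Model

The package classifies time-ordered observations `X ∈ R^{D×T}` with label
probabilities `Π ∈ [0,1]^{M×T}` by minimizing the four-term objective shown
in the README over

* `Γ ∈ [0,1]^{K×T}` — fuzzy cluster affiliations, columns on the simplex;
* `μ, σ ∈ R^{D×K}` — per-cluster, per-dimension Gaussian emission
  parameters (the emission model is a product of univariate Gaussians, i.e.
  diagonal covariance);
* `Λ ∈ [0,1]^{M×K}` — column-stochastic cluster-to-label classifier;
* `W ∈ [0,1]^D` — feature weights on the simplex, regularized by entropy.

The classification term is the *relaxed* Kullback-Leibler discrepancy with
the logarithm moved inside the cluster sum (by Jensen's inequality,
`−log ΣΛΓ ≤ −Σ(log Λ)Γ`).  This relaxation is what gives the `Λ` and `W`
blocks closed-form minimizers; the un-relaxed form would require an
interior-point solve for `Λ` and is not implemented.

Assumptions worth stating plainly: emissions are conditionally independent
across dimensions given the cluster; regime structure is expressible through
a first-order Markov prior on the affiliation path; labels depend on the
data only through the cluster affiliation.

## Block-coordinate solution

Each outer iteration runs `Γ → (μ, σ) → Λ → W`:

* **Γ** minimizes `b'γ + (1/T)γ'Hγ` over the product of per-time simplices.
  `H = I_K⊗diag(0,1,…,1) + PᵀP⊗diag(1,…,1,0) + Pᵀ⊗OD + P⊗ODᵀ`
  (cluster-major vectorization, `OD` the superdiagonal −1 matrix) reproduces
  the Markov penalty exactly for any `P`; with `P = I` it is block diagonal
  with path-graph Laplacians.  `b` stacks the weighted Gaussian errors plus
  the classification errors with signs chosen so the quadratic model equals
  the full objective up to the Γ-independent entropy term (an identity
  asserted in the tests).
* **(μ, σ)** are affiliation-weighted means and population SDs — the
  M-step of a fuzzy, diagonal Gaussian mixture.
* **Λ** is the column-normalized label/affiliation co-occurrence `ΠΓᵀ`.
* **W** is `softmax(−ε_L b_W / (T ε_E))` with `b_W` the per-dimension
  affiliation-weighted NLL.  Note the `ε_L` factor: the likelihood block of
  the objective carries `ε_L/T`, so the exact conditional minimizer scales
  the softmax logits by `ε_L` as well (only the ratio `ε_L/ε_E` matters).

Every step is an exact conditional minimizer except `Γ`, which is solved
inexactly but warm-started at the incumbent, so the total loss is
monotonically non-increasing (asserted to 1e-9 slack in the tests).

### SPG-QP

The Γ-step QP is solved by spectral projected gradient: Barzilai-Borwein
step lengths safeguarded to `[1e-10, 1e10]`, Euclidean projection of every
iterate onto the feasible set (per-column sort-and-threshold simplex
projection, O(K log K)), and a nonmonotone Armijo line search with memory
10 evaluated in closed form on the exact 1-D quadratic.  Stopping: norm of
the projected gradient step below `tol`, default `1e-10·K·T` for standalone
solves.  This tight default is what makes independently started predictions
agree to ~1e-6 whenever the minimizer is unique (the linear term has a
component outside the image of `H`); inside the training loop a looser
`1e-8·K·T` is used, since the solve is repeated every outer iteration.
`max_iter` defaults to `10·K·T`.  For `K = 1` the constraints pin `Γ` to
the all-ones row and the solver returns it immediately.

## Fitting, prediction, one-shot learning

`fit` runs 10 random restarts by default (uniform random columns projected
to the simplex, seeded deterministically from `(seed, restart)`); outer
iteration stops when the relative loss decrease drops below 1e-8 or after
200 iterations; the restart with the lowest final loss wins.  A cluster
whose affiliation mass vanishes (< 1e-12) is reseeded at a random data
column with σ set to the data SD.  σ values are floored at 1e-6 (data
units) to keep the likelihood finite on degenerate clusters.  `K > T`,
non-finite input, and non-stochastic `Π` are rejected.

`predict` solves the Γ problem once on the new stretch with `ε_CL = 0`
(labels unavailable), keeping the trained `ε_L/T` weighting so the
likelihood/smoothness balance matches training, then returns `Π̂ = ΛΓ`.

`fit_oneshot` applies when clusters and labels are in bijection (`K = M`):
`Γ_train = Π`, `Λ = I` (which makes the classification term exactly zero),
`(μ, σ)` from one analytic update, and `W` in closed form per `ε_E`.  The
`(ε_E, ε_L)` pair is selected from a grid by solving one prediction-mode Γ
problem per pair on the training data and picking the pair minimizing
`‖Π − Γ*‖²_F` (ties to the earliest grid entry).  The per-pair solves use
`ε_CL = 0` because the selection emulates what prediction on unseen data
will do, and `Λ = I` makes the classification weight irrelevant during
training.

`grid_search` uses contiguous triple splitting (train/validation/test,
sizes within one of each other), fits every grid combination on the
training block, selects by validation AUC (score = positive label's row of
`Π̂`), and reports the selected model's test AUC.  The validation and test
predictions use independently derived random starts: with a weak likelihood
signal the predicted affiliation pattern retains a memory of its start, and
sharing one start across adjacent blocks would let validation selection
leak into the test score.

The default hyperparameter grid is
`ε_CL ∈ {1e-4, 1e-3, 1e-2}`, `ε_L ∈ {1e-5, …, 1e-1, 1, 2, 5, 10}`,
`ε_E ∈ {1e-4, …, 1e-1}`, `K ∈ {2, 3, 5}`.

### Feature standardization

The Gaussian likelihood rewards low-variance dimensions regardless of class
information (a U[0,1] noise dimension has lower NLL than an informative
dimension with per-state SDs 1 and 1/3), so on raw scales the entropic
feature selection would concentrate on whichever features are merely
small.  The pipeline level (`grid_search`, the CLI) therefore z-scores each
feature with training-block statistics by default and applies the same
transform at prediction; after standardization an informative dimension has
a strictly lower affiliation-weighted NLL than noise, and `W` concentrates
correctly.  The core `fit`/`predict` functions consume data as-is, so users
who need raw scales (e.g. the single-dimension nanopore trace, where
`W = (1)` is trivial) can bypass standardization.

## Synthetic generators

The generators are first-class, tested code; all are driven by
`numpy.random.default_rng` and fully reproducible from their spec + seed.

* **Two-state chain** — switch probability `ε = 0.01` per step
  (persistent regimes).  `pure-chain` mode simulates the chain literally;
  `block-dwell` mode alternates states with dwell lengths drawn uniformly
  from `[0.8c, 1.2c]`, `c = T/18` (about six alternations per third of the
  record), which guarantees both classes appear in every third — needed so
  contiguous triple splits always contain both labels.
* **Variance-switching regimes** — dimension 1 emits `N(0, σ_state²)` with
  `σ₁ = 1`, `σ₂ = 1/σ-ratio`; dimensions `2..D` are i.i.d. U[0,1] noise.
  σ-ratio 1 makes the regimes statistically identical (chance-level floor);
  which state becomes sharper as the ratio grows is a sign convention with
  no effect on separability.
* **Rotated bivariate regimes** — state 1 emits a centered bivariate
  Gaussian with covariance `diag(ε_thick, 1)`, default `ε_thick = 0.05`;
  state 2 is the same cloud rotated by `α ∈ (0, π/2]`.  Means coincide by
  construction; `α` controls separability.
* **Nanopore toy** — alphabet {A, B}, k-mer width 2.  Current means
  `(80, 100, 120, 140)` with SD 8 for AA/AB/BA/BB (2.5-SD level spacing,
  arbitrary picoampere-like units) and geometric dwell times with means
  `(40, 30, 15, 60)` samples, so 'BA' dwells are the shortest and 'BB' the
  longest.  These numeric defaults are this package's own choice — they
  realize the qualitative description of the process (distinct current
  level per k-mer, k-mer-specific dwell law) and are all overridable in the
  spec.

What the generators deliberately do **not** emulate: real nanopore traces
have level drift, 1/f noise, correlated samples within a dwell, and far
larger k-mer alphabets; real regime-switching series are rarely exactly
Gaussian per state.  Passing tests therefore demonstrate correctness of the
optimization and the method's qualitative claims (variance-based regime
separation, feature selection, persistence denoising), not performance on
any real instrument.

A delay-embedding utility (`takens_embed`, stacking each time point with
its `l` predecessors, default windows {10, 50, 100}) is provided for
benchmarking order-blind models; the method itself consumes unembedded
data.

## Evaluation

AUC is computed as the Mann-Whitney statistic (ties at half weight) via
scikit-learn; the positive class's row of `Π̂` is the ranking score.  AUC
is undefined and an error when a split contains a single class.

## Numerical conventions

`0·log 0 := 0` throughout; `log 0` under positive weight yields `+inf` in
the loss (never an exception) and a large finite penalty (−1e6) in the QP
linear term, which forces zero affiliation mass rather than breaking the
solver.  All losses are reported in nats.  Matrices are validated
column-stochastic to 1e-8 internally and 1e-6 at the I/O boundary.

## Benchmark scale

The chance-level control run by `scripts/acceptance.py` uses 10 datasets of
3×1000 points, a reduced sub-grid
(`ε_CL = 1e-3`, `ε_L ∈ {1e-4, 1e-2, 1}`, `ε_E ∈ {1e-3, 1e-1}`, `K = 2`)
and 3 restarts per fit — sizes chosen so a desk-scale run finishes in about
a minute while still averaging enough datasets for the mean test AUC to
concentrate near 0.5.  At σ-ratio 1 no hyperparameter choice can beat
chance, so the reduced grid does not change the expected outcome.

## Known limitations

* Diagonal (per-dimension) Gaussian emissions only; no general loss
  functions or full covariances.
* `P` is accepted as an arbitrary K×K prior but only `P = I` (persistence)
  is exercised by the benchmarks; `P` is never learned from data.
* Binary labels only in `grid_search`/AUC scoring (the core model supports
  any `M`).
* The one-shot path requires `K = M` and every label present in training.
* AUC on strongly smoothed predictions has few effective degrees of freedom
  when regimes are long-lived; single-split AUCs at chance level scatter
  widely, which is why the benchmark averages over datasets.
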