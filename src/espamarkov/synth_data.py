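"""Synthetic benchmark generators, delay embedding, and evaluation metrics.

Three generative processes exercise the method end to end without any
external data:

* **Variance-switching regimes** (:func:`gen_example1`): a persistent
  two-state Markov chain where both states emit zero-mean Gaussians that
  differ only in standard deviation -- the overlapping-means scenario where
  distance-based clustering fails.
* **Rotated bivariate regimes** (:func:`gen_example2`): both states emit a
  centered, anisotropic bivariate Gaussian; the second state's cloud is the
  first rotated by an angle ``alpha``, which controls separability.
* **Nanopore-inspired current trace** (:func:`gen_nanopore_toy`): a two-base
  alphabet read through a width-2 k-mer window; each of the four k-mers emits
  current samples from its own Gaussian for a k-mer-specific random dwell
  time -- a semi-Markov toy of raw nanopore sequencing signal.

Extra "uninformative" dimensions drawn i.i.d. from U[0, 1] can be appended
to the first two examples to probe feature selection.  Labels are always
exact one-hot, column-stochastic matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray
from sklearn.metrics import roc_auc_score

__all__ = [
    "TwoStateChainSpec",
    "Example1Spec",
    "Example2Spec",
    "NanoporeToySpec",
    "gen_two_state_path",
    "gen_example1",
    "gen_example2",
    "gen_nanopore_toy",
    "takens_embed",
    "auc_score",
    "triple_split",
    "states_to_onehot",
]


@dataclass(frozen=True)
class TwoStateChainSpec:
    """A persistent two-state chain: P(switch) = eps_trans each step.

    ``mode='pure-chain'`` simulates the chain literally; ``mode='block-dwell'``
    alternates the states deterministically with stochastic dwell lengths
    chosen so that both states are visited in every third of the sequence
    (so each block of a contiguous triple split contains both classes).
    """

    T: int
    eps_trans: float = 0.01
    mode: str = "pure-chain"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.eps_trans < 0.5:
            raise ValueError("eps_trans must lie in (0, 0.5)")
        if self.mode not in ("pure-chain", "block-dwell"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.T < 2:
            raise ValueError("T must be >= 2")


@dataclass(frozen=True)
class Example1Spec:
    """Variance-switching regimes: state SDs (1, 1/sigma_ratio), D-1 noise dims."""

    sigma_ratio: float = 2.0
    D: int = 1
    chain: TwoStateChainSpec = field(default_factory=lambda: TwoStateChainSpec(1000))

    def __post_init__(self) -> None:
        if self.sigma_ratio <= 0.0:
            raise ValueError("sigma_ratio must be > 0")
        if self.D < 1:
            raise ValueError("D must be >= 1")


@dataclass(frozen=True)
class Example2Spec:
    """Rotated bivariate regimes: covariance diag(eps_thick, 1) vs its rotation."""

    alpha: float = np.pi / 2
    eps_thick: float = 0.05
    D: int = 2
    chain: TwoStateChainSpec = field(default_factory=lambda: TwoStateChainSpec(1000))

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= np.pi / 2:
            raise ValueError("alpha must lie in (0, pi/2]")
        if self.eps_thick <= 0.0:
            raise ValueError("eps_thick must be > 0")
        if self.D < 2:
            raise ValueError("D must be >= 2 (two informative dimensions)")


#: k-mer order used everywhere for the nanopore toy labels.
NANOPORE_KMERS = ("AA", "AB", "BA", "BB")


@dataclass(frozen=True)
class NanoporeToySpec:
    """Two-base, 2-mer nanopore current toy.

    Each of the four k-mers has a current mean and SD (arbitrary picoampere-
    like units) and a geometric dwell-time distribution (mean samples).
    Defaults separate the four current levels by 2.5 SDs and give 'BA' the
    shortest and 'BB' the longest typical dwell.  ``sequence`` may be given
    explicitly (a string over {A, B}) or generated uniformly with
    ``n_bases``.
    """

    sequence: str | None = None
    n_bases: int = 50
    current_mean: tuple[float, float, float, float] = (80.0, 100.0, 120.0, 140.0)
    current_sd: tuple[float, float, float, float] = (8.0, 8.0, 8.0, 8.0)
    dwell_mean: tuple[float, float, float, float] = (40.0, 30.0, 15.0, 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sequence is not None:
            if len(self.sequence) < 2:
                raise ValueError("sequence must hold at least one 2-mer")
            if set(self.sequence) - {"A", "B"}:
                raise ValueError("sequence must use the {A, B} alphabet")
        elif self.n_bases < 2:
            raise ValueError("n_bases must be >= 2")
        if any(sd <= 0 for sd in self.current_sd):
            raise ValueError("current SDs must be > 0")
        if any(dm < 1 for dm in self.dwell_mean):
            raise ValueError("mean dwell times must be >= 1 sample")


def gen_two_state_path(spec: TwoStateChainSpec) -> NDArray[np.intp]:
    """State sequence in {1, 2} of length ``spec.T``."""
    rng = np.random.default_rng(spec.seed)
    T = spec.T
    if spec.mode == "pure-chain":
        switches = rng.random(T - 1) < spec.eps_trans
        states = np.empty(T, dtype=np.intp)
        states[0] = rng.integers(1, 3)
        flips = np.cumsum(switches)
        states[1:] = 1 + (states[0] - 1 + flips) % 2
        return states
    # block-dwell: alternate states; dwell ~ U[0.8c, 1.2c] with c = T/18,
    # i.e. about six alternations per third of the sequence, which keeps every
    # dwell well below a third's length and so guarantees both states appear
    # in each third.
    c = T / 18.0
    if c * 0.8 < 1.0:
        raise ValueError(
            f"T={T} too small for the block-dwell both-states-per-third guarantee"
        )
    states = np.empty(T, dtype=np.intp)
    state = int(rng.integers(1, 3))
    pos = 0
    while pos < T:
        dwell = int(round(rng.uniform(0.8 * c, 1.2 * c)))
        dwell = max(dwell, 1)
        states[pos : pos + dwell] = state
        pos += dwell
        state = 3 - state
    return states


def states_to_onehot(states: ArrayLike, n_labels: int | None = None) -> NDArray[np.float64]:
    """One-hot (n_labels x T) encoding of a 1-based state sequence."""
    states = np.asarray(states, dtype=np.intp)
    if n_labels is None:
        n_labels = int(states.max())
    Pi = np.zeros((n_labels, states.size))
    Pi[states - 1, np.arange(states.size)] = 1.0
    return Pi


def _append_noise_dims(
    X_inf: NDArray[np.float64], D: int, rng: np.random.Generator
) -> NDArray[np.float64]:
    d_inf, T = X_inf.shape
    if D == d_inf:
        return X_inf
    return np.vstack([X_inf, rng.uniform(size=(D - d_inf, T))])


def gen_example1(
    spec: Example1Spec,
) -> tuple[NDArray[np.float64], NDArray[np.float64], NDArray[np.intp]]:
    """Variance-switching dataset: (X (D x T), one-hot Pi (2 x T), states).

    Dimension 1 emits N(0, sigma_state^2) with sigma_1 = 1 and
    sigma_2 = 1/sigma_ratio; dimensions 2..D are i.i.d. U[0, 1] noise.
    ``sigma_ratio = 1`` makes the two states statistically identical.
    """
    states = gen_two_state_path(spec.chain)
    rng = np.random.default_rng(np.random.SeedSequence(spec.chain.seed, spawn_key=(1,)))
    sigma = np.where(states == 1, 1.0, 1.0 / spec.sigma_ratio)
    x0 = rng.normal(0.0, 1.0, size=states.size) * sigma
    X = _append_noise_dims(x0[None, :], spec.D, rng)
    return X, states_to_onehot(states, 2), states


def gen_example2(
    spec: Example2Spec,
) -> tuple[NDArray[np.float64], NDArray[np.float64], NDArray[np.intp]]:
    """Rotated bivariate dataset: (X (D x T), one-hot Pi (2 x T), states).

    Both states emit centered bivariate Gaussians: state 1 with covariance
    diag(eps_thick, 1), state 2 with that cloud rotated by ``alpha``;
    dimensions 3..D are U[0, 1] noise.  Means overlap by construction.
    """
    states = gen_two_state_path(spec.chain)
    rng = np.random.default_rng(np.random.SeedSequence(spec.chain.seed, spawn_key=(2,)))
    T = states.size
    z = rng.standard_normal((2, T))
    A1 = np.diag([np.sqrt(spec.eps_thick), 1.0])
    ca, sa = np.cos(spec.alpha), np.sin(spec.alpha)
    R = np.array([[ca, -sa], [sa, ca]])
    xy = np.where(states == 1, 1.0, 0.0) * (A1 @ z) + np.where(states == 2, 1.0, 0.0) * (
        R @ A1 @ z
    )
    X = _append_noise_dims(xy, spec.D, rng)
    return X, states_to_onehot(states, 2), states


def gen_nanopore_toy(
    spec: NanoporeToySpec,
) -> tuple[NDArray[np.float64], NDArray[np.float64], list[str]]:
    """Simulated nanopore current trace: (X (1 x T), one-hot Pi (4 x T), kmers).

    A width-2 window slides over the base sequence; each k-mer persists for
    a geometric dwell time (its own mean) emitting Gaussian current samples
    (its own mean/SD).  ``kmers`` lists the k-mer underlying each window
    position, in reading order; ``Pi`` labels every current sample with its
    k-mer, ordered as :data:`NANOPORE_KMERS`.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.sequence is not None:
        seq = spec.sequence
    else:
        seq = "".join(rng.choice(["A", "B"], size=spec.n_bases))
    kmers = [seq[i : i + 2] for i in range(len(seq) - 1)]
    idx = {km: i for i, km in enumerate(NANOPORE_KMERS)}
    samples: list[NDArray[np.float64]] = []
    labels: list[NDArray[np.intp]] = []
    for km in kmers:
        i = idx[km]
        # geometric on {1, 2, ...}: mean m  <->  p = 1/m, so dwell >= 1 always
        dwell = int(rng.geometric(1.0 / spec.dwell_mean[i]))
        samples.append(rng.normal(spec.current_mean[i], spec.current_sd[i], size=dwell))
        labels.append(np.full(dwell, i + 1, dtype=np.intp))
    X = np.concatenate(samples)[None, :]
    states = np.concatenate(labels)
    return X, states_to_onehot(states, 4), kmers


def takens_embed(X: ArrayLike, l: int) -> NDArray[np.float64]:
    """Delay embedding: stack each column with its ``l`` predecessors.

    Output has ``D*(l+1)`` rows and ``T - l`` columns (only windows fully
    inside the record are kept); row blocks are ordered lag 0, 1, ..., l.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if l < 0:
        raise ValueError("embedding window l must be >= 0")
    D, T = X.shape
    if T <= l:
        raise ValueError(f"T={T} leaves no full window of length l+1={l + 1}")
    if l == 0:
        return X.copy()
    return np.vstack([X[:, l - j : T - j] for j in range(l + 1)])


def auc_score(scores: ArrayLike, labels: ArrayLike) -> float:
    """Area under the ROC curve of ``scores`` against binary ``labels``.

    Equals the Mann-Whitney U statistic normalized by n+ * n- (ties count
    one half): 0.5 is chance level, 1 perfect ranking.  Raises if only one
    class is present.
    """
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def triple_split(
    T: int,
) -> tuple[NDArray[np.intp], NDArray[np.intp], NDArray[np.intp]]:
    """Contiguous, disjoint train/validation/test blocks of near-equal size.

    Sizes differ by at most one (remainder goes to the earlier blocks);
    together the blocks cover 0..T-1 exactly once, in time order.
    """
    if T < 6:
        raise ValueError("T must be >= 6 to split into three usable blocks")
    base, rem = divmod(T, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    edges = np.cumsum([0] + sizes)
    idx = np.arange(T)
    return idx[edges[0] : edges[1]], idx[edges[1] : edges[2]], idx[edges[2] : edges[3]]
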