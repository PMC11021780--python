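"""Expectation–Maximization attention over a compact basis set.

Instead of the quadratic-cost pairwise attention map, a small dictionary of K
bases μ ∈ R^{D×K} is iterated by alternating an E step (softmax
responsibilities A ∈ R^{N×K} of every voxel feature for every basis) and an
M step (bases re-estimated as responsibility-weighted feature means, then
L2-renormalized).  The feature map is reconstructed as the low-rank product
μAᵀ, passed through a pointwise convolution and added back residually.

The inner EM loop runs outside the gradient graph; only the two pointwise
convolutions are trained.  A persistent global basis set is maintained across
training batches by an exponential moving average and seeds the iteration at
inference.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import Module, Parameter, Tensor, conv3d, he_init, no_grad


@dataclasses.dataclass
class EmaConfig:
    channels: int
    n_bases: int = 64
    n_iterations: int = 3        # E/M alternations per forward pass
    basis_momentum: float = 0.9
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_bases < 1 or self.n_iterations < 1:
            raise ValueError("n_bases and n_iterations must be >= 1")
        if not 0.0 <= self.basis_momentum <= 1.0:
            raise ValueError("basis_momentum must lie in [0, 1]")


@dataclasses.dataclass
class BasisSet:
    """Columns are unit-norm bases μ_k, shape (D, K)."""

    mu: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float32)
        if self.mu.ndim != 2:
            raise ValueError("mu must be a D x K matrix")


def init_bases(channels: int, n_bases: int, rng: np.random.Generator) -> BasisSet:
    mu = rng.normal(size=(channels, n_bases)).astype(np.float32)
    return BasisSet(mu=_normalize_columns(mu))


def init_bases_from_data(x_flat: np.ndarray, n_bases: int,
                         rng: np.random.Generator) -> BasisSet:
    """Distance-spread (k-means++-style) basis seeding from feature columns.

    EM with few alternations is sensitive to initialization: two nearly tied
    random bases can split one mode's responsibility indefinitely.  Seeding
    each basis from a data column chosen proportionally to its squared
    distance from the already-chosen set spreads the bases across modes and
    resolves such ties.  Used for clustering-style analyses; the network
    layer keeps its persistent (momentum-maintained) bases instead.
    """
    d, n = x_flat.shape
    idx = [int(rng.integers(n))]
    for _ in range(n_bases - 1):
        d2 = np.min([((x_flat - x_flat[:, [i]]) ** 2).sum(axis=0) for i in idx],
                    axis=0)
        total = float(d2.sum())
        probs = d2 / total if total > 0 else np.full(n, 1.0 / n)
        idx.append(int(rng.choice(n, p=probs)))
    return BasisSet(mu=_normalize_columns(x_flat[:, idx].astype(np.float32)))


def _normalize_columns(mu: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    norms = np.linalg.norm(mu, axis=0, keepdims=True)
    return (mu / np.maximum(norms, eps)).astype(np.float32)


def _softmax_rows(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def e_step(x_flat: np.ndarray, basis: BasisSet) -> np.ndarray:
    """Responsibilities A (N×K): row-softmax of feature–basis inner products.

    The inner product uses unit scaling (λ = 1); the M step's basis
    renormalization keeps the logits bounded.
    """
    if not np.all(np.isfinite(x_flat)):
        raise FloatingPointError("e_step received non-finite features")
    logits = x_flat.T @ basis.mu          # (N, K)
    return _softmax_rows(logits)


def m_step(x_flat: np.ndarray, attention: np.ndarray,
           epsilon: float = 1e-6, prev: BasisSet | None = None) -> BasisSet:
    """Bases as responsibility-weighted feature means, columns renormalized.

    A basis whose responsibility column is (numerically) all zero has no
    assigned features; it keeps its previous value when one is supplied.
    """
    weights = attention.sum(axis=0)                        # (K,)
    mu = (x_flat @ attention) / (weights + epsilon)        # (D, K)
    if prev is not None:
        dead = weights <= epsilon
        if dead.any():
            mu[:, dead] = prev.mu[:, dead]
    return BasisSet(mu=_normalize_columns(mu))


def em_iterate(x_flat: np.ndarray, basis0: BasisSet, t: int = 3,
               epsilon: float = 1e-6) -> tuple[BasisSet, np.ndarray]:
    """Run exactly ``t`` alternations of e_step then m_step."""
    if t < 1:
        raise ValueError("t must be >= 1")
    basis = basis0
    attention = None
    for _ in range(t):
        attention = e_step(x_flat, basis)
        basis = m_step(x_flat, attention, epsilon=epsilon, prev=basis)
    return basis, attention


def reconstruct(basis: BasisSet, attention: np.ndarray) -> np.ndarray:
    """Low-rank reconstruction X̃ = μ Aᵀ, shape (D, N); rank ≤ K."""
    return basis.mu @ attention.T


def update_global_bases(state: BasisSet, converged: BasisSet,
                        momentum: float) -> BasisSet:
    """EMA maintenance of the persistent bases, renormalized to unit columns."""
    mixed = momentum * state.mu + (1.0 - momentum) * converged.mu
    return BasisSet(mu=_normalize_columns(mixed))


class EMAttention3d(Module):
    """EMA block: pointwise conv in → EM loop → reconstruct → pointwise conv
    out → residual sum with the input."""

    def __init__(self, config: EmaConfig, rng: np.random.Generator):
        self.config = config
        d = config.channels
        self.w_in = Parameter(he_init(rng, (d, d, 1, 1, 1), fan_in=d))
        self.b_in = Parameter(np.zeros(d, dtype=np.float32))
        self.w_out = Parameter(he_init(rng, (d, d, 1, 1, 1), fan_in=d))
        self.b_out = Parameter(np.zeros(d, dtype=np.float32))
        self.global_bases = init_bases(d, config.n_bases, rng)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        if x.data.shape[0] != self.config.channels:
            raise ValueError(f"EMA expects {self.config.channels} channels, "
                             f"got {x.data.shape[0]}")
        z = conv3d(x, self.w_in, self.b_in)
        d = z.data.shape[0]
        with no_grad():
            x_flat = z.data.reshape(d, -1)
            converged, attention = em_iterate(
                x_flat, self.global_bases, t=self.config.n_iterations,
                epsilon=self.config.epsilon)
            recon = reconstruct(converged, attention).reshape(z.data.shape)
        if training:
            self.global_bases = update_global_bases(
                self.global_bases, converged, self.config.basis_momentum)
        out = conv3d(Tensor(recon), self.w_out, self.b_out)
        return x + out

    __call__ = forward


def ema_forward(x: Tensor | np.ndarray, module: EMAttention3d,
                training: bool = False) -> Tensor:
    """Functional wrapper around :class:`EMAttention3d`."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    return module.forward(x, training=training)
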