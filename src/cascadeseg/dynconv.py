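"""Dynamic 3-D convolution: attention-weighted aggregation of parallel kernels.

A bank of K parallel kernels is collapsed, per input sample, into a single
kernel W̃ = Σ_k π_k W_k (and bias b̃ = Σ_k π_k b_k) whose mixture weights π
come from a squeeze-and-excitation head: global average pooling over space,
a bottleneck fully-connected pair with a rectifier in between, and a softmax
with temperature τ, so Σ_k π_k = 1 always.  Aggregating before convolving is
mathematically identical to convolving with each kernel and mixing the
outputs (linearity), at 1/K the cost; the expanded form serves as the test
oracle.

The nonlinearity of the layer lives entirely in π's dependence on the input;
the kernel aggregation itself is linear.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import (Module, Parameter, Tensor, conv3d, he_init, matmul,
                       relu, softmax, tmean, tsum)


@dataclasses.dataclass
class DyConvConfig:
    in_channels: int
    out_channels: int
    kernel_size: int = 3
    n_kernels: int = 4
    reduction: int = 4
    temperature: float = 30.0    # annealed toward 1 by the trainer

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if self.n_kernels < 2:
            raise ValueError("n_kernels must be >= 2")
        if self.reduction < 1:
            raise ValueError("reduction must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


class DynamicConv3d(Module):
    """Stride-1 'same' 3-D convolution with per-sample kernel attention."""

    def __init__(self, config: DyConvConfig, rng: np.random.Generator):
        self.config = config
        cin, cout, k, kk = (config.in_channels, config.out_channels,
                            config.kernel_size, config.n_kernels)
        hidden = max(1, cin // config.reduction)
        fan = cin * k ** 3
        self.bank_w = Parameter(he_init(rng, (kk, cout, cin, k, k, k), fan_in=fan))
        self.bank_b = Parameter(np.zeros((kk, cout), dtype=np.float32))
        self.fc1_w = Parameter(he_init(rng, (hidden, cin), fan_in=cin))
        self.fc1_b = Parameter(np.zeros(hidden, dtype=np.float32))
        self.fc2_w = Parameter(he_init(rng, (kk, hidden), fan_in=hidden))
        self.fc2_b = Parameter(np.zeros(kk, dtype=np.float32))
        self.temperature = config.temperature

    # -- attention head ------------------------------------------------------

    def attention(self, x: Tensor) -> Tensor:
        """π for one sample: GAP → FC → ReLU → FC → softmax(·/τ). Shape (K,)."""
        if x.data.shape[0] != self.config.in_channels:
            raise ValueError(f"expected {self.config.in_channels} channels, "
                             f"got {x.data.shape[0]}")
        pooled = tmean(x, axis=(1, 2, 3))                       # (C_in,)
        h = relu(matmul(self.fc1_w, pooled) + self.fc1_b)
        logits = matmul(self.fc2_w, h) + self.fc2_b             # (K,)
        return softmax(logits * (1.0 / self.temperature), axis=0)

    # -- aggregation and convolution -----------------------------------------

    def aggregate(self, pi: Tensor) -> tuple[Tensor, Tensor]:
        """Collapse the bank with mixture weights π: W̃ = Σ π_k W_k."""
        pw = pi.reshape((-1, 1, 1, 1, 1, 1))
        weight = tsum(pw * self.bank_w, axis=0)
        bias = tsum(pi.reshape((-1, 1)) * self.bank_b, axis=0)
        return weight, bias

    def forward(self, x: Tensor) -> Tensor:
        pi = self.attention(x)
        weight, bias = self.aggregate(pi)
        return conv3d(x, weight, bias)

    __call__ = forward


# ---- functional surface ----------------------------------------------------

def kernel_attention(x, layer: DynamicConv3d) -> np.ndarray:
    """Mixture weights π for one sample as a plain (K,) array."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    return layer.attention(x).data


def aggregate_kernels(bank_w: np.ndarray, bank_b: np.ndarray,
                      pi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """W̃ = Σ_k π_k W_k and b̃ = Σ_k π_k b_k for plain arrays."""
    pi = np.asarray(pi, dtype=np.float32)
    weight = np.tensordot(pi, np.asarray(bank_w, dtype=np.float32), axes=(0, 0))
    bias = np.tensordot(pi, np.asarray(bank_b, dtype=np.float32), axes=(0, 0))
    return weight, bias


def dyconv_forward(batch, layer: DynamicConv3d) -> np.ndarray:
    """Apply the layer independently to each sample of a (B, C, D, H, W) batch.

    Per-sample semantics are guaranteed regardless of batching: every sample
    gets its own π and hence its own aggregated kernel.
    """
    batch = np.asarray(batch, dtype=np.float32)
    if batch.ndim == 4:
        batch = batch[None]
    return np.stack([layer.forward(Tensor(x)).data for x in batch])
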