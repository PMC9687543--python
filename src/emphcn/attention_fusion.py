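"""Efficient channel attention (ECA) fusion of multi-view drug channels.

Each similarity view yields one channel of the drug embedding.  A
channel descriptor vector Z is obtained by global average pooling over
drugs and features; a single shared 1-D convolution kernel (default
length 3, zero same-padding) maps Z to per-channel logits, squashed by a
logistic to attention weights in (0,1); the fused embedding is the
attention-weighted sum of channels.  Weights are deliberately not
re-normalized to sum to one.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad

DEFAULT_KERNEL_SIZE = 3


def _is_tensor_stack(stack) -> bool:
    return isinstance(stack, (list, tuple)) and any(
        isinstance(c, ad.Tensor) for c in stack
    )


def global_average_pool(stack):
    """Per-channel mean over the drug and feature axes.

    ``stack`` is either an M x F x S array or a list of S channel
    Tensors/arrays.  Returns a length-S vector (array or Tensor).
    """
    if _is_tensor_stack(stack):
        means = [ad.tensor_mean(ad.as_tensor(c)) for c in stack]
        return ad.concat([_reshape1(m) for m in means], axis=0)
    if isinstance(stack, (list, tuple)):
        stack = np.stack([np.asarray(c) for c in stack], axis=-1)
    stack = np.asarray(stack, dtype=np.float64)
    if stack.size == 0:
        raise ValueError("empty channel stack")
    return stack.mean(axis=(0, 1))


def _reshape1(scalar: ad.Tensor) -> ad.Tensor:
    out = ad.Tensor(scalar.value.reshape(1), parents=(scalar,))

    def backward(grad):
        if scalar.requires_grad:
            scalar._accum(grad.reshape(scalar.value.shape))

    out._backward = backward
    return out


def eca_weights(z, kernel):
    """Attention weights: logistic of a shared same-padded 1-D convolution.

    ``kernel`` has odd length k; the descriptor is zero-padded by k//2 on
    both sides so the output length equals the channel count for any
    S >= 1.
    """
    kernel_len = kernel.shape[0] if isinstance(kernel, ad.Tensor) else len(kernel)
    if kernel_len % 2 == 0:
        raise ValueError("ECA kernel length must be odd")
    half = kernel_len // 2
    tensor_mode = isinstance(z, ad.Tensor) or isinstance(kernel, ad.Tensor)
    s = z.shape[0] if isinstance(z, ad.Tensor) else len(z)
    # shift matrices implement the zero same-padding: (T_t @ Z)[i] = Zpad[i+t]
    shifts = []
    for t in range(kernel_len):
        mat = np.zeros((s, s))
        off = t - half
        for i in range(s):
            j = i + off
            if 0 <= j < s:
                mat[i, j] = 1.0
        shifts.append(mat)
    if tensor_mode:
        zt, kt = ad.as_tensor(z), ad.as_tensor(kernel)
        terms = [ad.mul(ad.matmul(ad.Tensor(shifts[t]), zt), kt[t : t + 1])
                 for t in range(kernel_len)]
        acc = terms[0]
        for term in terms[1:]:
            acc = ad.add(acc, term)
        return ad.sigmoid(acc)
    z = np.asarray(z, dtype=np.float64)
    kernel = np.asarray(kernel, dtype=np.float64)
    conv = sum(kernel[t] * (shifts[t] @ z) for t in range(kernel_len))
    return 1.0 / (1.0 + np.exp(-conv))


def fuse_channels(stack, weights):
    """Weighted channel sum: X-tilde = sum_s w_s * channel_s."""
    if _is_tensor_stack(stack) or isinstance(weights, ad.Tensor):
        channels = [ad.as_tensor(c) for c in stack] if isinstance(stack, (list, tuple)) \
            else [ad.as_tensor(np.asarray(stack)[:, :, s]) for s in range(np.asarray(stack).shape[2])]
        w = ad.as_tensor(weights)
        if w.shape[0] != len(channels):
            raise ValueError("weight length must equal channel count")
        acc = ad.mul(channels[0], w[0:1])
        for s in range(1, len(channels)):
            acc = ad.add(acc, ad.mul(channels[s], w[s : s + 1]))
        return acc
    stack = np.stack([np.asarray(c) for c in stack], axis=-1) \
        if isinstance(stack, (list, tuple)) else np.asarray(stack, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape[0] != stack.shape[2]:
        raise ValueError("weight length must equal channel count")
    return np.tensordot(stack, weights, axes=([2], [0]))


def init_eca_kernel(rng: np.random.Generator, size: int = DEFAULT_KERNEL_SIZE,
                    scale: float = 0.01) -> np.ndarray:
    """Small-uniform kernel so the initial attention is near-uniform (~0.5)."""
    return rng.uniform(-scale, scale, size=size)
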