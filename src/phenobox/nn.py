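"""Framework-free reference implementations of the detector's numeric blocks.

These are inference-semantics references for verification, not trainable
layers: adaptive-kernel convolution (a convex, weight-mixed sum of
convolutions with different kernel sizes), scaled dot-product attention,
local (non-overlapping window) attention, and bi-level routing attention (a
convex combination of per-group attentions).  Mixing weights that would be
learned in a network are plain inputs here, constrained to the probability
simplex.

Everything operates on small numpy arrays; tests compare each operation to
a naive-loop oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError

_SIMPLEX_TOL = 1e-9


def _check_simplex(weights: np.ndarray, name: str) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if np.any(w < -_SIMPLEX_TOL) or abs(w.sum() - 1.0) > 1e-6:
        raise ConfigError(f"{name} must be non-negative and sum to 1, got {w}")
    return w


def conv2d(X: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """'Same' zero-padded cross-correlation.

    ``X`` has shape (C_in, H, W) and ``kernel`` (C_out, C_in, k, k) with k
    odd; output is (C_out, H, W).
    """
    X = np.asarray(X, dtype=float)
    K = np.asarray(kernel, dtype=float)
    if X.ndim != 3 or K.ndim != 4:
        raise ConfigError("X must be (C,H,W) and kernel (C_out,C_in,k,k)")
    c_out, c_in, kh, kw = K.shape
    if kh != kw or kh % 2 == 0:
        raise ConfigError(f"kernel must be square with odd size, got {kh}x{kw}")
    if X.shape[0] != c_in:
        raise ConfigError(f"channel mismatch: X has {X.shape[0]}, kernel expects {c_in}")
    pad = kh // 2
    Xp = np.pad(X, ((0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(Xp, (kh, kw), axis=(1, 2))
    # windows: (C_in, H, W, k, k); kernel: (C_out, C_in, k, k)
    return np.einsum("chwij,ocij->ohw", windows, K)


@dataclass(frozen=True)
class KernelBank:
    """Kernels of differing sizes with simplex-constrained mixing weights."""

    kernels: tuple[np.ndarray, ...]
    alphas: tuple[float, ...]

    def __post_init__(self):
        if len(self.kernels) != len(self.alphas) or not self.kernels:
            raise ConfigError("need matching, non-empty kernels and alphas")
        _check_simplex(np.asarray(self.alphas), "alphas")
        shapes = {k.shape[:2] for k in self.kernels}
        if len(shapes) != 1:
            raise ConfigError("all kernels must share (C_out, C_in)")

    @classmethod
    def from_logits(cls, kernels: Sequence[np.ndarray], logits: Sequence[float]) -> "KernelBank":
        """Softmax-normalize raw attention scores into mixing weights."""
        z = np.asarray(logits, dtype=float)
        e = np.exp(z - z.max())
        return cls(tuple(np.asarray(k, dtype=float) for k in kernels), tuple(e / e.sum()))


def akconv_forward(X: np.ndarray, bank: KernelBank) -> np.ndarray:
    """Adaptive-kernel convolution: Y = sum_i alpha_i * conv2d(X, K_i).

    A convex combination of same-padded convolutions with different kernel
    sizes; linear in X.
    """
    return sum(a * conv2d(X, k) for a, k in zip(bank.alphas, bank.kernels))


def scaled_dot_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray, d: float | None = None, scale: str = "sqrt"
) -> np.ndarray:
    """softmax(Q K^T / sqrt(d)) V.

    ``d`` defaults to the key dimension.  The sqrt normalization keeps dot
    products from saturating the softmax; ``scale='linear'`` divides by d
    instead.
    """
    Q = np.asarray(Q, dtype=float)
    K = np.asarray(K, dtype=float)
    V = np.asarray(V, dtype=float)
    if Q.shape[1] != K.shape[1] or K.shape[0] != V.shape[0]:
        raise ConfigError("incompatible Q/K/V shapes")
    d = float(Q.shape[1]) if d is None else float(d)
    if d <= 0:
        raise ConfigError("d must be positive")
    denom = np.sqrt(d) if scale == "sqrt" else d
    scores = Q @ K.T / denom
    scores -= scores.max(axis=1, keepdims=True)
    weights = np.exp(scores)
    weights /= weights.sum(axis=1, keepdims=True)
    return weights @ V


def local_window_attention(
    X: np.ndarray, window_size: int, d: float | None = None, scale: str = "sqrt"
) -> np.ndarray:
    """Self-attention restricted to non-overlapping spatial windows.

    ``X`` is an (H, W, D) token grid; tokens attend only within their own
    ``window_size`` x ``window_size`` window (Q = K = V = the window's
    tokens).  Grids not divisible by the window size get truncated edge
    windows, i.e. edge tokens attend over the valid tokens of their window
    only - equivalent to masked zero-padding.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ConfigError("X must be an (H, W, D) token grid")
    if window_size < 1:
        raise ConfigError("window_size must be >= 1")
    H, W, _ = X.shape
    out = np.empty_like(X)
    for i0 in range(0, H, window_size):
        for j0 in range(0, W, window_size):
            block = X[i0 : i0 + window_size, j0 : j0 + window_size]
            bh, bw, D = block.shape
            tokens = block.reshape(bh * bw, D)
            out[i0 : i0 + window_size, j0 : j0 + window_size] = scaled_dot_attention(
                tokens, tokens, tokens, d=d, scale=scale
            ).reshape(bh, bw, D)
    return out


def bilevel_routing_attention(
    Q: np.ndarray,
    K: np.ndarray,
    V: np.ndarray,
    groups: Sequence[Sequence[int]],
    pi: Sequence[float],
    d: float | None = None,
    scale: str = "sqrt",
) -> np.ndarray:
    """sum_i pi_i * softmax(Q K_i^T / sqrt(d)) V_i over key/value groups.

    ``groups`` index rows of K/V (the routing partition); ``pi`` are the
    simplex-constrained routing weights.  Output is the pi-weighted convex
    combination of the per-group attention outputs.
    """
    w = _check_simplex(np.asarray(pi), "pi")
    if len(groups) != w.size:
        raise ConfigError("groups and pi must have equal length")
    K = np.asarray(K, dtype=float)
    V = np.asarray(V, dtype=float)
    out = None
    for wi, idx in zip(w, groups):
        idx = np.asarray(idx, dtype=int)
        if idx.size == 0:
            raise ConfigError("empty routing group")
        term = wi * scaled_dot_attention(Q, K[idx], V[idx], d=d, scale=scale)
        out = term if out is None else out + term
    return out
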