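"""Neural-network building blocks on top of the autodiff tensor."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d_same, gelu, layer_norm, softmax

__all__ = ["Module", "Linear", "Conv2d", "LayerNorm", "MultiHeadSelfAttention", "Mlp", "trunc_normal"]


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02, dtype=np.float32) -> np.ndarray:
    """Truncated-normal init at +/- 2 std."""
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2 * std, 2 * std).astype(dtype)


class Module:
    """Tiny module base: recursive named-parameter collection."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out[name] = val
            elif isinstance(val, Module):
                for sub, p in val.parameters().items():
                    out[f"{name}.{sub}"] = p
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            out[f"{name}.{i}.{sub}"] = p
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise ValueError(f"parameter name mismatch loading state: {sorted(missing)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}")
            p.data = state[name].astype(p.data.dtype)

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype=np.float32):
        self.w = Tensor(trunc_normal(rng, (d_in, d_out), dtype=dtype), requires_grad=True)
        self.b = Tensor(np.zeros(d_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    """Odd-kernel zero-same-padding 2-D convolution, (B, C, H, W) layout."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, dtype=np.float32):
        fan_in = c_in * k * k
        std = float(np.sqrt(2.0 / fan_in))  # He init: convs feed GELUs
        self.w = Tensor(rng.normal(0, std, size=(c_out, c_in, k, k)).astype(dtype), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d_same(x, self.w, self.b)


class LayerNorm(Module):
    def __init__(self, d: int, dtype=np.float32):
        self.gamma = Tensor(np.ones(d, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(d, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product self-attention over (..., N, d) tokens.

    The inner (query/key/value) dimension may be smaller than the embedding
    dimension — a lightweight choice that halves the projection cost.
    """

    def __init__(self, d_model: int, n_heads: int, d_inner: int, rng: np.random.Generator, dtype=np.float32):
        if d_inner % n_heads:
            raise ValueError(f"attention dim {d_inner} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.d_head = d_inner // n_heads
        self.qkv = Linear(d_model, 3 * d_inner, rng, dtype)
        self.proj = Linear(d_inner, d_model, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        *lead, N, d = x.shape
        B = int(np.prod(lead)) if lead else 1
        h, dh = self.n_heads, self.d_head
        qkv = self.qkv(x).reshape(B, N, 3, h, dh).transpose(2, 0, 3, 1, 4)  # (3, B, h, N, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = softmax((q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh)), axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(*lead, N, h * dh)
        return self.proj(out)


class Mlp(Module):
    def __init__(self, d_model: int, d_hidden: int, rng: np.random.Generator, dtype=np.float32):
        self.fc1 = Linear(d_model, d_hidden, rng, dtype)
        self.fc2 = Linear(d_hidden, d_model, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))


class TransformerBlock(Module):
    """Pre-LN attention + MLP block with residuals."""

    def __init__(self, d_model: int, n_heads: int, d_inner: int, d_hidden: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.ln1 = LayerNorm(d_model, dtype)
        self.attn = MultiHeadSelfAttention(d_model, n_heads, d_inner, rng, dtype)
        self.ln2 = LayerNorm(d_model, dtype)
        self.mlp = Mlp(d_model, d_hidden, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.mlp(self.ln2(x))
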