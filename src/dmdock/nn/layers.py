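"""Neural-network building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, matmul

__all__ = ["Module", "Linear", "LayerNorm", "MLP", "RowAttention", "Adam"]


class Module:
    """Minimal parameter container with named traversal for checkpoints."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                out[name] = value
            elif isinstance(value, Module):
                for sub, t in value.parameters().items():
                    out[f"{name}.{sub}"] = t
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for sub, t in item.parameters().items():
                            out[f"{name}.{i}.{sub}"] = t
        return out

    def zero_grad(self) -> None:
        for t in self.parameters().values():
            t.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)}")
        for k, t in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != t.data.shape:
                raise ValueError(
                    f"shape mismatch for {k}: {arr.shape} vs {t.data.shape}")
            t.data = arr.copy()


class Linear(Module):
    """Affine map with Xavier init.

    ``init_scale`` rescales the weight init; residual output layers use a
    small (or zero) scale so each branch starts near the identity without
    being gradient-dead.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False, bias: bool = True,
                 init_scale: float = 1.0):
        if zero_init:
            w = np.zeros((d_in, d_out))
        else:
            scale = init_scale * np.sqrt(2.0 / (d_in + d_out))
            w = rng.normal(0.0, scale, size=(d_in, d_out))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        lead = x.shape[:-1]
        flat = x.reshape(-1, x.shape[-1]) if x.ndim != 2 else x
        y = matmul(flat, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y.reshape(*lead, self.weight.shape[1]) if x.ndim != 2 else y


class LayerNorm(Module):
    """Layer norm over the last axis with learned affine parameters."""

    def __init__(self, d: int):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm() * self.gamma + self.beta


class MLP(Module):
    """Two-layer ReLU MLP; the output layer may be zero-initialized so a
    residual branch starts as the identity."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int,
                 rng: np.random.Generator, zero_init_out: bool = False,
                 out_scale: float = 1.0):
        self.fc1 = Linear(d_in, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_out, rng, zero_init=zero_init_out,
                          init_scale=out_scale)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class RowAttention(Module):
    """Multihead self-attention over the second-to-last axis of a
    (..., L, d) tensor — used per pocket row over ligand positions."""

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator,
                 out_scale: float = 1.0):
        if d % n_heads:
            raise ValueError("embedding size must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.wq = Linear(d, d, rng, bias=False)
        self.wk = Linear(d, d, rng, bias=False)
        self.wv = Linear(d, d, rng, bias=False)
        self.wo = Linear(d, d, rng, zero_init=(out_scale == 0.0),
                         init_scale=out_scale)

    def __call__(self, x: Tensor) -> Tensor:
        # x: (p, c, d) -> heads (p, h, c, dh)
        p, c, d = x.shape
        h, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:
            return t.reshape(p, c, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = matmul(q, k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = scores.softmax()
        ctx = matmul(attn, v)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(p, c, d)
        return self.wo(ctx)


class Adam:
    """Adaptive-moment gradient descent with optional per-parameter
    learning-rate scales (``lr_scales`` maps name prefixes to factors)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 lr_scales: dict[str, float] | None = None):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.scale = {}
        for k in params:
            factor = 1.0
            for prefix, f in (lr_scales or {}).items():
                if k.startswith(prefix):
                    factor = f
            self.scale[k] = factor

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= (self.lr * self.scale[k]) * mhat / (np.sqrt(vhat)
                                                          + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()
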