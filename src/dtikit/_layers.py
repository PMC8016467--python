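"""Neural building blocks used by the encoder architectures.

Every layer owns its parameters (a flat dict of named
:func:`~dtikit._autograd.Parameter` tensors) and exposes a functional
``__call__``.  Initialization is Glorot-uniform from an explicit
``numpy.random.Generator``, so a model built twice from the same seed is
bit-identical.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Parameter, Tensor, concat, softmax

__all__ = [
    "Module",
    "Linear",
    "MLP",
    "Embedding",
    "Conv1d",
    "BiRNN",
    "LayerNorm",
    "TransformerBlock",
]


class Module:
    """Base class: parameter registry plus (de)serialization to flat dicts."""

    def __init__(self):
        self._params: dict = {}
        self._children: dict = {}

    def add_param(self, name: str, value) -> Tensor:
        p = Parameter(value)
        self._params[name] = p
        return p

    def add_module(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def parameters(self) -> dict:
        out = dict(self._params)
        for cname, child in self._children.items():
            for pname, p in child.parameters().items():
                out[f"{cname}.{pname}"] = p
        return out

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.parameters().items()}

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise ValueError(f"parameter name mismatch: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data[...] = state[k]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, rng, in_dim: int, out_dim: int):
        super().__init__()
        self.W = self.add_param("W", _glorot(rng, in_dim, out_dim, (in_dim, out_dim)))
        self.b = self.add_param("b", np.zeros(out_dim))
        self.out_dim = out_dim

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class MLP(Module):
    """Stack of Linear+ReLU layers; final layer optionally linear."""

    def __init__(self, rng, in_dim: int, hidden, final_activation: bool = True):
        super().__init__()
        self.layers = []
        dims = [in_dim] + list(hidden)
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            self.layers.append(self.add_module(f"lin{i}", Linear(rng, a, b)))
        self.final_activation = final_activation
        self.out_dim = dims[-1]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1 or self.final_activation:
                x = x.relu()
        return x


class Embedding(Module):
    def __init__(self, rng, vocab_size: int, dim: int):
        super().__init__()
        self.table = self.add_param("table", rng.normal(0.0, 0.1, size=(vocab_size, dim)))
        # PAD row zeroed so padding contributes nothing before masking
        self.table.data[0] = 0.0
        self.dim = dim

    def __call__(self, indices: np.ndarray) -> Tensor:
        return self.table[indices]


class Conv1d(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int):
        super().__init__()
        self.W = self.add_param(
            "W", _glorot(rng, in_ch * kernel, out_ch, (out_ch, in_ch, kernel)))
        self.b = self.add_param("b", np.zeros(out_ch))
        self.kernel = kernel

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d(self.W, self.b)


class BiRNN(Module):
    """Bidirectional tanh RNN; returns the concatenated last hidden states."""

    def __init__(self, rng, in_dim: int, hidden_dim: int):
        super().__init__()
        self.hidden_dim = hidden_dim
        for d in ("fwd", "bwd"):
            self.add_param(f"{d}_Wx", _glorot(rng, in_dim, hidden_dim, (in_dim, hidden_dim)))
            self.add_param(f"{d}_Wh", _glorot(rng, hidden_dim, hidden_dim, (hidden_dim, hidden_dim)))
            self.add_param(f"{d}_b", np.zeros(hidden_dim))
        self.out_dim = 2 * hidden_dim

    def _run(self, x: Tensor, direction: str, mask: np.ndarray) -> Tensor:
        Wx = self._params[f"{direction}_Wx"]
        Wh = self._params[f"{direction}_Wh"]
        b = self._params[f"{direction}_b"]
        batch, steps, _ = x.shape
        order = range(steps) if direction == "fwd" else range(steps - 1, -1, -1)
        h = Tensor(np.zeros((batch, self.hidden_dim)))
        for t in order:
            m = Tensor(mask[:, t:t + 1].astype(float))
            h_new = (x[:, t, :] @ Wx + h @ Wh + b).tanh()
            h = h_new * m + h * (1.0 - m)  # padded steps carry state through
        return h

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        """``x``: (batch, steps, in_dim); ``mask``: (batch, steps) 0/1."""
        return concat([self._run(x, "fwd", mask), self._run(x, "bwd", mask)], axis=1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.add_param("gamma", np.ones(dim))
        self.beta = self.add_param("beta", np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5 * self.gamma + self.beta


class TransformerBlock(Module):
    """Pre-LN multi-head self-attention block with padding mask."""

    def __init__(self, rng, dim: int, n_heads: int, ff_dim: int):
        super().__init__()
        if dim % n_heads:
            raise ValueError("model dim must be divisible by n_heads")
        self.dim, self.n_heads, self.head_dim = dim, n_heads, dim // n_heads
        for name in ("q", "k", "v", "o"):
            self.add_module(name, Linear(rng, dim, dim))
        self.ln1 = self.add_module("ln1", LayerNorm(dim))
        self.ln2 = self.add_module("ln2", LayerNorm(dim))
        self.ff1 = self.add_module("ff1", Linear(rng, dim, ff_dim))
        self.ff2 = self.add_module("ff2", Linear(rng, ff_dim, dim))

    def _split(self, t: Tensor, batch: int, steps: int) -> Tensor:
        return t.reshape(batch, steps, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        batch, steps, _ = x.shape
        h = self.ln1(x)
        q = self._split(self._children["q"](h), batch, steps)
        k = self._split(self._children["k"](h), batch, steps)
        v = self._split(self._children["v"](h), batch, steps)
        scores = q @ k.transpose(0, 1, 3, 2) * (self.head_dim ** -0.5)
        neg = (1.0 - mask[:, None, None, :]) * -1e9  # mask padded keys
        att = softmax(scores + Tensor(neg), axis=-1)
        ctx = (att @ v).transpose(0, 2, 1, 3).reshape(batch, steps, self.dim)
        x = x + self._children["o"](ctx)
        x = x + self.ff2(self.ff1(self.ln2(x)).relu())
        return x
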