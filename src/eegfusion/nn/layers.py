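"""Neural-network building blocks on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor, concat  # noqa: F401  (concat re-exported)


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery (dicts/lists supported)."""

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, (Module, Tensor)):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, (Module, Tensor)):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in self._children():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor):
                if value.requires_grad:
                    yield full, value
            else:
                yield from value.named_parameters(prefix=full + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = parameter(rng.uniform(-limit, limit, size=(n_in, n_out)))
        self.b = parameter(np.zeros(n_out)) if bias else None
        self.n_in, self.n_out = n_in, n_out

    def __call__(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        lead = x.shape[:-1]
        out = x.reshape((-1, self.n_in)) @ self.W
        if self.b is not None:
            out = out + self.b
        return out.reshape(lead + (self.n_out,))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.g = parameter(np.ones(dim))
        self.b = parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.g + self.b


def relu(x: Tensor) -> Tensor:
    return as_tensor(x).relu()


def gelu(x: Tensor) -> Tensor:
    """tanh-approximated Gaussian error linear unit."""
    x = as_tensor(x)
    c = float(np.sqrt(2.0 / np.pi))
    return 0.5 * x * (1.0 + (c * (x + 0.044715 * x * x * x)).tanh())


ACTIVATIONS = {"relu": relu, "gelu": gelu, "identity": lambda x: as_tensor(x)}


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    m = Tensor(np.max(x.data, axis=axis, keepdims=True))  # shift, no grad needed
    e = (x - m).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    m = Tensor(np.max(x.data, axis=axis, keepdims=True))
    z = x - m
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer class targets."""
    targets = np.asarray(targets)
    if logits.ndim != 2:
        raise ValueError("logits must be (batch, n_classes)")
    logp = log_softmax(logits, axis=-1)
    picked = logp[np.arange(len(targets)), targets]
    return -picked.mean()
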