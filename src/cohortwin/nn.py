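"""Small neural-network layer toolkit on top of :mod:`cohortwin.autodiff`.

Provides seeded Glorot-initialized Linear/MLP layers and a GRU cell — the
only building blocks the model components require.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch when loading state")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch when loading state")
            p.data = np.asarray(a, dtype=np.float64).copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = Tensor(_glorot(rng, in_dim, out_dim), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class MLP(Module):
    """Feed-forward net with tanh hidden activations and a linear head."""

    def __init__(self, in_dim: int, hidden: list[int], out_dim: int,
                 rng: np.random.Generator):
        dims = [in_dim] + list(hidden) + [out_dim]
        self.layers = [Linear(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).tanh()
        return self.layers[-1](x)


class GRUCell(Module):
    """Standard gated recurrent unit cell.

    r_t = sigma(W_r [x_t, h_{t-1}] + b_r)
    z_t = sigma(W_z [x_t, h_{t-1}] + b_z)
    n_t = tanh(W_n [x_t, r_t * h_{t-1}] + b_n)
    h_t = (1 - z_t) * n_t + z_t * h_{t-1}
    """

    def __init__(self, in_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.hidden_dim = hidden_dim
        d = in_dim + hidden_dim
        self.W_r = Tensor(_glorot(rng, d, hidden_dim), requires_grad=True)
        self.b_r = Tensor(np.zeros(hidden_dim), requires_grad=True)
        self.W_z = Tensor(_glorot(rng, d, hidden_dim), requires_grad=True)
        self.b_z = Tensor(np.zeros(hidden_dim), requires_grad=True)
        self.W_n = Tensor(_glorot(rng, d, hidden_dim), requires_grad=True)
        self.b_n = Tensor(np.zeros(hidden_dim), requires_grad=True)

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        xh = concat([x, h], axis=-1)
        r = (xh @ self.W_r + self.b_r).sigmoid()
        z = (xh @ self.W_z + self.b_z).sigmoid()
        xrh = concat([x, r * h], axis=-1)
        n = (xrh @ self.W_n + self.b_n).tanh()
        return (1.0 - z) * n + z * h

    def init_state(self, batch: int) -> Tensor:
        return Tensor(np.zeros((batch, self.hidden_dim)))
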