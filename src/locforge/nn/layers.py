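"""Neural-network layers on the autograd engine.

Linear, strided valid convolution, max pooling, and a multi-layer
bidirectional LSTM, with Glorot-uniform initialization drawn from an
explicit numpy Generator so every model build is seed-reproducible.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = ["Module", "Linear", "Conv2d", "MaxPool2d", "BiLSTM"]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            p.data = a.copy()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.weight = Tensor(
            _glorot(rng, in_features, out_features, (in_features, out_features)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int,
        rng: np.random.Generator,
    ):
        fan_in = in_channels * kernel * kernel
        fan_out = out_channels * kernel * kernel
        self.weight = Tensor(
            _glorot(rng, fan_in, fan_out, (out_channels, in_channels, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.stride)


class MaxPool2d(Module):
    def __init__(self, pool: int, stride: int):
        self.pool = pool
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return x.maxpool2d(self.pool, self.stride)


class _LSTMDirection(Module):
    """One direction of one LSTM layer (gate order: input, forget, cell, output)."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.wx = Tensor(_glorot(rng, input_dim, 4 * hidden, (input_dim, 4 * hidden)), requires_grad=True)
        self.wh = Tensor(_glorot(rng, hidden, 4 * hidden, (hidden, 4 * hidden)), requires_grad=True)
        bias = np.zeros(4 * hidden)
        bias[hidden : 2 * hidden] = 1.0  # standard forget-gate bias
        self.bias = Tensor(bias, requires_grad=True)

    def __call__(self, xs: list[Tensor], reverse: bool) -> list[Tensor]:
        """Run over a list of T (N, D) tensors; returns T hidden states in input order."""
        N = xs[0].shape[0]
        H = self.hidden
        h = Tensor(np.zeros((N, H)))
        c = Tensor(np.zeros((N, H)))
        order = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
        outputs: list[Tensor | None] = [None] * len(xs)
        for t in order:
            gates = xs[t] @ self.wx + h @ self.wh + self.bias
            i = gates[:, 0:H].sigmoid()
            f = gates[:, H : 2 * H].sigmoid()
            g = gates[:, 2 * H : 3 * H].tanh()
            o = gates[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outputs[t] = h
        return outputs  # type: ignore[return-value]


class BiLSTM(Module):
    """Stacked bidirectional LSTM over (N, T, D) inputs.

    Each layer runs a forward and a backward pass and concatenates them
    per timestep; the final representation is the concatenation of the
    forward direction's last state and the backward direction's first-
    timestep state (its last processed step), giving a 2*hidden vector.
    """

    def __init__(self, input_dim: int, hidden: int, layers: int, rng: np.random.Generator):
        self.hidden = hidden
        self.layers = []
        dim = input_dim
        for _ in range(layers):
            self.layers.append(
                (_LSTMDirection(dim, hidden, rng), _LSTMDirection(dim, hidden, rng))
            )
            dim = 2 * hidden

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for fwd, bwd in self.layers:
            params.extend(fwd.parameters())
            params.extend(bwd.parameters())
        return params

    def __call__(self, x: Tensor) -> Tensor:
        T = x.shape[1]
        xs = [x[:, t, :] for t in range(T)]
        for fwd, bwd in self.layers:
            hf = fwd(xs, reverse=False)
            hb = bwd(xs, reverse=True)
            xs = [concat([hf[t], hb[t]], axis=1) for t in range(T)]
            last_final = concat([hf[T - 1], hb[0]], axis=1)
        return last_final
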