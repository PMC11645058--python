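"""Neural-network layers built on the autograd engine.

Initialisation follows the usual fan-in scaling (uniform Glorot/He style);
every layer draws its weights from the generator it is given so that model
construction is fully reproducible.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, batch_norm2d, concat, conv2d, max_pool2d

DTYPE = np.float32


class Module:
    """Minimal container: tracks parameters, sub-modules and train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        for attr in vars(self).values():
            if isinstance(attr, Module):
                yield attr
                yield from attr.modules()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params = []
        for m in [self, *self.modules()]:
            for attr in vars(m).values():
                if isinstance(attr, Tensor) and attr.requires_grad:
                    params.append(attr)
        # dedupe while keeping order (shared weights appear once)
        seen, out = set(), []
        for p in params:
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out

    def train(self):
        self.training = True
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable weights plus batch-norm running buffers, in a stable order."""
        arrays = [p.data for p in self.parameters()]
        for m in [self, *self.modules()]:
            if isinstance(m, BatchNorm2d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError(f"state mismatch: {len(own)} slots vs {len(arrays)} arrays")
        for dst, src in zip(own, arrays):
            if dst.shape != src.shape:
                raise ValueError(f"shape mismatch: {dst.shape} vs {src.shape}")
            dst[...] = src


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape).astype(DTYPE), requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _uniform(rng, (in_features, out_features), in_features)
        self.bias = _uniform(rng, (out_features,), in_features)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """Same-padding, unit-stride 2-D convolution; weight stored flattened."""

    def __init__(self, in_channels: int, out_channels: int, kernel: tuple[int, int],
                 rng: np.random.Generator):
        super().__init__()
        kh, kw = kernel
        self.kernel = (kh, kw)
        fan_in = in_channels * kh * kw
        self.weight = _uniform(rng, (out_channels, fan_in), fan_in)
        self.bias = _uniform(rng, (out_channels,), fan_in)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.kernel)


class BatchNorm2d(Module):
    def __init__(self, num_channels: int):
        super().__init__()
        self.gamma = Tensor(np.ones(num_channels, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(num_channels, dtype=DTYPE), requires_grad=True)
        self.running_mean = np.zeros(num_channels, dtype=DTYPE)
        self.running_var = np.ones(num_channels, dtype=DTYPE)

    def __call__(self, x: Tensor) -> Tensor:
        return batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training)


class ConvBlock(Module):
    """conv -> batch norm -> ReLU -> non-overlapping max pool."""

    def __init__(self, in_channels: int, out_channels: int, kernel: tuple[int, int],
                 pool: tuple[int, int], rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, kernel, rng)
        self.bn = BatchNorm2d(out_channels)
        self.pool = pool

    def __call__(self, x: Tensor) -> Tensor:
        return max_pool2d(self.bn(self.conv(x)).relu(), self.pool)


class GRU(Module):
    """Single-direction GRU layer (update/reset/new gates, torch convention)."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.hidden_size = hidden_size
        h = hidden_size
        self.w_ih = _uniform(rng, (input_size, 3 * h), h)
        self.w_hh = _uniform(rng, (h, 3 * h), h)
        self.b_ih = _uniform(rng, (3 * h,), h)
        self.b_hh = _uniform(rng, (3 * h,), h)

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """x: (T, B, F). Returns (outputs (T, B, H), last state (B, H))."""
        t, b, f = x.shape
        h = self.hidden_size
        # one big matmul for the input projections of every step
        xproj = (x.reshape(t * b, f) @ self.w_ih + self.b_ih).reshape(t, b, 3 * h)
        state = Tensor(np.zeros((b, h), dtype=x.data.dtype))
        outputs = []
        for step in range(t):
            xp = xproj[step]
            hp = state @ self.w_hh + self.b_hh
            z = (xp[:, :h] + hp[:, :h]).sigmoid()
            r = (xp[:, h:2 * h] + hp[:, h:2 * h]).sigmoid()
            n = (xp[:, 2 * h:] + r * hp[:, 2 * h:]).tanh()
            state = (1.0 - z) * n + z * state
            outputs.append(state)
        seq = concat([s.reshape(1, b, h) for s in outputs], axis=0)
        return seq, state


class BiGRU(Module):
    """Bidirectional GRU: forward pass plus a pass over the time-reversed input."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.fw = GRU(input_size, hidden_size, rng)
        self.bw = GRU(input_size, hidden_size, rng)

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (outputs (T, B, 2H), summary (B, 2H)).

        The summary concatenates the forward direction's final state with the
        backward direction's final state (its view of the first frame).
        """
        fw_seq, fw_last = self.fw(x)
        bw_seq, bw_last = self.bw(x.flip(0))
        seq = concat([fw_seq, bw_seq.flip(0)], axis=2)
        summary = concat([fw_last, bw_last], axis=1)
        return seq, summary
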