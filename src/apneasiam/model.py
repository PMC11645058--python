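"""Convolutional-recurrent embedding backbone.

A stack of convolutional blocks (same-padding conv, batch norm, ReLU,
non-overlapping max pool with a pooling size that grows with depth)
compresses the spectrogram; the surviving frequency rows are flattened
with the channels into a per-frame vector sequence, which bidirectional
GRU layers summarise; a linear head maps the sequence summary to a
128-dimensional embedding.

Hyperparameters are restricted to the random-search space (kernel sizes
[5,5]/[3,3]/[5,1]/[3,1], 2-4 conv blocks, GRU widths 32/64/128) unless
``allow_custom`` is set.
"""

from __future__ import annotations

import json
import os
from contextlib import contextmanager
from dataclasses import dataclass, asdict

import numpy as np

from .nn import BiGRU, ConvBlock, Linear, Module, Tensor

SEARCH_KERNELS = ((5, 5), (3, 3), (5, 1), (3, 1))
SEARCH_BLOCKS = (2, 3, 4)
SEARCH_GRU_HIDDEN = (32, 64, 128)
# per-block (freq, time) pooling; pooling grows with depth
POOL_SCHEDULE = ((2, 2), (2, 2), (4, 2), (4, 2))
EMBEDDING_DIM = 128


@dataclass(frozen=True)
class CRNNHyperParams:
    kernel_size: tuple[int, int] = (3, 3)
    n_conv_blocks: int = 2
    gru_hidden: int = 128
    conv_channels: int = 64
    n_gru_layers: int = 2
    embedding_dim: int = EMBEDDING_DIM
    allow_custom: bool = False

    def __post_init__(self):
        if self.embedding_dim != EMBEDDING_DIM:
            raise ValueError(f"embedding_dim is fixed at {EMBEDDING_DIM}")
        if self.allow_custom:
            return
        if tuple(self.kernel_size) not in SEARCH_KERNELS:
            raise ValueError(f"kernel_size {self.kernel_size} outside search space "
                             f"{SEARCH_KERNELS}")
        if self.n_conv_blocks not in SEARCH_BLOCKS:
            raise ValueError(f"n_conv_blocks {self.n_conv_blocks} outside search space "
                             f"{SEARCH_BLOCKS}")
        if self.gru_hidden not in SEARCH_GRU_HIDDEN:
            raise ValueError(f"gru_hidden {self.gru_hidden} outside search space "
                             f"{SEARCH_GRU_HIDDEN}")


def shape_trace(hp: CRNNHyperParams, input_shape: tuple[int, int]
                ) -> list[tuple[int, int, tuple[int, int]]]:
    """Per-block (freq, time) sizes after pooling, with the pool actually used.

    The frequency pool is clamped to the rows remaining (the frequency
    axis may legitimately shrink to one row); a time axis that would
    collapse to zero is a configuration error.
    """
    f, t = input_shape
    trace = []
    for i in range(hp.n_conv_blocks):
        pf, pt = POOL_SCHEDULE[i]
        pf = min(pf, f)
        f, t = f // pf, t // pt
        if t < 1:
            raise ValueError(f"conv block {i + 1} pools the time axis to zero "
                             f"(pool {pt} on {t * pt} frames)")
        trace.append((f, t, (pf, pt)))
    return trace


class EmbeddingNetwork(Module):
    """The full backbone; call with a (B, 1, bands, frames) tensor."""

    def __init__(self, hp: CRNNHyperParams, input_shape: tuple[int, int],
                 rng: np.random.Generator):
        super().__init__()
        self.hp = hp
        self.input_shape = tuple(input_shape)
        trace = shape_trace(hp, input_shape)
        self.blocks = []
        cin = 1
        for f, t, pool in trace:
            self.blocks.append(ConvBlock(cin, hp.conv_channels,
                                         tuple(hp.kernel_size), pool, rng))
            cin = hp.conv_channels
        self.final_freq, self.final_time = trace[-1][0], trace[-1][1]
        self.grus = []
        in_size = hp.conv_channels * self.final_freq
        for _ in range(hp.n_gru_layers):
            self.grus.append(BiGRU(in_size, hp.gru_hidden, rng))
            in_size = 2 * hp.gru_hidden
        self.head = Linear(2 * hp.gru_hidden, hp.embedding_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[2:] != self.input_shape:
            raise ValueError(f"expected input {self.input_shape}, got {x.shape[2:]}")
        for blk in self.blocks:
            x = blk(x)
        b = x.shape[0]
        # (B, C, F, T) -> sequence (T, B, C*F)
        seq = x.transpose((3, 0, 1, 2)).reshape(x.shape[3], b,
                                                x.shape[1] * x.shape[2])
        summary = None
        for gru in self.grus:
            seq, summary = gru(seq)
        return self.head(summary)


def build_model(hp: CRNNHyperParams, input_shape: tuple[int, int],
                seed: int = 0) -> EmbeddingNetwork:
    """Construct the network with reproducible initialisation."""
    rng = np.random.default_rng(seed)
    return EmbeddingNetwork(hp, input_shape, rng)


def count_parameters(model: EmbeddingNetwork) -> int:
    return int(sum(p.data.size for p in model.parameters()))


@contextmanager
def inference_mode(model: Module):
    """Eval mode with the autograd tape disabled for the model's weights."""
    params = model.parameters()
    was_training = model.training
    model.eval()
    for p in params:
        p.requires_grad = False
    try:
        yield
    finally:
        for p in params:
            p.requires_grad = True
        if was_training:
            model.train()


def embed(model: EmbeddingNetwork, values: np.ndarray,
          batch_size: int = 256) -> np.ndarray:
    """Embed one (bands, frames) window or a batch of them; returns float64.

    Single-window input yields a (128,) vector, batched input (n, 128).
    """
    arr = np.asarray(values, dtype=np.float32)
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    if arr.shape[1:] != model.input_shape:
        raise ValueError(f"expected features of shape {model.input_shape}, "
                         f"got {arr.shape[1:]}")
    out = np.empty((arr.shape[0], model.hp.embedding_dim), dtype=np.float64)
    with inference_mode(model):
        for lo in range(0, arr.shape[0], batch_size):
            chunk = arr[lo: lo + batch_size]
            emb = model(Tensor(chunk[:, None, :, :]))
            out[lo: lo + chunk.shape[0]] = emb.data.astype(np.float64)
    return out[0] if single else out


def save_checkpoint(path: str | os.PathLike, model: EmbeddingNetwork,
                    feature_fingerprint: str, extra: dict | None = None) -> None:
    """Weights + hyperparameters + feature fingerprint, refused on mismatch at load."""
    arrays = model.state_arrays()
    meta = {
        "hyperparams": asdict(model.hp),
        "input_shape": list(model.input_shape),
        "feature_fingerprint": feature_fingerprint,
        "extra": extra or {},
    }
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **{f"arr_{i}": a for i, a in enumerate(arrays)})


def load_checkpoint(path: str | os.PathLike,
                    feature_fingerprint: str | None = None
                    ) -> tuple[EmbeddingNetwork, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        arrays = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
    if feature_fingerprint is not None and \
            meta["feature_fingerprint"] != feature_fingerprint:
        raise ValueError("checkpoint was trained on a different feature configuration")
    hp = CRNNHyperParams(**{k: tuple(v) if k == "kernel_size" else v
                            for k, v in meta["hyperparams"].items()})
    model = build_model(hp, tuple(meta["input_shape"]))
    model.load_state_arrays(arrays)
    return model, meta
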