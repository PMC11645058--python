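"""Pair construction, contrastive loss, and the metric-learning stage.

Pairs follow the asymmetric scheme used for apnea screening: *similar*
pairs are apnea-apnea (pair label 0) and *dissimilar* pairs are
apnea-non-apnea (pair label 1); non-apnea windows are never paired with
each other.  The contrastive loss over a batch of N pairs with embedding
distances e_d and labels y is

    L = (1/N) * sum_i  (1 - y_i) * e_d_i**2  +  y_i * max(0, m - e_d_i)**2

with margin m = 2 by default: similar pairs are pulled together,
dissimilar pairs pushed beyond the margin.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .nn import Adam, Tensor
from .model import EmbeddingNetwork

_DIST_EPS = 1e-12


@dataclass(frozen=True)
class PairSample:
    """Indices of the two windows plus the pair label (0 similar, 1 dissimilar)."""

    index_a: int
    index_b: int
    pair_label: int

    def __post_init__(self):
        if self.index_a == self.index_b:
            raise ValueError("a pair cannot contain the same window twice")
        if self.pair_label not in (0, 1):
            raise ValueError("pair_label must be 0 (similar) or 1 (dissimilar)")


@dataclass(frozen=True)
class LossConfig:
    margin: float = 2.0

    def __post_init__(self):
        if self.margin <= 0:
            raise ValueError("margin must be positive")


@dataclass
class TrainingConfig:
    batch_size: int = 128
    epochs: int = 30
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    selection_criterion: str = "train_loss"  # or "val_loss"
    pairs_per_epoch: int | None = None  # None: the full enumerated pair set
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch_size must be at least 2")
        if self.selection_criterion not in ("train_loss", "val_loss"):
            raise ValueError("selection_criterion must be train_loss or val_loss")
        if self.optimizer != "adam":
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def make_pairs(labels: list[str] | np.ndarray, balance: bool = False,
               seed: int = 0) -> list[PairSample]:
    """Enumerate similar (apnea-apnea) and dissimilar (apnea x non-apnea) pairs.

    With ``balance`` on, the minority pair class is oversampled with
    replacement (seeded) to match the majority count.  Order is
    deterministic for a fixed seed.
    """
    labels = np.asarray(labels)
    apnea_idx = np.flatnonzero(labels == "apnea")
    non_idx = np.flatnonzero(labels == "non_apnea")
    if len(apnea_idx) == 0:
        raise ValueError("no apnea windows: cannot form pairs")
    if len(non_idx) == 0:
        raise ValueError("no non_apnea windows: cannot form pairs")
    similar = [PairSample(int(i), int(j), 0) for i, j in combinations(apnea_idx, 2)]
    dissimilar = [PairSample(int(i), int(j), 1) for i in apnea_idx for j in non_idx]
    if balance:
        rng = np.random.default_rng(seed)
        if len(similar) < len(dissimilar):
            extra = rng.integers(0, len(similar), size=len(dissimilar) - len(similar))
            similar = similar + [similar[k] for k in extra]
        elif len(dissimilar) < len(similar):
            extra = rng.integers(0, len(dissimilar), size=len(similar) - len(dissimilar))
            dissimilar = dissimilar + [dissimilar[k] for k in extra]
    pairs = similar + dissimilar
    rng = np.random.default_rng(seed + 1)
    order = rng.permutation(len(pairs))
    return [pairs[k] for k in order]


def sample_balanced_pairs(labels: np.ndarray, n_pairs: int,
                          rng: np.random.Generator) -> list[PairSample]:
    """Draw an exactly 50/50 similar/dissimilar pair batch without enumeration.

    The full Cartesian pair set of a realistic cohort is combinatorially
    huge; training regenerates a fresh balanced sample each epoch instead.
    """
    apnea_idx = np.flatnonzero(labels == "apnea")
    non_idx = np.flatnonzero(labels == "non_apnea")
    if len(apnea_idx) < 2 or len(non_idx) < 1:
        raise ValueError("need at least two apnea and one non_apnea window")
    n_sim = n_pairs // 2
    n_dis = n_pairs - n_sim
    pairs = []
    for _ in range(n_sim):
        i, j = rng.choice(apnea_idx, size=2, replace=False)
        pairs.append(PairSample(int(i), int(j), 0))
    a = rng.choice(apnea_idx, size=n_dis)
    b = rng.choice(non_idx, size=n_dis)
    pairs.extend(PairSample(int(i), int(j), 1) for i, j in zip(a, b))
    order = rng.permutation(len(pairs))
    return [pairs[k] for k in order]


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def contrastive_loss(distances: np.ndarray, labels: np.ndarray,
                     cfg: LossConfig = LossConfig()) -> float:
    """Mean contrastive loss of a batch of pair distances (see module docstring)."""
    d = np.asarray(distances, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if d.shape != y.shape:
        raise ValueError("distances and labels must have equal length")
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("pair labels must be 0 or 1")
    terms = (1.0 - y) * d ** 2 + y * np.maximum(0.0, cfg.margin - d) ** 2
    return float(terms.mean())


def _loss_tensor(emb_a: Tensor, emb_b: Tensor, labels: np.ndarray,
                 margin: float) -> Tensor:
    """Differentiable contrastive loss on a batch of embedding pairs."""
    diff = emb_a - emb_b
    d = ((diff * diff).sum(axis=1) + _DIST_EPS).sqrt()
    y = Tensor(labels.astype(np.float32))
    sim = (1.0 - y) * d * d
    dis = y * (margin - d).relu() ** 2.0
    return (sim + dis).mean()


def _epoch_pairs(labels: np.ndarray, cfg: TrainingConfig,
                 rng: np.random.Generator) -> list[PairSample]:
    if cfg.pairs_per_epoch is None:
        return make_pairs(labels, balance=True,
                          seed=int(rng.integers(0, 2 ** 31)))
    return sample_balanced_pairs(labels, cfg.pairs_per_epoch, rng)


def pair_distances(model: EmbeddingNetwork, values: np.ndarray,
                   pairs: list[PairSample]) -> np.ndarray:
    """Embedding distances of the given pairs under the current weights."""
    from .model import embed

    emb = embed(model, values)
    return np.array([euclidean_distance(emb[p.index_a], emb[p.index_b])
                     for p in pairs])


def train_siamese(model: EmbeddingNetwork, values: np.ndarray, labels: np.ndarray,
                  cfg: TrainingConfig,
                  val_values: np.ndarray | None = None,
                  val_labels: np.ndarray | None = None
                  ) -> tuple[list[np.ndarray], dict]:
    """Stage-one metric learning with shared weights on both branches.

    ``values`` is the (n, bands, frames) feature stack, ``labels`` the
    per-window class labels.  Returns (best weight arrays, history dict);
    the best epoch minimises the configured selection criterion.  Both
    pair members go through the same model instance, so weight sharing is
    structural rather than enforced by synchronisation.
    """
    if cfg.selection_criterion == "val_loss" and val_values is None:
        raise ValueError("val_loss selection requires validation data")
    labels = np.asarray(labels)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    margin = cfg.loss.margin
    history = {"train_loss": [], "val_loss": [], "wall_time_s": []}
    best = None
    best_score = np.inf
    x32 = np.asarray(values, dtype=np.float32)
    for epoch in range(cfg.epochs):
        t0 = time.perf_counter()
        pairs = _epoch_pairs(labels, cfg, rng)
        model.train()
        losses = []
        for lo in range(0, len(pairs), cfg.batch_size):
            batch = pairs[lo: lo + cfg.batch_size]
            ia = np.array([p.index_a for p in batch])
            ib = np.array([p.index_b for p in batch])
            y = np.array([p.pair_label for p in batch])
            # one forward through the shared weights for both branch inputs
            stacked = Tensor(np.concatenate([x32[ia], x32[ib]])[:, None, :, :])
            emb = model(stacked)
            emb_a, emb_b = emb[: len(batch)], emb[len(batch):]
            loss = _loss_tensor(emb_a, emb_b, y, margin)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {lo // cfg.batch_size}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        train_loss = float(np.mean(losses))
        history["train_loss"].append(train_loss)
        if val_values is not None:
            val_pairs = sample_balanced_pairs(
                np.asarray(val_labels), min(len(pairs), 512), rng)
            d = pair_distances(model, val_values, val_pairs)
            y = np.array([p.pair_label for p in val_pairs])
            history["val_loss"].append(contrastive_loss(d, y, cfg.loss))
        history["wall_time_s"].append(time.perf_counter() - t0)
        score = history[cfg.selection_criterion][-1]
        if score < best_score:
            best_score = score
            best = [a.copy() for a in model.state_arrays()]
    model.load_state_arrays(best)
    history["best_epoch"] = int(np.argmin(history[cfg.selection_criterion]))
    history["seed"] = cfg.seed
    return best, history
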