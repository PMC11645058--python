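"""Hyperparameter random search and patient-level data splits.

The search space crosses the architecture options (4 kernel sizes x 3
conv-block depths x 3 GRU widths) with the six input variants (Mel with
8/12/18/25/32 bands kept, plus the 1 kHz linear STFT) for 216
combinations; configurations are sampled uniformly without replacement.
Trials are ranked by validation F1, ties broken by fewer parameters.

Splits are patient-level: every patient belongs to exactly one of
train/validation/test.  ``REFERENCE_SPLITS`` carries the published
patient-ID lists (23/6/8 patients) for the public tracheal-audio corpus,
so experiments on that corpus can reuse them verbatim.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .features import FeatureConfig, MEL_BAND_OPTIONS
from .model import (
    CRNNHyperParams,
    SEARCH_BLOCKS,
    SEARCH_GRU_HIDDEN,
    SEARCH_KERNELS,
    build_model,
    count_parameters,
)
from .pipeline import FeatureTable, featurize_cohort, run_experiment
from .qc_eval import MetricsReport
from .siamese import TrainingConfig

INPUT_VARIANTS = tuple(f"mel{k}" for k in MEL_BAND_OPTIONS) + ("stft",)

DEFAULT_FRACTIONS = (0.65, 0.15, 0.20)

# Published patient-level splits (23 train / 6 validation / 8 test) for the
# public tracheal-audio corpus this pipeline targets.
REFERENCE_SPLITS = {
    1: {
        "train": [1112, 1110, 1108, 1106, 1095, 1093, 1089, 1088, 1086, 1082,
                  1071, 1069, 1057, 1045, 1041, 1039, 1037, 1028, 1022, 1010,
                  1008, 1006, 995],
        "validation": [1120, 1104, 1043, 1024, 1018, 1014],
        "test": [1118, 1116, 1073, 1059, 1026, 1020, 1000, 999],
    },
    2: {
        "train": [1120, 1118, 1116, 1112, 1110, 1108, 1106, 1104, 1095, 1093,
                  1089, 1088, 1086, 1082, 1073, 1071, 1069, 1059, 1057, 1045,
                  1043, 1041, 1039],
        "validation": [1010, 1008, 1006, 1000, 999, 995],
        "test": [1037, 1028, 1026, 1024, 1022, 1020, 1018, 1014],
    },
    3: {
        "train": [1086, 1082, 1073, 1071, 1069, 1059, 1057, 1045, 1043, 1041,
                  1039, 1037, 1028, 1026, 1024, 1022, 1020, 1018, 1014, 1010,
                  1008, 1006, 1000],
        "validation": [1120, 1118, 1116, 1112, 999, 995],
        "test": [1110, 1108, 1106, 1104, 1095, 1093, 1089, 1088],
    },
}


def variant_config(variant: str) -> FeatureConfig:
    """The FeatureConfig behind an input-variant name such as 'mel8' or 'stft'."""
    if variant == "stft":
        return FeatureConfig(feature_type="stft", analysis_sr=1000)
    if variant.startswith("mel"):
        k = int(variant[3:])
        return FeatureConfig(feature_type="mel", n_bands_kept=k)
    raise ValueError(f"unknown input variant {variant!r}")


@dataclass(frozen=True)
class SearchSpace:
    kernels: tuple = SEARCH_KERNELS
    conv_blocks: tuple = SEARCH_BLOCKS
    gru_hidden: tuple = SEARCH_GRU_HIDDEN
    input_variants: tuple = INPUT_VARIANTS

    @property
    def size(self) -> int:
        return (len(self.kernels) * len(self.conv_blocks) * len(self.gru_hidden)
                * len(self.input_variants))

    def enumerate(self) -> list[dict]:
        return [
            {"kernel_size": k, "n_conv_blocks": b, "gru_hidden": g, "variant": v}
            for k, b, g, v in product(self.kernels, self.conv_blocks,
                                      self.gru_hidden, self.input_variants)
        ]


def sample_configs(space: SearchSpace, n: int, seed: int = 0) -> list[dict]:
    """n distinct configurations drawn uniformly without replacement."""
    if n > space.size:
        raise ValueError(f"cannot sample {n} distinct configurations from a space "
                         f"of {space.size}")
    rng = np.random.default_rng(seed)
    all_configs = space.enumerate()
    picks = rng.choice(len(all_configs), size=n, replace=False)
    return [all_configs[i] for i in picks]


@dataclass
class SplitSpec:
    train: list = field(default_factory=list)
    validation: list = field(default_factory=list)
    test: list = field(default_factory=list)

    def __post_init__(self):
        groups = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("split partitions must be pairwise disjoint")

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump({"train": list(self.train), "validation": list(self.validation),
                       "test": list(self.test)}, fh, indent=1)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "SplitSpec":
        with open(path) as fh:
            data = json.load(fh)
        return cls(train=data["train"], validation=data["validation"],
                   test=data["test"])


def make_patient_splits(patient_ids, fractions=DEFAULT_FRACTIONS,
                        seed: int = 0) -> SplitSpec:
    """Shuffled patient-level split with largest-remainder rounding."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    ids = list(patient_ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 patients for a three-way split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    quotas = [f * len(ids) for f in fractions]
    sizes = [int(q) for q in quotas]
    remainders = [q - s for q, s in zip(quotas, sizes)]
    for _ in range(len(ids) - sum(sizes)):
        k = int(np.argmax(remainders))
        sizes[k] += 1
        remainders[k] = -1.0
    a, b = sizes[0], sizes[0] + sizes[1]
    return SplitSpec(train=shuffled[:a], validation=shuffled[a:b],
                     test=shuffled[b:])


@dataclass
class TrialResult:
    config: dict
    metrics: MetricsReport | None
    n_parameters: int | None
    seed: int
    error: str | None = None


def run_search(configs: list[dict],
               cohort: dict,
               split: SplitSpec,
               train_cfg: TrainingConfig,
               feature_tables: dict[str, FeatureTable] | None = None
               ) -> list[TrialResult]:
    """Train and score every configuration; rank by validation F1.

    Validation patients serve as the scoring partition for each trial
    (the test partition is reserved for the final model).  Features for
    each input variant are computed once and shared across trials; a
    precomputed ``feature_tables`` map can be supplied.  Failed trials
    are recorded with their error and skipped in the ranking.
    """
    feature_tables = dict(feature_tables or {})
    results: list[TrialResult] = []
    for cfg in configs:
        variant = cfg["variant"]
        try:
            if variant not in feature_tables:
                feature_tables[variant] = featurize_cohort(
                    cohort, variant_config(variant))
            table = feature_tables[variant]
            hp = CRNNHyperParams(kernel_size=tuple(cfg["kernel_size"]),
                                 n_conv_blocks=cfg["n_conv_blocks"],
                                 gru_hidden=cfg["gru_hidden"])
            result = run_experiment(
                table, train_ids=split.train, test_ids=split.validation,
                feature_config=variant_config(variant), hp=hp,
                train_cfg=train_cfg, readout_seed=train_cfg.seed,
            )
            n_params = count_parameters(
                build_model(hp, table.values.shape[1:], seed=train_cfg.seed))
            results.append(TrialResult(config=cfg, metrics=result.metrics,
                                       n_parameters=n_params, seed=train_cfg.seed))
        except Exception as exc:  # noqa: BLE001 - a failed trial must not kill the search
            results.append(TrialResult(config=cfg, metrics=None, n_parameters=None,
                                       seed=train_cfg.seed, error=str(exc)))
    ok = [r for r in results if r.error is None]
    failed = [r for r in results if r.error is not None]
    ok.sort(key=lambda r: (-r.metrics.f1, r.n_parameters))
    return ok + failed


def best_per_variant(results: list[TrialResult]) -> dict[str, TrialResult]:
    """The highest-ranked successful trial for each input variant present."""
    winners: dict[str, TrialResult] = {}
    for r in results:
        if r.error is None and r.config["variant"] not in winners:
            winners[r.config["variant"]] = r
    return winners
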