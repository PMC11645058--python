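"""Window-level evaluation metrics and per-patient separability QC.

Metrics treat *apnea* as the positive class:

    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F1        = 2 * precision * recall / (precision + recall)

The QC procedure screens for corrupted recordings (broken device,
external noise) by deliberately overfitting a fresh Siamese model on a
single patient's windows and measuring how far apart the mean apnea and
mean non-apnea embeddings end up.  Clean recordings separate to roughly
the contrastive margin; recordings whose breathing structure is drowned
in noise cannot be separated and land well below it, so a distance under
the threshold (default 1.5) flags the patient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .model import CRNNHyperParams, build_model, embed
from .siamese import TrainingConfig, euclidean_distance, train_siamese

QC_DISTANCE_THRESHOLD = 1.5


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall: float
    f1: float


@dataclass
class PatientQCReport:
    patient_id: str
    centroid_distance: float
    pca_coordinates: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    flagged: bool = False


def confusion_counts(predicted, truth) -> ConfusionCounts:
    """Confusion table with apnea as the positive class."""
    p = np.asarray(predicted)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    return ConfusionCounts(
        tp=int(np.sum((p == "apnea") & (t == "apnea"))),
        fp=int(np.sum((p == "apnea") & (t == "non_apnea"))),
        fn=int(np.sum((p == "non_apnea") & (t == "apnea"))),
        tn=int(np.sum((p == "non_apnea") & (t == "non_apnea"))),
    )


def precision_recall_f1(counts: ConfusionCounts) -> MetricsReport:
    """Precision/recall/F1; degenerate 0/0 ratios return 0 with a warning."""
    if counts.tp + counts.fn == 0:
        warnings.warn("no positive ground-truth windows; recall set to 0", stacklevel=2)
        recall = 0.0
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    if counts.tp + counts.fp == 0:
        warnings.warn("no positive predictions; precision set to 0", stacklevel=2)
        precision = 0.0
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return MetricsReport(precision=precision, recall=recall, f1=f1)


def evaluate(predicted, truth) -> MetricsReport:
    return precision_recall_f1(confusion_counts(predicted, truth))


def pca_project(embeddings: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Project embeddings onto their top-variance directions (for QC plots)."""
    x = np.asarray(embeddings, dtype=np.float64)
    if x.shape[0] < 2:
        raise ValueError("PCA projection needs at least two points")
    n_components = min(n_components, x.shape[0], x.shape[1])
    return PCA(n_components=n_components).fit_transform(x)


def class_centroid_distance(embeddings: np.ndarray, labels) -> float:
    """Euclidean distance between the mean apnea and mean non-apnea embedding."""
    y = np.asarray(labels)
    x = np.asarray(embeddings, dtype=np.float64)
    mean_apnea = x[y == "apnea"].mean(axis=0)
    mean_non = x[y == "non_apnea"].mean(axis=0)
    return euclidean_distance(mean_apnea, mean_non)


def patient_separability(patient_id: str, values: np.ndarray, labels,
                         hp: CRNNHyperParams, cfg: TrainingConfig,
                         threshold: float = QC_DISTANCE_THRESHOLD
                         ) -> PatientQCReport:
    """Overfit a fresh model on one patient and measure class separability.

    ``values`` is the patient's (n, bands, frames) feature stack; ``cfg``
    should be a small quick-overfit schedule.  The returned report carries
    the centroid distance, a 2-D PCA projection of all window embeddings
    for plotting, and the flag (distance < threshold).
    """
    y = np.asarray(labels)
    for cls in ("apnea", "non_apnea"):
        if not np.any(y == cls):
            raise ValueError(f"patient {patient_id} has no {cls} windows; "
                             "separability undefined")
    input_shape = values.shape[1:]
    model = build_model(hp, input_shape, seed=cfg.seed)
    train_siamese(model, values, y, cfg)
    emb = embed(model, values)
    dist = class_centroid_distance(emb, y)
    coords = pca_project(emb, 2)
    return PatientQCReport(patient_id=patient_id, centroid_distance=dist,
                           pca_coordinates=coords, labels=y,
                           flagged=dist < threshold)


def cohort_qc(per_patient: dict[str, tuple[np.ndarray, np.ndarray]],
              hp: CRNNHyperParams, cfg: TrainingConfig,
              threshold: float = QC_DISTANCE_THRESHOLD,
              rule: str = "absolute") -> list[PatientQCReport]:
    """Run the separability QC over a cohort.

    ``rule='absolute'`` flags distance < threshold; ``rule='cohort'``
    flags distances below mean - 3*SD of the cohort's distances.
    """
    reports = [
        patient_separability(pid, values, labels, hp, cfg, threshold)
        for pid, (values, labels) in per_patient.items()
    ]
    if rule == "cohort":
        d = np.array([r.centroid_distance for r in reports])
        cut = d.mean() - 3 * d.std()
        for r in reports:
            r.flagged = r.centroid_distance < cut
    elif rule != "absolute":
        raise ValueError("rule must be 'absolute' or 'cohort'")
    return reports


def plot_qc_scatter(report: PatientQCReport, path: str) -> None:
    """Save a 2-D scatter of the QC embedding projection (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    for cls, color in (("apnea", "tab:red"), ("non_apnea", "tab:blue")):
        mask = report.labels == cls
        ax.scatter(report.pca_coordinates[mask, 0], report.pca_coordinates[mask, 1],
                   s=8, label=cls, color=color, alpha=0.7)
    ax.set_title(f"{report.patient_id}: centroid distance "
                 f"{report.centroid_distance:.2f}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
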