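"""Stage-two classifier: nearest-centroid readout on the learned embeddings.

k-means with k = 2 is fitted on the *training* embeddings only; each
cluster takes the majority true label of its members, and new windows are
classified by the shortest Euclidean distance to a centroid.  SVC and KNN
readouts are provided for comparison experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

LABELS = ("apnea", "non_apnea")
TIE_LABEL = "non_apnea"  # conservative default at exact-tie distances


@dataclass
class CentroidModel:
    centroids: np.ndarray = field(repr=False)  # (2, embedding_dim)
    class_of_cluster: dict[int, str] = field(default_factory=dict)
    metric: str = "euclidean"

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        if self.centroids.shape[0] != 2:
            raise ValueError("exactly two centroids required")
        if set(self.class_of_cluster.keys()) != {0, 1} or \
                set(self.class_of_cluster.values()) != set(LABELS):
            raise ValueError("class_of_cluster must map {0,1} bijectively onto the classes")


@dataclass(frozen=True)
class Prediction:
    predicted_label: str
    distance_apnea: float
    distance_non_apnea: float
    window: object = None


def fit_readout(embeddings: np.ndarray, labels: list[str] | np.ndarray,
                seed: int = 0) -> CentroidModel:
    """Fit k-means (k=2, 10 seeded restarts) and map clusters by majority label."""
    x = np.asarray(embeddings, dtype=np.float64)
    y = np.asarray(labels)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two embedding points")
    for cls in LABELS:
        if not np.any(y == cls):
            raise ValueError(f"class {cls!r} absent from training labels")
    if np.allclose(x, x[0]):
        raise ValueError("all embedding points identical; clustering is degenerate")
    km = KMeans(n_clusters=2, n_init=10, tol=1e-4, max_iter=300, random_state=seed)
    assign = km.fit_predict(x)
    mapping: dict[int, str] = {}
    majority = {}
    for c in (0, 1):
        members = y[assign == c]
        n_apnea = int(np.sum(members == "apnea"))
        majority[c] = "apnea" if n_apnea > len(members) - n_apnea else "non_apnea"
    if majority[0] != majority[1]:
        mapping = majority
    else:
        # both clusters share a majority: the cluster nearer the apnea points
        # becomes apnea, the other non_apnea
        apnea_pts = x[y == "apnea"]
        mean_dist = [np.linalg.norm(apnea_pts - km.cluster_centers_[c], axis=1).mean()
                     for c in (0, 1)]
        apnea_cluster = int(np.argmin(mean_dist))
        mapping = {apnea_cluster: "apnea", 1 - apnea_cluster: "non_apnea"}
        warnings.warn("both clusters had the same majority label; mapping resolved "
                      "by distance to apnea points", stacklevel=2)
    return CentroidModel(centroids=km.cluster_centers_, class_of_cluster=mapping)


def predict(model: CentroidModel,
            embeddings: np.ndarray) -> list[Prediction]:
    """Assign each embedding the class of its nearest centroid (ties -> non_apnea)."""
    x = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
    if x.shape[1] != model.centroids.shape[1]:
        raise ValueError(f"embedding dim {x.shape[1]} does not match centroids "
                         f"({model.centroids.shape[1]})")
    d = np.linalg.norm(x[:, None, :] - model.centroids[None, :, :], axis=2)
    preds = []
    for row in d:
        dist = {model.class_of_cluster[c]: float(row[c]) for c in (0, 1)}
        if np.isclose(dist["apnea"], dist["non_apnea"]):
            label = TIE_LABEL
        else:
            label = min(dist, key=dist.get)
        preds.append(Prediction(predicted_label=label,
                                distance_apnea=dist["apnea"],
                                distance_non_apnea=dist["non_apnea"]))
    return preds


def predicted_labels(model: CentroidModel, embeddings: np.ndarray) -> np.ndarray:
    return np.array([p.predicted_label for p in predict(model, embeddings)])


def fit_alternative_readout(kind: str, embeddings: np.ndarray,
                            labels: list[str] | np.ndarray, seed: int = 0,
                            n_neighbors: int | None = None):
    """SVC or KNN readout, for comparing against the centroid rule."""
    x = np.asarray(embeddings, dtype=np.float64)
    y = np.asarray(labels)
    for cls in LABELS:
        if not np.any(y == cls):
            raise ValueError(f"class {cls!r} absent from training labels")
    if kind == "svc":
        clf = SVC(random_state=seed)
    elif kind == "knn":
        clf = KNeighborsClassifier(n_neighbors=n_neighbors or min(5, len(y)))
    else:
        raise ValueError(f"unknown readout kind {kind!r} (expected 'svc' or 'knn')")
    clf.fit(x, y)
    return clf
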