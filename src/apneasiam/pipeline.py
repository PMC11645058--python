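"""End-to-end experiment orchestration.

Given an annotated cohort and a patient-level split, this module
featurizes every recording, trains the Siamese embedding stage on the
training patients only, fits the k-means readout on the training
embeddings, and scores window predictions on the held-out patients.
Every run carries a leakage audit recording exactly which patients
entered pair construction and centroid fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import ApneaEvent, AudioRecording, load_events, load_recording
from .features import FeatureConfig, extract_features
from .model import CRNNHyperParams, build_model, embed
from .qc_eval import MetricsReport, evaluate
from .readout import CentroidModel, fit_readout, predict
from .siamese import TrainingConfig, train_siamese


@dataclass
class FeatureTable:
    """Stacked features of a set of windows with their labels and owners."""

    values: np.ndarray = field(repr=False)  # (n, bands, frames)
    labels: np.ndarray = field(repr=False)
    patient_ids: np.ndarray = field(repr=False)
    start_s: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.start_s is None:
            self.start_s = np.full(len(self.labels), np.nan)

    def subset(self, patients) -> "FeatureTable":
        mask = np.isin(self.patient_ids, list(patients))
        return FeatureTable(self.values[mask], self.labels[mask],
                            self.patient_ids[mask], self.start_s[mask])


@dataclass
class ExperimentResult:
    metrics: MetricsReport
    history: dict
    audit: dict
    readout: CentroidModel
    predictions: pd.DataFrame


def load_cohort(manifest: pd.DataFrame) -> dict[str, tuple[AudioRecording, list[ApneaEvent]]]:
    """Materialise a cohort manifest (from disk paths or in-memory columns)."""
    cohort = {}
    for _, row in manifest.iterrows():
        if "recording" in manifest.columns and isinstance(row.get("recording"),
                                                          AudioRecording):
            cohort[row["patient_id"]] = (row["recording"], row["events"])
        else:
            cohort[row["patient_id"]] = (load_recording(row["wav_path"]),
                                         load_events(row["events_path"]))
    return cohort


def featurize_cohort(cohort: dict[str, tuple[AudioRecording, list[ApneaEvent]]],
                     config: FeatureConfig) -> FeatureTable:
    values, labels, pids, starts = [], [], [], []
    for pid, (rec, events) in cohort.items():
        for f in extract_features(rec, events, config):
            values.append(f.values)
            labels.append(f.window.label)
            pids.append(pid)
            starts.append(f.window.start_s)
    return FeatureTable(np.stack(values), np.array(labels), np.array(pids),
                        np.array(starts))


def run_experiment(table: FeatureTable, train_ids, test_ids,
                   feature_config: FeatureConfig, hp: CRNNHyperParams,
                   train_cfg: TrainingConfig, val_ids=(),
                   readout_seed: int = 0) -> ExperimentResult:
    """Train both stages on the training patients and score the test patients."""
    train_ids, val_ids, test_ids = set(train_ids), set(val_ids), set(test_ids)
    if train_ids & test_ids or train_ids & val_ids or val_ids & test_ids:
        raise ValueError("train/validation/test patient sets must be disjoint")
    train = table.subset(train_ids)
    test = table.subset(test_ids)
    val = table.subset(val_ids) if val_ids else None

    input_shape = train.values.shape[1:]
    model = build_model(hp, input_shape, seed=train_cfg.seed)
    _, history = train_siamese(
        model, train.values, train.labels, train_cfg,
        val_values=None if val is None else val.values,
        val_labels=None if val is None else val.labels,
    )
    train_emb = embed(model, train.values)
    readout = fit_readout(train_emb, train.labels, seed=readout_seed)

    test_emb = embed(model, test.values)
    predictions_full = predict(readout, test_emb)
    pred = np.array([p.predicted_label for p in predictions_full])
    metrics = evaluate(pred, test.labels)

    audit = {
        "pair_patients": sorted(set(train.patient_ids)),
        "kmeans_patients": sorted(set(train.patient_ids)),
        "test_patients": sorted(test_ids),
        "feature_fingerprint": feature_config.fingerprint(),
    }
    predictions = pd.DataFrame({
        "patient_id": test.patient_ids,
        "start_s": test.start_s,
        "end_s": test.start_s + 6.0,
        "truth": test.labels,
        "predicted": pred,
        "distance_apnea": [p.distance_apnea for p in predictions_full],
        "distance_non_apnea": [p.distance_non_apnea for p in predictions_full],
    })
    return ExperimentResult(metrics=metrics, history=history, audit=audit,
                            readout=readout, predictions=predictions)
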