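"""Nearest-centroid classification over signature feature vectors.

Each sample's methylation profile is reduced to the signature's probe
vector; class centroids are the arithmetic means of the class members'
vectors.  Leave-one-out (LOO) prediction removes the sample, recomputes
both centroids, and assigns the sample to the nearer one.  Gastric (GC)
is the positive class for precision/recall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mss_screen import Signature
from .preprocess import NormalizedMatrix
from .synthetic_cohort import EC, GC

METRICS = ("euclidean", "correlation")


@dataclass
class CentroidModel:
    signature: Signature
    centroid_ec: np.ndarray
    centroid_gc: np.ndarray
    metric: str = "euclidean"


@dataclass
class PredictionMetrics:
    """Confusion counts with GC as the positive class.

    ``precision``/``recall`` are None when their denominator is zero —
    undefined is distinct from 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def precision(self):
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def recall(self):
        d = self.tp + self.fn
        return self.tp / d if d else None


def _values(matrix) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, NormalizedMatrix) else matrix


def signature_vector(column, signature: Signature) -> np.ndarray:
    """Extract one sample's feature vector in the signature's canonical order."""
    missing = [p for p in signature.probe_ids if p not in column.index]
    if missing:
        raise KeyError(f"signature probes missing from profile: {missing}")
    return column.loc[list(signature.probe_ids)].to_numpy(dtype=float)


def _feature_matrix(matrix, signature: Signature) -> np.ndarray:
    values = _values(matrix)
    missing = [p for p in signature.probe_ids if p not in values.index]
    if missing:
        raise KeyError(f"signature probes missing from matrix: {missing}")
    return values.loc[list(signature.probe_ids)].to_numpy(dtype=float).T  # samples x features


def _distances(x: np.ndarray, centroid: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return np.sqrt(((x - centroid[None, :]) ** 2).sum(axis=1))
    if metric == "correlation":
        xc = x - x.mean(axis=1, keepdims=True)
        cc = centroid - centroid.mean()
        denom = np.sqrt((xc**2).sum(axis=1) * (cc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (xc @ cc) / denom, 0.0)
        return 1.0 - r
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def _check_labels(labels: pd.Series) -> None:
    unknown = set(labels) - {EC, GC}
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")


def loo_predict(matrix, class_label, signature: Signature, metric: str = "euclidean") -> pd.DataFrame:
    """Leave-one-out nearest-centroid prediction for every sample.

    For each sample both class centroids are recomputed with the sample
    excluded; exact distance ties go to EC.  Returns a DataFrame indexed
    by sample_id with columns truth, predicted, dist_ec, dist_gc.
    """
    values = _values(matrix)
    labels = class_label.loc[values.columns] if isinstance(class_label, pd.Series) else pd.Series(
        np.asarray(class_label, dtype=object), index=values.columns
    )
    _check_labels(labels)
    x = _feature_matrix(matrix, signature)
    is_gc = (labels == GC).to_numpy()
    n_gc, n_ec = int(is_gc.sum()), int((~is_gc).sum())
    if n_gc < 2 or n_ec < 2:
        raise ValueError(
            f"each class needs >= 2 samples so no centroid collapses on exclusion (GC={n_gc}, EC={n_ec})"
        )
    sum_gc = x[is_gc].sum(axis=0)
    sum_ec = x[~is_gc].sum(axis=0)

    preds, d_ec_all, d_gc_all = [], [], []
    for i in range(x.shape[0]):
        if is_gc[i]:
            c_gc = (sum_gc - x[i]) / (n_gc - 1)
            c_ec = sum_ec / n_ec
        else:
            c_gc = sum_gc / n_gc
            c_ec = (sum_ec - x[i]) / (n_ec - 1)
        d_ec = float(_distances(x[i : i + 1], c_ec, metric)[0])
        d_gc = float(_distances(x[i : i + 1], c_gc, metric)[0])
        preds.append(GC if d_gc < d_ec else EC)  # ties -> EC
        d_ec_all.append(d_ec)
        d_gc_all.append(d_gc)
    return pd.DataFrame(
        {"truth": labels.to_numpy(), "predicted": preds, "dist_ec": d_ec_all, "dist_gc": d_gc_all},
        index=values.columns,
    )


def fit_centroids(matrix, class_label, signature: Signature, metric: str = "euclidean") -> CentroidModel:
    values = _values(matrix)
    labels = class_label.loc[values.columns] if isinstance(class_label, pd.Series) else pd.Series(
        np.asarray(class_label, dtype=object), index=values.columns
    )
    _check_labels(labels)
    x = _feature_matrix(matrix, signature)
    is_gc = (labels == GC).to_numpy()
    if is_gc.sum() == 0 or (~is_gc).sum() == 0:
        raise ValueError("both classes must be present to fit centroids")
    return CentroidModel(
        signature=signature,
        centroid_ec=x[~is_gc].mean(axis=0),
        centroid_gc=x[is_gc].mean(axis=0),
        metric=metric,
    )


def transfer_predict(model: CentroidModel, matrix, class_label=None) -> pd.DataFrame:
    """Assign new samples to the nearer of two pre-fit centroids."""
    values = _values(matrix)
    x = _feature_matrix(matrix, model.signature)
    d_ec = _distances(x, model.centroid_ec, model.metric)
    d_gc = _distances(x, model.centroid_gc, model.metric)
    preds = np.where(d_gc < d_ec, GC, EC)
    out = pd.DataFrame({"predicted": preds, "dist_ec": d_ec, "dist_gc": d_gc}, index=values.columns)
    if class_label is not None:
        labels = class_label.loc[values.columns] if isinstance(class_label, pd.Series) else pd.Series(
            np.asarray(class_label, dtype=object), index=values.columns
        )
        out.insert(0, "truth", labels.to_numpy())
    return out


def precision_recall(predicted, truth) -> PredictionMetrics:
    """Confusion counts with GC positive (a true positive is a gastric
    sample predicted gastric; a false positive an esophageal sample
    predicted gastric)."""
    predicted = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have the same length")
    unknown = (set(predicted) | set(truth)) - {EC, GC}
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    tp = int(((predicted == GC) & (truth == GC)).sum())
    fp = int(((predicted == GC) & (truth == EC)).sum())
    fn = int(((predicted == EC) & (truth == GC)).sum())
    tn = int(((predicted == EC) & (truth == EC)).sum())
    return PredictionMetrics(tp=tp, fp=fp, fn=fn, tn=tn)
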