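"""SVM classification of regulatory versus random loci from shape profiles.

Each locus is represented by the single-nucleotide ProT values in a fixed
window (default 2000 bp) around its midpoint.  An ensemble of linear
support-vector classifiers is trained on independent seeded balanced
train/test splits; accuracy is summarised as the mean held-out ROC AUC
across models (mAUC) plus a pooled ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.impute import SimpleImputer
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .regions import GenomicInterval, center_profile
from .shape import ShapeTrack

__all__ = [
    "ProfileFeatureSet",
    "ROCResult",
    "EnsembleResult",
    "featurize",
    "roc_auc",
    "train_ensemble",
]


@dataclass
class ProfileFeatureSet:
    """Regions x window matrix of per-base shape values used as features.

    The raw matrix may contain NaN (positions with no defined shape value);
    imputation with the training-set per-position mean and per-position
    standardisation happen inside each trained model, never on held-out data.
    Regions whose whole window is undefined are dropped at featurisation
    (``n_dropped`` counts them).
    """

    matrix: np.ndarray
    window: int
    intervals: list[GenomicInterval] = field(default_factory=list)
    n_dropped: int = 0
    imputation: str = "per-position training mean (fit within each model)"

    @property
    def n_regions(self) -> int:
        return len(self.matrix)


@dataclass(frozen=True)
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray


@dataclass
class EnsembleResult:
    """Per-model held-out AUCs, their mean (mAUC) and a pooled ROC curve."""

    n_models: int
    aucs: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    @property
    def mauc(self) -> float:
        return float(np.mean(self.aucs))


def featurize(
    tracks: Mapping[str, ShapeTrack],
    intervals: Sequence[GenomicInterval],
    window: int = 2000,
) -> ProfileFeatureSet:
    """Extract per-base shape windows centred on interval midpoints.

    Even window sizes are accepted: column ``j`` holds the track value at
    ``midpoint - (window-1)//2 + j``, matching the region-profiler midpoint
    rule (an even window extends one base further right of centre).
    """
    if not intervals:
        raise ValueError("no intervals supplied")
    if window < 1:
        raise ValueError("window must be positive")
    # reuse the profiling matrix, then trim one column for even windows
    prof = center_profile(tracks, intervals, window=window if window % 2 else window + 1)
    matrix = prof.matrix[:, :window]
    keep = np.isfinite(matrix).any(axis=1)
    if not keep.any():
        raise ValueError("every interval has an all-missing window")
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} interval(s) with all-missing windows", stacklevel=2)
    return ProfileFeatureSet(
        matrix=matrix[keep],
        window=window,
        intervals=[iv for iv, k in zip(intervals, keep) if k],
        n_dropped=n_dropped,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC curve and AUC for binary labels.

    The AUC equals the Mann-Whitney U statistic divided by
    ``n_pos * n_neg`` with half credit for tied scores.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    y = (labels == classes.max()).astype(int)
    fpr, tpr, _ = roc_curve(y, scores)
    return ROCResult(auc=float(roc_auc_score(y, scores)), fpr=fpr, tpr=tpr)


def _make_model():
    # linear kernel: 2000-dim profiles, deterministic fit, interpretable weights
    return make_pipeline(
        SimpleImputer(strategy="mean", keep_empty_features=True),
        StandardScaler(),
        SVC(kernel="linear", C=1.0),
    )


def train_ensemble(
    pos: ProfileFeatureSet,
    neg: ProfileFeatureSet,
    n_models: int = 9,
    seed: int = 0,
    test_fraction: float = 0.2,
) -> EnsembleResult:
    """Train ``n_models`` linear SVMs on independent balanced splits.

    Each model subsamples the larger class down to the smaller one, draws a
    seeded ``1 - test_fraction`` / ``test_fraction`` split, fits
    impute -> standardise -> linear SVM on the training part only, and is
    scored by ROC AUC on its disjoint held-out part.  mAUC is the arithmetic
    mean of the per-model AUCs; the pooled ROC concatenates all held-out
    decision scores.
    """
    if pos.window != neg.window:
        raise ValueError("positive and negative feature sets use different windows")
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    n_per_class = min(pos.n_regions, neg.n_regions)
    if n_per_class < 20:
        raise ValueError(f"need >= 20 examples per class, got {n_per_class}")
    n_test = max(int(round(test_fraction * n_per_class)), 2)
    n_train = n_per_class - n_test
    if n_train < 2:
        raise ValueError("class too small for the requested test fraction")
    rng = np.random.default_rng(seed)
    aucs = []
    pooled_scores, pooled_labels = [], []
    for _ in range(n_models):
        idx_pos = rng.permutation(pos.n_regions)[:n_per_class]
        idx_neg = rng.permutation(neg.n_regions)[:n_per_class]
        x_train = np.vstack([pos.matrix[idx_pos[:n_train]], neg.matrix[idx_neg[:n_train]]])
        y_train = np.concatenate([np.ones(n_train), np.zeros(n_train)])
        x_test = np.vstack([pos.matrix[idx_pos[n_train:]], neg.matrix[idx_neg[n_train:]]])
        y_test = np.concatenate([np.ones(n_test), np.zeros(n_test)])
        model = _make_model()
        model.fit(x_train, y_train)
        scores = model.decision_function(x_test)
        aucs.append(roc_auc_score(y_test, scores))
        pooled_scores.append(scores)
        pooled_labels.append(y_test)
    fpr, tpr, _ = roc_curve(np.concatenate(pooled_labels), np.concatenate(pooled_scores))
    return EnsembleResult(n_models=n_models, aucs=np.asarray(aucs), fpr=fpr, tpr=tpr)
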