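"""Weighted kNN tumor/healthy discrimination with patch-level voting.

Training spectra are the labeled representative spectra (one per ink
mark). A test patch is classified pixel by pixel with a weighted
k-nearest-neighbor rule (k = 10, Euclidean metric, squared inverse
distance weights); the patch is called malignant when at least
``vote_threshold`` of its 100 pixels are classified as tumor — 10 pixels
(~5 mm of tissue at 0.5 mm/pixel) by default, matching the clinical
re-excision criterion of > 4 mm of tumor on the surface.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .errors import BandGridError, ShapeMismatchError
from .labeling import LabeledSpectrum, PixelPatch

DEFAULT_K = 10
DEFAULT_VOTE_THRESHOLD = 10


@dataclass
class KNNModel:
    """Lazy learner: stores the training data verbatim plus a search index."""

    training_spectra: np.ndarray  # (n, bands)
    training_labels: np.ndarray  # (n,) in {0, 1}
    k: int = DEFAULT_K

    def __post_init__(self) -> None:
        self.training_spectra = np.asarray(self.training_spectra, dtype=float)
        self.training_labels = np.asarray(self.training_labels, dtype=int)
        n = self.training_spectra.shape[0]
        if self.training_labels.shape != (n,):
            raise ShapeMismatchError("one label per training spectrum required")
        if not set(np.unique(self.training_labels)) <= {0, 1}:
            raise ValueError("labels must be binary (0 = healthy, 1 = tumor)")
        if len(np.unique(self.training_labels)) < 2:
            raise ValueError("both classes must be present in the training set")
        if n < self.k:
            raise ValueError(f"need at least k={self.k} training spectra, got {n}")
        self._nn = NearestNeighbors(n_neighbors=self.k, metric="euclidean")
        self._nn.fit(self.training_spectra)

    @property
    def n_bands(self) -> int:
        return self.training_spectra.shape[1]


@dataclass
class PatchPrediction:
    """Pixel-level labels/scores of a patch and the voted patch label."""

    pixel_labels: np.ndarray  # (10, 10) binary
    pixel_scores: np.ndarray  # (10, 10) tumor score in [0, 1]
    tumor_pixel_count: int
    patch_label: int
    vote_threshold: int

    @property
    def patch_score(self) -> float:
        """ROC score of the patch: fraction of tumor-voted pixels."""
        return self.tumor_pixel_count / self.pixel_labels.size


def train_knn(labeled: list[LabeledSpectrum], k: int = DEFAULT_K) -> KNNModel:
    """Build the weighted kNN model from labeled representative spectra."""
    if not labeled:
        raise ValueError("empty training set")
    X = np.array([ls.spectrum for ls in labeled], dtype=float)
    y = np.array([ls.label for ls in labeled], dtype=int)
    return KNNModel(X, y, k=k)


def _scores_from_neighbors(
    dist: np.ndarray, labels: np.ndarray, query_norms: np.ndarray
) -> np.ndarray:
    """Tumor scores for a batch of queries given kNN distances and labels.

    Regular case: score = sum of 1/d^2 weights of tumor neighbors over the
    total weight. A query coinciding with one or more training points is
    decided by those points alone (the infinite-weight limit): majority
    label among the coincident points, ties to healthy, score 0 or 1.
    Coincidence is detected up to floating-point slack relative to the
    query magnitude (the search backend computes distances via the
    quadratic expansion, which does not return exact zeros).
    """
    scores = np.empty(dist.shape[0])
    zero_mask = dist <= 1e-6 * (1.0 + query_norms)[:, None]
    any_zero = zero_mask.any(axis=1)
    with np.errstate(divide="ignore"):
        w = 1.0 / dist**2
    for i in range(dist.shape[0]):
        if any_zero[i]:
            lab = labels[i][zero_mask[i]]
            scores[i] = 1.0 if lab.sum() * 2 > lab.size else 0.0
        else:
            scores[i] = w[i][labels[i] == 1].sum() / w[i].sum()
    return scores


def classify_pixels(model: KNNModel, spectra: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classify a batch of spectra; returns (labels, tumor scores).

    A pixel is labeled tumor iff its score exceeds 0.5; an exact 0.5 tie
    goes to healthy, favoring specificity.
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    if X.shape[1] != model.n_bands:
        raise BandGridError(
            f"query spectra have {X.shape[1]} bands, model expects {model.n_bands}"
        )
    dist, idx = model._nn.kneighbors(X)
    scores = _scores_from_neighbors(
        dist, model.training_labels[idx], np.linalg.norm(X, axis=1)
    )
    labels = (scores > 0.5).astype(int)
    return labels, scores


def classify_pixel(model: KNNModel, spectrum: np.ndarray) -> tuple[int, float]:
    """Classify a single spectrum; returns (label, tumor score)."""
    labels, scores = classify_pixels(model, np.asarray(spectrum)[None, :])
    return int(labels[0]), float(scores[0])


def classify_patch(
    model: KNNModel, patch: PixelPatch, vote_threshold: int = DEFAULT_VOTE_THRESHOLD
) -> PatchPrediction:
    """Pixel-wise classification of a 10x10 patch plus the vote rule.

    The patch is malignant iff at least ``vote_threshold`` of its 100
    pixels are classified as tumor.
    """
    H, W, m = patch.block.shape
    labels, scores = classify_pixels(model, patch.block.reshape(H * W, m))
    pixel_labels = labels.reshape(H, W)
    count = int(pixel_labels.sum())
    return PatchPrediction(
        pixel_labels=pixel_labels,
        pixel_scores=scores.reshape(H, W),
        tumor_pixel_count=count,
        patch_label=int(count >= vote_threshold),
        vote_threshold=vote_threshold,
    )


def split_by_patient(
    dataset: list[PixelPatch], train_fraction: float = 0.8, seed: int = 0
) -> tuple[list[PixelPatch], list[PixelPatch]]:
    """Partition patches into train/test with no patient in both halves.

    Patients (not patches) are shuffled with the given seed; the first
    ``round(train_fraction * n_patients)`` go to training. Deterministic
    under the seed.
    """
    patients = sorted({p.patient_id for p in dataset})
    if len(patients) < 2:
        raise ValueError("patient-level split requires at least two patients")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_train = int(round(train_fraction * len(patients)))
    n_train = max(1, min(len(patients) - 1, n_train))
    train_ids = {patients[i] for i in order[:n_train]}
    train = [p for p in dataset if p.patient_id in train_ids]
    test = [p for p in dataset if p.patient_id not in train_ids]
    return train, test
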