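"""Posture codebook of calibrated exemplar classifiers.

For every candidate patch an ensemble of K randomized exemplar SVMs is
trained (the single patch as positive against randomly sampled negative
sets), aggregated by a coordinatewise max-projection, and calibrated by
logistic regression.  The classifiers induce a symmetric pairwise
similarity between candidates; merging duplicates with normalized cuts on
that similarity yields a compact dictionary of prototypical paw postures,
each represented by its cluster medoid's calibrated classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .foreground import CandidateSet

DEFAULT_C = 0.01  # soft margin, cross-validated value
DEFAULT_K = 10  # ensemble size
DEFAULT_CODEBOOK_SIZE = 100


@dataclass
class ExemplarEnsemble:
    """K randomized exemplar classifiers for one candidate."""

    exemplar_index: int
    weights: np.ndarray  # (K, d)
    offsets: np.ndarray  # (K,)
    negative_sets: list[np.ndarray]  # index lists into the candidate set
    C: float

    def __post_init__(self) -> None:
        if self.weights.ndim != 2 or len(self.weights) != len(self.offsets):
            raise ValueError("weights/offsets shape mismatch")
        for ns in self.negative_sets:
            if self.exemplar_index in ns:
                raise ValueError("negative set contains the exemplar itself")


@dataclass
class CalibratedClassifier:
    """Max-projected exemplar weights with optional logistic calibration."""

    weights: np.ndarray
    slope: float | None = None
    intercept: float | None = None

    def score(self, x: np.ndarray) -> np.ndarray:
        """Raw activation <w, x>."""
        return np.asarray(x) @ self.weights

    def probability(self, x: np.ndarray) -> np.ndarray:
        if self.slope is None:
            raise ValueError("classifier is not calibrated")
        z = self.slope * self.score(x) + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


def exemplar_objective(
    w: np.ndarray, b: float, x_pos: np.ndarray, x_neg: np.ndarray, C: float
) -> float:
    """Regularised hinge objective of one exemplar classifier.

    ||w||^2 + C * max(0, 1 - (<w, x_pos> + b))
           + C/|neg| * sum_j max(0, 1 + <w, x_j> + b)
    """
    pos = max(0.0, 1.0 - (x_pos @ w + b))
    neg = np.maximum(0.0, 1.0 + x_neg @ w + b).sum() / len(x_neg)
    return float(w @ w + C * pos + C * neg)


def _fit_exemplar_svm(
    x_pos: np.ndarray, x_neg: np.ndarray, C: float, tol: float
) -> tuple[np.ndarray, float]:
    # Halving the objective maps it onto the standard SVM primal
    # (1/2||w||^2 + sum_m c_m hinge_m) with per-sample costs C/2 for the
    # positive and C/(2 n_neg) for each negative.
    n_neg = len(x_neg)
    x = np.vstack([x_pos[None, :], x_neg])
    y = np.r_[1.0, -np.ones(n_neg)]
    sw = np.r_[C / 2.0, np.full(n_neg, C / (2.0 * n_neg))]
    svm = SVC(kernel="linear", C=1.0, tol=tol)
    svm.fit(x, y, sample_weight=sw)
    return svm.coef_.ravel().copy(), float(svm.intercept_[0])


def train_exemplar_ensemble(
    i: int,
    candidates: CandidateSet | np.ndarray,
    K: int = DEFAULT_K,
    negative_set_size: int | None = None,
    C: float = DEFAULT_C,
    seed: int = 0,
    tol: float = 1e-5,
    extra_negatives: np.ndarray | None = None,
) -> ExemplarEnsemble:
    """Train K exemplar SVMs for candidate ``i`` on random negative sets.

    ``extra_negatives`` (e.g. background-only patches) are appended to
    every member's sampled negative set.
    """
    x = (
        candidates.descriptor_matrix()
        if isinstance(candidates, CandidateSet)
        else np.asarray(candidates, dtype=float)
    )
    n = len(x)
    if negative_set_size is None:
        negative_set_size = n // 2
    if K < 1:
        raise ValueError("K must be >= 1")
    if n <= negative_set_size + 1:
        raise ValueError("candidate set too small for requested negative sets")
    rng = np.random.default_rng(seed)
    pool = np.setdiff1d(np.arange(n), [i])
    weights, offsets, neg_sets = [], [], []
    for _ in range(K):
        neg_idx = rng.choice(pool, size=negative_set_size, replace=False)
        x_neg = x[neg_idx]
        if extra_negatives is not None and len(extra_negatives):
            x_neg = np.vstack([x_neg, extra_negatives])
        w, b = _fit_exemplar_svm(x[i], x_neg, C, tol)
        weights.append(w)
        offsets.append(b)
        neg_sets.append(np.sort(neg_idx))
    return ExemplarEnsemble(i, np.stack(weights), np.asarray(offsets), neg_sets, C)


def max_project(ensemble: ExemplarEnsemble) -> CalibratedClassifier:
    """Coordinatewise maximum over ensemble members (uncalibrated stage)."""
    if len(ensemble.weights) == 0:
        raise ValueError("empty ensemble")
    return CalibratedClassifier(weights=ensemble.weights.max(axis=0))


def calibrate(
    classifier: CalibratedClassifier,
    positive_scores: np.ndarray,
    negative_scores: np.ndarray,
    max_iter: int = 1000,
) -> CalibratedClassifier:
    """Two-parameter logistic map from raw score to probability (MLE)."""
    pos = np.asarray(positive_scores, dtype=float).ravel()
    neg = np.asarray(negative_scores, dtype=float).ravel()
    if len(pos) < 1 or len(neg) < 2:
        raise ValueError("need >= 1 positive and >= 2 negative scores")
    scores = np.r_[pos, neg]
    if np.ptp(scores) == 0:
        raise ValueError("degenerate calibration: all scores equal")
    y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
    lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=max_iter)
    lr.fit(scores[:, None], y)
    slope = float(lr.coef_[0, 0])
    if slope <= 0:
        raise ValueError("calibration is not increasing in the raw score")
    return CalibratedClassifier(
        weights=classifier.weights, slope=slope, intercept=float(lr.intercept_[0])
    )


def pairwise_similarity(
    descriptors: np.ndarray, classifiers: list[CalibratedClassifier]
) -> np.ndarray:
    """s(x_i, x_j) = 1/2 (<w_i, x_j> + <w_j, x_i>), symmetric by construction."""
    x = np.asarray(descriptors, dtype=float)
    if len(classifiers) != len(x):
        raise ValueError("need one max-projected classifier per candidate")
    w = np.stack([c.weights for c in classifiers])
    a = w @ x.T
    return (a + a.T) / 2.0


def spectral_medoid_clustering(
    similarity: np.ndarray, n_clusters: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized-cuts partition of a similarity graph plus cluster medoids.

    The similarity is shifted to be non-negative, the symmetric normalized
    Laplacian is eigendecomposed, and k-means (fixed seed) runs on the
    row-normalised spectral embedding.  Each cluster's medoid maximises
    within-cluster total similarity.  Returns (labels, medoid_indices);
    medoids are ordered by their cluster label.
    """
    s = np.asarray(similarity, dtype=float)
    n = len(s)
    if n_clusters > n:
        raise ValueError("more clusters than points")
    a = s - s.min() if s.min() < 0 else s.copy()
    np.fill_diagonal(a, 0.0)
    n_comp, _ = connected_components((a > 0).astype(int), directed=False)
    if n_comp > n_clusters:
        raise ValueError(
            f"similarity graph has {n_comp} connected components "
            f"(> {n_clusters} requested clusters)"
        )
    if n_clusters == n:
        return np.arange(n), np.arange(n)
    deg = a.sum(axis=1)
    dinv = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    lap = np.eye(n) - dinv[:, None] * a * dinv[None, :]
    _, vecs = eigh(lap, subset_by_index=[0, n_clusters - 1])
    rows = vecs / np.maximum(np.linalg.norm(vecs, axis=1, keepdims=True), 1e-12)
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    labels = km.fit_predict(rows)
    medoids = np.empty(n_clusters, dtype=int)
    for c in range(n_clusters):
        idx = np.nonzero(labels == c)[0]
        within = a[np.ix_(idx, idx)].sum(axis=1)
        medoids[c] = idx[int(np.argmax(within))]
    return labels, medoids


@dataclass
class Codebook:
    """Dictionary of prototypical posture classifiers (cluster medoids)."""

    classifiers: list[CalibratedClassifier]
    medoid_indices: np.ndarray
    assignments: np.ndarray
    patch_size: int = 40
    grid: tuple[int, int] = (10, 10)
    n_orientations: int = 9

    def __len__(self) -> int:
        return len(self.classifiers)

    @property
    def weight_matrix(self) -> np.ndarray:
        return np.stack([c.weights for c in self.classifiers])

    def raw_scores(self, descriptor: np.ndarray) -> np.ndarray:
        """Raw activations; accepts one descriptor (d,) or a batch (..., d)."""
        return np.asarray(descriptor, dtype=float) @ self.weight_matrix.T

    def probabilities(self, descriptor: np.ndarray) -> np.ndarray:
        z = self._slopes * self.raw_scores(descriptor) + self._intercepts
        return 1.0 / (1.0 + np.exp(-z))

    @property
    def _slopes(self) -> np.ndarray:
        return np.array([c.slope for c in self.classifiers])

    @property
    def _intercepts(self) -> np.ndarray:
        return np.array([c.intercept for c in self.classifiers])

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            weights=self.weight_matrix,
            slopes=self._slopes,
            intercepts=self._intercepts,
            medoid_indices=self.medoid_indices,
            assignments=self.assignments,
        )
        path.with_suffix(".json").write_text(
            json.dumps(
                {
                    "n_entries": len(self),
                    "patch_size": self.patch_size,
                    "grid": list(self.grid),
                    "n_orientations": self.n_orientations,
                }
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "Codebook":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        classifiers = [
            CalibratedClassifier(w, float(s), float(b))
            for w, s, b in zip(
                arrays["weights"], arrays["slopes"], arrays["intercepts"]
            )
        ]
        return cls(
            classifiers=classifiers,
            medoid_indices=arrays["medoid_indices"],
            assignments=arrays["assignments"],
            patch_size=int(meta["patch_size"]),
            grid=tuple(meta["grid"]),
            n_orientations=int(meta["n_orientations"]),
        )


def build_codebook(
    similarity: np.ndarray,
    classifiers: list[CalibratedClassifier],
    n_entries: int = DEFAULT_CODEBOOK_SIZE,
    seed: int = 0,
    patch_size: int = 40,
    grid: tuple[int, int] = (10, 10),
    n_orientations: int = 9,
) -> Codebook:
    """Merge duplicate candidates by normalized cuts into a posture dictionary."""
    labels, medoids = spectral_medoid_clustering(similarity, n_entries, seed)
    return Codebook(
        classifiers=[classifiers[m] for m in medoids],
        medoid_indices=medoids,
        assignments=labels,
        patch_size=patch_size,
        grid=grid,
        n_orientations=n_orientations,
    )


def train_posture_codebook(
    candidates: CandidateSet,
    K: int = DEFAULT_K,
    negative_set_size: int | None = None,
    C: float = DEFAULT_C,
    n_entries: int = DEFAULT_CODEBOOK_SIZE,
    seed: int = 0,
    n_calibration_neighbors: int = 24,
    svm_tol: float = 1e-4,
    background_negatives: np.ndarray | None = None,
) -> Codebook:
    """Full codebook stage: ensembles -> max-projection -> calibration -> cuts.

    Calibration positives for exemplar i are its own score together with
    the scores of its nearest-neighbour candidates (near-duplicate
    postures), so the logistic midpoint separates the exemplar's posture
    from the negative pool rather than stepping exactly at the single
    positive.  Negatives are the max-projected classifier's scores on the
    exemplar's pooled negative sets.
    """
    x = candidates.descriptor_matrix()
    n, _ = x.shape
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=min(n_calibration_neighbors + 1, n)).fit(x)
    _, nbr = nn.kneighbors(x)
    calibrated: list[CalibratedClassifier] = []
    for i in range(n):
        ens = train_exemplar_ensemble(
            i, x, K=K, negative_set_size=negative_set_size, C=C,
            seed=int(rng.integers(2**31)), tol=svm_tol,
            extra_negatives=background_negatives,
        )
        clf = max_project(ens)
        pos_idx = nbr[i]  # includes i itself
        neg_pool = np.setdiff1d(np.unique(np.concatenate(ens.negative_sets)), pos_idx)
        neg_scores = clf.score(x[neg_pool])
        if background_negatives is not None and len(background_negatives):
            neg_scores = np.r_[neg_scores, clf.score(background_negatives)]
        pos_scores = clf.score(x[pos_idx])
        calibrated.append(calibrate(clf, pos_scores, neg_scores))
    sim = pairwise_similarity(x, calibrated)
    return build_codebook(
        sim,
        calibrated,
        n_entries=n_entries,
        seed=seed,
        patch_size=candidates.patch_size,
    )
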