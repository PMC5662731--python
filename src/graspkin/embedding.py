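"""Posture embeddings, 2-D visualisation and phase-resolved statistics.

Each detected paw is represented by the activation of every codebook
classifier; a grasp becomes the time-ordered matrix of these embeddings.
For visualisation the high-dimensional embeddings are projected to 2-D
with t-SNE; grasps are drawn as polygonal chains and summarised by a mean
grasping contour over normalised time.  Phase-deviation bars quantify,
per time interval of the grasp, how far a test cohort's mean posture sits
from the baseline mean in units of the baseline spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.manifold import TSNE

from .codebook import Codebook


@dataclass
class GraspSequence:
    """An M-frame grasp as a sequence of posture embeddings (rows)."""

    embeddings: np.ndarray  # (M, |D|)
    meta: dict = field(default_factory=dict)
    apex_index: int | None = None  # frame of closest pellet approach

    def __post_init__(self) -> None:
        self.embeddings = np.atleast_2d(np.asarray(self.embeddings, dtype=float))
        if len(self.embeddings) < 1:
            raise ValueError("a grasp needs at least one frame")

    def __len__(self) -> int:
        return len(self.embeddings)

    def phases(self, align_apex: bool = True) -> np.ndarray:
        """Normalised time in [0, 1); the apex maps to 0.5 when known."""
        m = len(self)
        lin = np.arange(m) / m
        if not align_apex or self.apex_index is None or m < 3:
            return lin
        a = min(max(self.apex_index, 1), m - 2)
        t = np.arange(m, dtype=float)
        out = np.where(
            t <= a, 0.5 * t / a, 0.5 + 0.5 * (t - a) / (m - a)
        )
        return np.clip(out, 0.0, 1.0 - 1e-9)


def embed_posture(
    descriptor: np.ndarray, codebook: Codebook, calibrated: bool = True
) -> np.ndarray:
    """Activation of every codebook classifier on one detection.

    Calibrated probabilities by default (comparable across videos); the
    raw linear activations remain available and are linear in the input.
    """
    descriptor = np.asarray(descriptor, dtype=float)
    if descriptor.shape[-1] != codebook.weight_matrix.shape[1]:
        raise ValueError(
            f"descriptor dimension {descriptor.shape[-1]} does not match "
            f"codebook ({codebook.weight_matrix.shape[1]})"
        )
    if calibrated:
        return codebook.probabilities(descriptor)
    return codebook.raw_scores(descriptor)


def embed_2d(
    embeddings: np.ndarray,
    seed: int = 0,
    perplexity: float = 30.0,
    baseline_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Neighbourhood-preserving 2-D projection (t-SNE, PCA-initialised).

    Deterministic under a fixed seed.  Axes are scaled to units of the
    baseline standard deviation: per axis, the SD of the points selected
    by ``baseline_mask`` (all points if omitted).
    """
    x = np.asarray(embeddings, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 points for a 2-D embedding")
    perplexity = min(perplexity, (len(x) - 1) / 3.0)
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
        max_iter=500,
    )
    y = ts.fit_transform(x)
    ref = y if baseline_mask is None else y[np.asarray(baseline_mask, bool)]
    sd = ref.std(axis=0)
    return y / np.maximum(sd, 1e-12)


def mean_grasp_contour(
    paths: list[np.ndarray],
    n_phases: int = 20,
    phases: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Average path over normalised grasp time.

    ``paths`` are per-grasp (M_j, d) point sequences (typically the 2-D
    embedded postures of each grasp).  Each grasp is binned into
    ``n_phases`` equal time intervals; the per-bin mean over all grasps is
    returned in time order.  Empty bins are linearly interpolated.
    """
    if not paths or any(len(p) == 0 for p in paths):
        raise ValueError("all grasps must be non-empty")
    d = paths[0].shape[1]
    sums = np.zeros((n_phases, d))
    counts = np.zeros(n_phases)
    for gi, p in enumerate(paths):
        m = len(p)
        ph = phases[gi] if phases is not None else np.arange(m) / m
        bins = np.minimum((ph * n_phases).astype(int), n_phases - 1)
        for b, point in zip(bins, p):
            sums[b] += point
            counts[b] += 1
    contour = np.full((n_phases, d), np.nan)
    filled = counts > 0
    contour[filled] = sums[filled] / counts[filled, None]
    if not filled.all():
        idx = np.arange(n_phases)
        for k in range(d):
            contour[~filled, k] = np.interp(
                idx[~filled], idx[filled], contour[filled, k]
            )
    return contour


@dataclass
class PhaseBars:
    """Per-interval deviation of test postures from baseline, in baseline SD."""

    deviations: np.ndarray  # (n_intervals,)
    baseline_sd: np.ndarray
    n_intervals: int

    def __post_init__(self) -> None:
        if (self.deviations < 0).any():
            raise ValueError("deviations must be non-negative")


def _interval_index(phases: np.ndarray, n_intervals: int) -> np.ndarray:
    return np.minimum((phases * n_intervals).astype(int), n_intervals - 1)


def phase_deviation_bars(
    baseline: list[GraspSequence],
    test: list[GraspSequence],
    n_intervals: int = 5,
) -> PhaseBars:
    """Distance between baseline and test mean embeddings per grasp interval,
    relative to the baseline SD of that interval.

    The baseline SD of an interval is the standard deviation of the
    baseline postures' distances to their interval mean.  Identical sets
    give exactly zero bars.
    """
    if not baseline or not test:
        raise ValueError("both grasp sets must be non-empty")

    def pooled(grasps: list[GraspSequence]) -> tuple[np.ndarray, np.ndarray]:
        rows, bins = [], []
        for g in grasps:
            ph = g.phases()
            rows.append(g.embeddings)
            bins.append(_interval_index(ph, n_intervals))
        return np.vstack(rows), np.concatenate(bins)

    b_rows, b_bins = pooled(baseline)
    t_rows, t_bins = pooled(test)
    dev = np.empty(n_intervals)
    sds = np.empty(n_intervals)
    for k in range(n_intervals):
        bsel, tsel = b_bins == k, t_bins == k
        if not bsel.any():
            raise ValueError(f"interval {k} contains no baseline postures")
        if not tsel.any():
            raise ValueError(f"interval {k} contains no test postures")
        mb = b_rows[bsel].mean(axis=0)
        mt = t_rows[tsel].mean(axis=0)
        spread = np.linalg.norm(b_rows[bsel] - mb, axis=1)
        sd = spread.std()
        sds[k] = sd
        dev[k] = np.linalg.norm(mt - mb) / max(sd, 1e-12)
    return PhaseBars(deviations=dev, baseline_sd=sds, n_intervals=n_intervals)
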