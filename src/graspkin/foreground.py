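"""Foreground extraction and candidate paw regions.

A session is flattened to a pixels x frames matrix and split into a
low-rank background model plus a sparse foreground component by principal
component pursuit (inexact augmented-Lagrangian solver).  Candidate
regions are sampled from the foreground support, described by HOG over a
fixed cell grid, and pruned of rare outliers by k-nearest-neighbour
density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

DEFAULT_GRID = (10, 10)
DEFAULT_ORIENTATIONS = 9
DEFAULT_PATCH = 40
CELL = 4  # pixels per HOG cell at the default patch size
HOG_NOISE_FLOOR = 0.25  # gradient-energy floor per cell (intensity units)


@dataclass
class DecompositionResult:
    low_rank: np.ndarray  # (pixels, frames)
    sparse: np.ndarray  # (pixels, frames)
    residual_norm: float
    converged: bool
    n_iter: int
    frame_shape: tuple[int, int] | None = None

    def sparse_frames(self) -> np.ndarray:
        """Sparse component reshaped to (n_frames, H, W)."""
        if self.frame_shape is None:
            raise ValueError("frame_shape unknown")
        h, w = self.frame_shape
        return self.sparse.T.reshape(-1, h, w)


@dataclass(frozen=True)
class CandidateRegion:
    frame: int
    box: tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open
    descriptor: np.ndarray

    @property
    def center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.box
        return ((x0 + x1 - 1) / 2.0, (y0 + y1 - 1) / 2.0)


@dataclass
class CandidateSet:
    members: list[CandidateRegion]
    seed: int
    patch_size: int = DEFAULT_PATCH

    def __len__(self) -> int:
        return len(self.members)

    def descriptor_matrix(self) -> np.ndarray:
        return np.stack([m.descriptor for m in self.members])

    def keys(self) -> list[tuple[int, tuple[int, int, int, int]]]:
        return [(m.frame, m.box) for m in self.members]


def decompose_low_rank_sparse(
    frames: np.ndarray,
    sparsity_weight: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 200,
) -> DecompositionResult:
    """Principal component pursuit: frames = low-rank background + sparse foreground.

    ``frames`` may be a (n_frames, H, W) stack or an already-flattened
    (pixels, frames) matrix.  The sparsity weight defaults to
    ``1/sqrt(max(pixels, frames))``.  Converged when the relative
    reconstruction residual falls below ``tol``; otherwise a warning flag
    is set and the best iterate returned.
    """
    frames = np.asarray(frames, dtype=float)
    frame_shape = None
    if frames.ndim == 3:
        n, h, w = frames.shape
        frame_shape = (h, w)
        d = frames.reshape(n, h * w).T
    elif frames.ndim == 2:
        d = frames
    else:
        raise ValueError("frames must be a 2-D matrix or 3-D stack")
    if d.shape[1] < 2:
        raise ValueError("need at least 2 frames")
    if not np.isfinite(d).all():
        raise ValueError("non-finite pixel values in input")

    norm_d = np.linalg.norm(d)
    if norm_d == 0:
        return DecompositionResult(
            np.zeros_like(d), np.zeros_like(d), 0.0, True, 0, frame_shape
        )
    lam = sparsity_weight or 1.0 / np.sqrt(max(d.shape))

    # inexact ALM (Lin et al. style initialisation)
    two_norm = np.linalg.norm(d, 2)
    inf_norm = np.abs(d).max() / lam
    y = d / max(two_norm, inf_norm)
    mu = 1.25 / two_norm
    rho = 1.5
    mu_max = mu * 1e7
    s = np.zeros_like(d)
    low = np.zeros_like(d)
    residual = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u, sig, vt = np.linalg.svd(d - s + y / mu, full_matrices=False)
        sig = np.maximum(sig - 1.0 / mu, 0.0)
        low = (u * sig) @ vt
        tmp = d - low + y / mu
        s = np.sign(tmp) * np.maximum(np.abs(tmp) - lam / mu, 0.0)
        z = d - low - s
        y = y + mu * z
        mu = min(mu * rho, mu_max)
        residual = np.linalg.norm(z) / norm_d
        if residual <= tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"principal component pursuit: max_iter={max_iter} reached "
            f"(residual {residual:.2e})",
            RuntimeWarning,
        )
    return DecompositionResult(low, s, float(residual), converged, it, frame_shape)


def foreground_mask(
    decomp: DecompositionResult,
    n_mads: float = 3.0,
    signed: bool = False,
    min_blob: int = 0,
) -> np.ndarray:
    """Binarise the sparse component at ``n_mads`` robust SDs per frame.

    By default the magnitude |S| is thresholded.  With ``signed=True``
    only positive excursions count: the paw is brighter than the dim cage
    background, so the negative "ghost" the background model leaves at
    the vacated rest position is excluded.  The per-frame MAD scale is
    floored at a tenth of the session-wide scale so frames whose sparse
    component is mostly exact zeros do not admit pure noise.
    """
    s = decomp.sparse_frames()
    flat = np.abs(s.reshape(len(s), -1))
    mad = np.median(np.abs(flat - np.median(flat, axis=1, keepdims=True)), axis=1)
    gmad = np.median(np.abs(flat - np.median(flat)))
    thr = n_mads * 1.4826 * np.maximum.reduce(
        [mad, np.full_like(mad, 0.1 * gmad), np.full_like(mad, 1e-12)]
    )
    values = s if signed else np.abs(s)
    mask = values > thr[:, None, None]
    if min_blob > 0:
        from scipy.ndimage import label

        for f in range(len(mask)):
            lab, n_lab = label(mask[f])
            if n_lab:
                sizes = np.bincount(lab.ravel())
                small = np.nonzero(sizes < min_blob)[0]
                mask[f] &= ~np.isin(lab, small[small > 0])
    return mask


# ---------------------------------------------------------------------------
# HOG


def _cell_histograms(
    img: np.ndarray, cell_h: int, cell_w: int, n_orientations: int,
    noise_floor: float,
) -> np.ndarray:
    """Orientation histograms per cell, normalised with a noise floor.

    Gradients are central differences; unsigned orientations are binned
    by gradient magnitude.  Each cell histogram v is mapped to
    ``v / sqrt(|v|^2 + eps^2)`` (then clipped at 0.2 and renormalised the
    same way), with eps an absolute gradient-energy floor: cells whose
    gradient energy is dominated by sensor noise stay near zero instead
    of being blown up to unit norm, which makes the descriptor transfer
    across recordings of differing noise.
    """
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    gy, gx = np.gradient(img)
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), np.pi)
    bins = np.minimum((ang / np.pi * n_orientations).astype(int), n_orientations - 1)
    ch, cw = h // cell_h, w // cell_w
    hist = np.zeros((ch, cw, n_orientations))
    cy = np.minimum(np.arange(h) // cell_h, ch - 1)
    cx = np.minimum(np.arange(w) // cell_w, cw - 1)
    flat = (
        cy[: ch * cell_h, None] * (cw * n_orientations)
        + cx[None, : cw * cell_w] * n_orientations
        + bins[: ch * cell_h, : cw * cell_w]
    )
    np.add.at(
        hist.reshape(-1), flat.ravel(), mag[: ch * cell_h, : cw * cell_w].ravel()
    )
    return _normalise_cells(hist, cell_h * cell_w, noise_floor)


def _normalise_cells(hist: np.ndarray, cell_area: float, noise_floor: float
                     ) -> np.ndarray:
    eps = noise_floor * cell_area / 16.0  # floor scaled to cell area
    norm = np.sqrt((hist**2).sum(axis=-1, keepdims=True) + eps**2)
    out = np.clip(hist / norm, 0, 0.2)
    # renormalise, again against a floor so weak cells are not re-inflated
    norm2 = np.sqrt((out**2).sum(axis=-1, keepdims=True) + 0.3**2)
    return out / norm2


def hog_at_offsets(
    crop: np.ndarray,
    offsets: list[tuple[int, int]],
    patch_size: int,
    grid: tuple[int, int] = DEFAULT_GRID,
    n_orientations: int = DEFAULT_ORIENTATIONS,
    noise_floor: float = HOG_NOISE_FLOOR,
) -> np.ndarray:
    """Descriptors of ``patch_size`` windows at pixel offsets within a crop.

    Gradients are computed once over the crop, so evaluating many
    overlapping stride-1 windows (local refinement around a coarse
    detection) costs one gradient pass plus a histogram per window.
    """
    crop = np.asarray(crop, dtype=float)
    gh, gw = grid
    ch, cw = patch_size // gh, patch_size // gw
    gy, gx = np.gradient(crop)
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), np.pi)
    bins = np.minimum((ang / np.pi * n_orientations).astype(int), n_orientations - 1)
    rows = (np.arange(patch_size) // ch)[:, None]
    cols = (np.arange(patch_size) // cw)[None, :]
    cell_base = (rows * gw + cols) * n_orientations
    nfeat = gh * gw * n_orientations
    out = np.empty((len(offsets), nfeat))
    for k, (x0, y0) in enumerate(offsets):
        idx = cell_base + bins[y0 : y0 + patch_size, x0 : x0 + patch_size]
        hist = np.bincount(
            idx.ravel(),
            weights=mag[y0 : y0 + patch_size, x0 : x0 + patch_size].ravel(),
            minlength=nfeat,
        ).reshape(gh, gw, n_orientations)
        out[k] = _normalise_cells(hist, ch * cw, noise_floor).reshape(-1)
    return out


def compute_hog(
    patch: np.ndarray,
    grid: tuple[int, int] = DEFAULT_GRID,
    n_orientations: int = DEFAULT_ORIENTATIONS,
    noise_floor: float = HOG_NOISE_FLOOR,
) -> np.ndarray:
    """HOG descriptor over a fixed cell grid (length = gh * gw * n_orientations).

    Unsigned orientations, one cell per normalisation block, noise-floored
    L2-Hys normalisation; the descriptor is non-negative, deterministic,
    and all-zero for a constant patch.
    """
    patch = np.asarray(patch, dtype=float)
    gh, gw = grid
    if patch.ndim != 2 or patch.shape[0] < gh or patch.shape[1] < gw:
        raise ValueError(f"patch {patch.shape} smaller than cell grid {grid}")
    ch, cw = patch.shape[0] // gh, patch.shape[1] // gw
    patch = patch[: gh * ch, : gw * cw]
    return _cell_histograms(patch, ch, cw, n_orientations, noise_floor).reshape(-1)


def hog_cell_map(
    frame: np.ndarray,
    cell: int = CELL,
    n_orientations: int = DEFAULT_ORIENTATIONS,
    noise_floor: float = HOG_NOISE_FLOOR,
) -> np.ndarray:
    """Per-cell normalised HOG over a whole frame, shape (cy, cx, n_orient).

    Because normalisation is per cell, any cell-aligned window descriptor
    is (up to border-gradient handling) a contiguous slice of this map —
    dense detection reuses one map per frame instead of re-computing HOG
    per window.
    """
    return _cell_histograms(frame, cell, cell, n_orientations, noise_floor)


# ---------------------------------------------------------------------------
# candidate sampling


def extract_candidates(
    decomp: DecompositionResult,
    frames: np.ndarray,
    n_samples: int = 1000,
    patch_size: int = DEFAULT_PATCH,
    seed: int = 0,
    grid: tuple[int, int] = DEFAULT_GRID,
    n_orientations: int = DEFAULT_ORIENTATIONS,
) -> CandidateSet:
    """Sample candidate regions centred on foreground pixels.

    Candidate centres are drawn from the foreground support of each frame,
    biased toward the centre of the dominant foreground blob (jittered,
    then snapped back to the nearest foreground pixel) so the exemplars
    represent whole, centred paw postures rather than arbitrary offcuts.
    Returns min(n_samples, available positions) members.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    frames = np.asarray(frames, dtype=float)
    n, h, w = frames.shape
    if patch_size > min(h, w):
        raise ValueError("patch_size does not fit in frame")
    cell = patch_size // grid[0]
    # positive support only (the paw is brighter than the cage), and
    # isolated noise pixels removed: candidates must sit on a coherent blob
    mask = foreground_mask(decomp, signed=True, min_blob=25)
    half = patch_size // 2
    rng = np.random.default_rng(seed)

    positions = []  # (frame, x, y) jittered blob-centre samples
    per_frame = max(1, int(np.ceil(2 * n_samples / max(1, n))))
    for f in range(n):
        ys, xs = np.nonzero(mask[f])
        if xs.size == 0:
            continue
        cx, cy = xs.mean(), ys.mean()
        for _ in range(per_frame):
            jx = cx + rng.normal(0.0, 1.0)
            jy = cy + rng.normal(0.0, 1.0)
            k = int(np.argmin((xs - jx) ** 2 + (ys - jy) ** 2))
            x, y = int(xs[k]), int(ys[k])
            if half <= x < w - half + 1 and half <= y < h - half + 1:
                positions.append((f, x, y))
    if not positions:
        raise ValueError("no foreground detected")

    order = rng.permutation(len(positions))
    chosen: set[tuple[int, tuple[int, int, int, int]]] = set()
    for idx in order:
        f, x, y = positions[idx]
        x0 = min(max(x - half, 0), w - patch_size)
        y0 = min(max(y - half, 0), h - patch_size)
        chosen.add((f, (x0, y0, x0 + patch_size, y0 + patch_size)))
        if len(chosen) == n_samples:
            break

    members = []
    for (f, box) in sorted(chosen):
        x0, y0, x1, y1 = box
        desc = compute_hog(
            frames[f][y0:y1, x0:x1], grid=grid, n_orientations=n_orientations
        )
        members.append(CandidateRegion(frame=f, box=box, descriptor=desc))
    return CandidateSet(members=members, seed=seed, patch_size=patch_size)


def sample_background_regions(
    decomp: DecompositionResult,
    frames: np.ndarray,
    n_samples: int = 200,
    patch_size: int = DEFAULT_PATCH,
    seed: int = 0,
    grid: tuple[int, int] = DEFAULT_GRID,
    n_orientations: int = DEFAULT_ORIENTATIONS,
) -> np.ndarray:
    """Descriptors of patches that contain no foreground at all.

    Used as additional negatives when training exemplar classifiers: the
    candidate set contains only paw postures, so without these the
    classifiers would never see what the empty cage looks like.
    """
    frames = np.asarray(frames, dtype=float)
    n, h, w = frames.shape
    mask = foreground_mask(decomp, min_blob=9)
    rng = np.random.default_rng(seed)
    out = []
    attempts = 0
    while len(out) < n_samples and attempts < 50 * n_samples:
        attempts += 1
        f = int(rng.integers(n))
        x0 = int(rng.integers(0, w - patch_size + 1))
        y0 = int(rng.integers(0, h - patch_size + 1))
        if mask[f, y0 : y0 + patch_size, x0 : x0 + patch_size].any():
            continue
        out.append(
            compute_hog(
                frames[f][y0 : y0 + patch_size, x0 : x0 + patch_size],
                grid=grid,
                n_orientations=n_orientations,
            )
        )
    if not out:
        raise ValueError("could not find any background-only patches")
    return np.stack(out)


def knn_mean_distances(x: np.ndarray, k: int) -> np.ndarray:
    """Mean Euclidean distance of each row to its k nearest neighbours."""
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    dist, _ = nn.kneighbors(x)
    return dist[:, 1:].mean(axis=1)


def remove_outliers_knn(
    candidates: CandidateSet, k: int = 10, removal_fraction: float = 0.02
) -> CandidateSet:
    """Drop the floor(f*n) members with the largest mean kNN distance.

    Ties are broken by removing the lexicographically largest (frame, box)
    key first, so the surviving set is deterministic.  Order of survivors
    is preserved.
    """
    n = len(candidates)
    if not 0.0 <= removal_fraction < 1.0:
        raise ValueError("removal_fraction must be in [0, 1)")
    if k >= n:
        raise ValueError(f"k={k} must be < |X|={n}")
    n_remove = int(np.floor(removal_fraction * n))
    if n_remove == 0:
        return CandidateSet(list(candidates.members), candidates.seed,
                            candidates.patch_size)
    d = knn_mean_distances(candidates.descriptor_matrix(), k)
    keys = candidates.keys()
    order = sorted(range(n), key=lambda i: (-d[i], tuple(np.negative(_flat(keys[i])))))
    doomed = set(order[:n_remove])
    kept = [m for i, m in enumerate(candidates.members) if i not in doomed]
    return CandidateSet(kept, candidates.seed, candidates.patch_size)


def _flat(key: tuple[int, tuple[int, int, int, int]]) -> tuple[int, ...]:
    f, box = key
    return (f, *box)
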