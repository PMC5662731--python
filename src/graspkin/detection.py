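"""Dense paw detection, tracking, grasp segmentation and reach features.

All codebook classifiers are applied densely over each frame; the mean of
the top-k calibrated responses scores every sliding window, and the
argmax (with stride-1 local refinement) gives the paw detection.
Detections are linked greedily into tracks, tracks are cut into grasp
bouts at slit crossings, and each bout yields its furthest-extension
apex along the reach axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codebook import Codebook
from .foreground import compute_hog, hog_at_offsets, hog_cell_map


@dataclass(frozen=True)
class PawDetection:
    frame: int
    x: float
    y: float
    score: float


@dataclass
class PawTrack:
    detections: list[PawDetection]
    gaps: list[tuple[int, int]] = field(default_factory=list)

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections])

    @property
    def xs(self) -> np.ndarray:
        return np.array([d.x for d in self.detections])

    @property
    def ys(self) -> np.ndarray:
        return np.array([d.y for d in self.detections])

    def __len__(self) -> int:
        return len(self.detections)


@dataclass(frozen=True)
class ExtensionRecord:
    """Furthest extension of the paw within one grasp."""

    x: float
    y: float
    frame: int
    offset_from_pellet: tuple[float, float] | None = None


@dataclass
class GraspInterval:
    start: int  # half-open [start, end) in session frames
    end: int
    apex: ExtensionRecord | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("grasp interval must satisfy end > start")


def score_windows(
    frame: np.ndarray,
    codebook: Codebook,
    top_k: int = 5,
    stride: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-k mean calibrated score of every cell-aligned sliding window.

    Returns (scores, centers_x, centers_y) over the window grid.  The
    stride equals the HOG cell size so every window descriptor is a slice
    of one per-frame cell map.
    """
    if not len(codebook):
        raise ValueError("empty codebook")
    if top_k > len(codebook):
        raise ValueError("top_k exceeds codebook size")
    ps = codebook.patch_size
    gh, gw = codebook.grid
    cell = ps // gh
    h, w = frame.shape
    if h < ps or w < ps:
        raise ValueError(f"frame {frame.shape} smaller than window {ps}")
    cmap = hog_cell_map(frame, cell=cell, n_orientations=codebook.n_orientations)
    cy, cx = cmap.shape[:2]
    ny, nx = cy - gh + 1, cx - gw + 1
    # all windows as a (ny*nx, gh*gw*orient) view via stride tricks
    s0, s1, s2 = cmap.strides
    windows = np.lib.stride_tricks.as_strided(
        cmap, shape=(ny, nx, gh, gw, cmap.shape[2]), strides=(s0, s1, s0, s1, s2)
    ).reshape(ny * nx, -1)
    raw = windows @ codebook.weight_matrix.T  # (n_windows, |D|)
    z = raw * codebook._slopes[None, :] + codebook._intercepts[None, :]
    probs = 1.0 / (1.0 + np.exp(-z))
    if top_k == len(codebook):
        scores = probs.mean(axis=1)
    else:
        part = np.partition(probs, len(codebook) - top_k, axis=1)
        scores = part[:, len(codebook) - top_k :].mean(axis=1)
    scores = scores.reshape(ny, nx)
    centers_x = np.arange(nx) * cell + (ps - 1) / 2.0
    centers_y = np.arange(ny) * cell + (ps - 1) / 2.0
    return scores, centers_x, centers_y


def _topk_mean_prob(codebook: Codebook, desc: np.ndarray, top_k: int) -> float:
    p = codebook.probabilities(desc)
    return float(np.sort(p)[-top_k:].mean())


def detect_paw(
    frame: np.ndarray,
    codebook: Codebook,
    top_k: int = 5,
    threshold: float = 0.5,
    frame_index: int = 0,
    refine: int = 3,
) -> PawDetection | None:
    """Best-scoring window location, or None below ``threshold``.

    The coarse argmax over the cell-aligned window grid is refined at
    stride 1 within +-``refine`` pixels: the refined location is the
    score-weighted centroid of the near-maximal neighbourhood, which
    cancels the small positional offsets of individual exemplars.
    """
    frame = np.asarray(frame, dtype=float)
    scores, cxs, cys = score_windows(frame, codebook, top_k=top_k)
    iy, ix = np.unravel_index(np.argmax(scores), scores.shape)
    best = float(scores[iy, ix])
    ps = codebook.patch_size
    h, w = frame.shape
    bx, by = cxs[ix], cys[iy]
    if refine > 0:
        x0c, y0c = int(bx - (ps - 1) / 2), int(by - (ps - 1) / 2)
        cx0 = max(0, x0c - refine)
        cy0 = max(0, y0c - refine)
        cx1 = min(w, x0c + ps + refine)
        cy1 = min(h, y0c + ps + refine)
        crop = frame[cy0:cy1, cx0:cx1]
        offsets = [
            (x0 - cx0, y0 - cy0)
            for dy in range(-refine, refine + 1)
            for dx in range(-refine, refine + 1)
            if 0 <= (x0 := x0c + dx) <= w - ps and 0 <= (y0 := y0c + dy) <= h - ps
        ]
        descs = hog_at_offsets(
            crop, offsets, ps, grid=codebook.grid,
            n_orientations=codebook.n_orientations,
        )
        probs = codebook.probabilities(descs)  # (n_offsets, |D|)
        k_lo = len(codebook) - top_k
        vals = np.partition(probs, k_lo, axis=1)[:, k_lo:].mean(axis=1)
        pts = np.asarray(
            [(cx0 + ox + (ps - 1) / 2.0, cy0 + oy + (ps - 1) / 2.0)
             for ox, oy in offsets]
        )
        # the refined (patch-descriptor) score is what training saw;
        # acceptance is decided on it, not on the coarse map score
        best = float(vals.max())
        near = vals >= vals.max() - 0.1 * np.ptp(vals) - 1e-12
        wsum = vals[near] - vals[near].min() + 1e-9
        bx, by = (pts[near] * wsum[:, None]).sum(axis=0) / wsum.sum()
    if best < threshold:
        return None
    return PawDetection(frame=frame_index, x=float(bx), y=float(by), score=best)


def track(
    detections: list[PawDetection],
    max_jump: float = 20.0,
    max_gap: int = 3,
) -> list[PawTrack]:
    """Greedy nearest-neighbour linking of time-ordered detections.

    A displacement larger than ``max_jump`` (per elapsed frame) or a run
    of more than ``max_gap`` missing frames starts a new track.
    """
    tracks: list[PawTrack] = []
    open_tracks: list[PawTrack] = []
    by_frame: dict[int, list[PawDetection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)
    for f in sorted(by_frame):
        dets = by_frame[f]
        unused = list(dets)
        still_open = []
        for tr in open_tracks:
            last = tr.detections[-1]
            dt = f - last.frame
            if dt - 1 > max_gap:
                tracks.append(tr)
                continue
            if not unused:
                still_open.append(tr)
                continue
            dists = [np.hypot(d.x - last.x, d.y - last.y) for d in unused]
            j = int(np.argmin(dists))
            if dists[j] <= max_jump * dt:
                if dt > 1:
                    tr.gaps.append((last.frame + 1, f))
                tr.detections.append(unused.pop(j))
                still_open.append(tr)
            else:
                tracks.append(tr)
        open_tracks = still_open
        for d in unused:
            open_tracks.append(PawTrack(detections=[d]))
    tracks.extend(open_tracks)
    tracks.sort(key=lambda t: t.detections[0].frame)
    return tracks


def smooth_series(x: np.ndarray, window: int = 3) -> np.ndarray:
    """Centred moving average with edge shrinkage (window must be odd)."""
    x = np.asarray(x, dtype=float)
    if window <= 1 or len(x) < 2:
        return x.copy()
    half = window // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def segment_grasps(
    trk: PawTrack,
    slit_x: float,
    min_len: int = 5,
    smooth_window: int = 3,
) -> list[GraspInterval]:
    """Grasp bouts: outward slit crossing to return crossing of the track.

    Intervals shorter than ``min_len`` frames are dropped; each surviving
    interval carries its furthest-extension apex.
    """
    if len(trk) == 0:
        return []
    frames = trk.frames
    xs = smooth_series(trk.xs, smooth_window)
    beyond = xs >= slit_x
    intervals: list[GraspInterval] = []
    i = 0
    n = len(frames)
    while i < n:
        if beyond[i]:
            j = i
            while j < n and beyond[j]:
                j += 1
            start, end = int(frames[i]), int(frames[j - 1]) + 1
            if end - start >= min_len:
                g = GraspInterval(start=start, end=end)
                g.apex = furthest_extension(g, trk, smooth_window=smooth_window)
                intervals.append(g)
            i = j
        else:
            i += 1
    return intervals


def activity_rate(grasps: list[GraspInterval], duration_s: float) -> float:
    """Grasping activity in grasps per minute."""
    if duration_s <= 0:
        raise ValueError("session duration must be positive")
    return len(grasps) / (duration_s / 60.0)


def furthest_extension(
    grasp: GraspInterval,
    trk: PawTrack,
    smooth_window: int = 3,
    pellet_position: tuple[float, float] | None = None,
) -> ExtensionRecord:
    """Apex of the smoothed x-coordinate within the grasp (earliest on ties)."""
    frames = trk.frames
    sel = (frames >= grasp.start) & (frames < grasp.end)
    if not sel.any():
        raise ValueError("grasp interval contains no track points")
    xs = smooth_series(trk.xs, smooth_window)[sel]
    ys = smooth_series(trk.ys, smooth_window)[sel]
    fsel = frames[sel]
    i = int(np.argmax(xs))  # argmax returns the first maximum
    offset = None
    if pellet_position is not None:
        offset = (float(xs[i] - pellet_position[0]), float(ys[i] - pellet_position[1]))
    return ExtensionRecord(
        x=float(xs[i]), y=float(ys[i]), frame=int(fsel[i]), offset_from_pellet=offset
    )
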