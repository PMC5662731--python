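"""End-to-end pipeline: simulate -> candidates -> codebook -> detect ->
segment -> embed -> match -> report, with cached, idempotent stages.

Each stage writes its outputs under the working directory together with a
hash of its inputs and configuration section; re-running with unchanged
inputs skips the stage.  All randomness flows from the single config
seed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import synthetic
from .codebook import Codebook, train_posture_codebook
from .cohort import CohortSession, cohort_report
from .config import PipelineConfig
from .detection import ExtensionRecord, detect_paw, segment_grasps, track
from .embedding import GraspSequence, embed_posture
from .foreground import (
    CandidateRegion,
    CandidateSet,
    compute_hog,
    decompose_low_rank_sparse,
    extract_candidates,
    remove_outliers_knn,
    sample_background_regions,
)
from .matching import MatchingParams

log = logging.getLogger("graspkin.pipeline")


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str, log_path: Path | None = None):
        self.stage = stage
        self.log_path = log_path
        super().__init__(
            f"pipeline stage {stage!r} failed: {detail}"
            + (f" (log: {log_path})" if log_path else "")
        )


def _scene_config(cfg: PipelineConfig, seed: int = 0) -> synthetic.SceneConfig:
    s = cfg.scene
    return synthetic.SceneConfig(
        frame_size=(s.frame_height, s.frame_width),
        n_frames=s.n_frames,
        frame_rate=s.frame_rate,
        pellet_position=(s.pellet_x, s.pellet_y),
        slit_x=s.slit_x,
        paw_scale=s.paw_scale,
        noise_sd=s.noise_sd,
        seed=seed,
    )


class _Cache:
    def __init__(self, workdir: Path):
        self.path = workdir / "stage_hashes.json"
        self.state = (
            json.loads(self.path.read_text()) if self.path.exists() else {}
        )

    def fresh(self, stage: str, key: str, outputs: list[Path]) -> bool:
        return self.state.get(stage) == key and all(p.exists() for p in outputs)

    def update(self, stage: str, key: str) -> None:
        self.state[stage] = key
        self.path.write_text(json.dumps(self.state, indent=1))


def run_pipeline(
    config: PipelineConfig, workdir: str | Path, make_plots: bool = True
) -> dict:
    """Run the full synthetic-cohort pipeline; returns a summary dict."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    log_path = workdir / "pipeline.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    cache = _Cache(workdir)
    chash = config.hash()
    summary = {"config_hash": chash, "seed": config.seed, "stages": {}}
    log.info("pipeline start, config %s seed %d (C=%s, |X| target=%d, |D|=%d)",
             chash, config.seed, config.codebook.C,
             config.candidates.n_samples, config.codebook.n_entries)
    try:
        t0 = time.time()
        fixtures = _stage_simulate(config, workdir, cache)
        summary["stages"]["simulate"] = time.time() - t0

        t0 = time.time()
        codebook = _stage_codebook(config, workdir, cache, fixtures)
        summary["stages"]["codebook"] = time.time() - t0

        t0 = time.time()
        sessions = _stage_detect_embed(config, workdir, cache, fixtures, codebook)
        summary["stages"]["detect"] = time.time() - t0

        t0 = time.time()
        tables = _stage_report(config, workdir, cache, sessions, make_plots)
        summary["stages"]["report"] = time.time() - t0
    except Exception as exc:  # noqa: BLE001
        if isinstance(exc, StageError):
            raise
        raise StageError("pipeline", str(exc), log_path) from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    summary["tables"] = {k: len(v) for k, v in tables.items()}
    (workdir / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def _stage_simulate(
    cfg: PipelineConfig, workdir: Path, cache: _Cache
) -> list[synthetic.SessionFixture]:
    base = _scene_config(cfg)
    fixtures = synthetic.generate_cohort(
        base,
        synthetic.default_cohort_effects(),
        n_animals=cfg.cohort.n_animals,
        n_grasps=cfg.cohort.n_grasps,
        time_points=tuple(cfg.cohort.time_points),
        seed=cfg.seed,
    )
    key = cfg.hash() + ":simulate"
    sess_dir = workdir / "sessions"
    outputs = [sess_dir / f"session_{f.session_id}" / "manifest.yaml" for f in fixtures]
    if cache.fresh("simulate", key, outputs):
        log.info("simulate: cached (%d sessions)", len(fixtures))
        return fixtures
    for f in fixtures:
        frames, truth = f.render()
        synthetic.write_fixture(
            sess_dir / f"session_{f.session_id}", frames, truth, f.manifest()
        )
    cache.update("simulate", key)
    log.info("simulate: wrote %d sessions", len(fixtures))
    return fixtures


def _candidate_sessions(
    cfg: PipelineConfig, fixtures: list[synthetic.SessionFixture]
) -> list[synthetic.SessionFixture]:
    base = [f for f in fixtures if f.time_point == "baseline"]
    acute = [f for f in fixtures if f.time_point == "2d"]
    picked = (base + acute)[: max(1, cfg.candidates.n_train_sessions)]
    return picked


def _stage_codebook(
    cfg: PipelineConfig,
    workdir: Path,
    cache: _Cache,
    fixtures: list[synthetic.SessionFixture],
) -> Codebook:
    key = cfg.hash() + ":codebook"
    cb_path = workdir / "codebook"
    outputs = [cb_path.with_suffix(".npz"), cb_path.with_suffix(".json")]
    if cache.fresh("codebook", key, outputs):
        log.info("codebook: cached")
        return Codebook.load(cb_path)
    train = _candidate_sessions(cfg, fixtures)
    members: list[CandidateRegion] = []
    bg_descs = []
    per_sess = int(np.ceil(cfg.candidates.n_samples / len(train)))
    for f in train:
        frames, _ = f.render()
        decomp = decompose_low_rank_sparse(
            frames, tol=cfg.candidates.rpca_tol,
            max_iter=cfg.candidates.rpca_max_iter,
        )
        cs = extract_candidates(
            decomp, frames, n_samples=per_sess,
            patch_size=cfg.candidates.patch_size, seed=cfg.seed,
        )
        members.extend(cs.members)
        bg_descs.append(
            sample_background_regions(
                decomp, frames, n_samples=per_sess // 2,
                patch_size=cfg.candidates.patch_size, seed=cfg.seed + 1,
            )
        )
    candidates = CandidateSet(
        members[: cfg.candidates.n_samples], cfg.seed, cfg.candidates.patch_size
    )
    candidates = remove_outliers_knn(
        candidates, k=cfg.candidates.knn_k,
        removal_fraction=cfg.candidates.removal_fraction,
    )
    if len(candidates) <= cfg.codebook.n_entries:
        raise StageError("codebook", "fewer candidates than codebook entries")
    neg_size = int(cfg.codebook.negative_fraction * len(candidates))
    codebook = train_posture_codebook(
        candidates,
        K=cfg.codebook.K,
        negative_set_size=neg_size,
        C=cfg.codebook.C,
        n_entries=cfg.codebook.n_entries,
        seed=cfg.seed,
        svm_tol=cfg.codebook.svm_tol,
        background_negatives=np.vstack(bg_descs),
    )
    codebook.save(cb_path)
    cache.update("codebook", key)
    log.info("codebook: %d candidates -> %d entries", len(candidates), len(codebook))
    return codebook


def detect_and_embed_session(
    frames: np.ndarray,
    codebook: Codebook,
    slit_x: float,
    det,
) -> tuple[list[GraspSequence], list[ExtensionRecord]]:
    """Detect, track, segment and embed every grasp of one session.

    ``det`` is the detection section of a PipelineConfig.  Returns the
    grasp sequences (codebook-probability embeddings per frame, apex
    index attached) and the per-grasp furthest-extension records.
    """
    detections = []
    for fi, frame in enumerate(frames):
        d = detect_paw(
            frame, codebook, top_k=det.top_k, threshold=det.threshold,
            frame_index=fi, refine=det.refine,
        )
        if d is not None:
            detections.append(d)
    tracks = track(detections, max_jump=det.max_jump, max_gap=det.max_gap)
    grasps: list[GraspSequence] = []
    ext: list[ExtensionRecord] = []
    ps = codebook.patch_size
    h, w = frames.shape[1:]
    for tr in tracks:
        for g in segment_grasps(
            tr, slit_x, min_len=det.min_len, smooth_window=det.smooth_window
        ):
            rows = []
            sel = (tr.frames >= g.start) & (tr.frames < g.end)
            for fr, x, y in zip(tr.frames[sel], tr.xs[sel], tr.ys[sel]):
                x0 = min(max(int(round(x - (ps - 1) / 2)), 0), w - ps)
                y0 = min(max(int(round(y - (ps - 1) / 2)), 0), h - ps)
                desc = compute_hog(
                    frames[fr][y0 : y0 + ps, x0 : x0 + ps],
                    grid=codebook.grid,
                    n_orientations=codebook.n_orientations,
                )
                rows.append(embed_posture(desc, codebook))
            if not rows:
                continue
            a_idx = int(np.argmax(tr.frames[sel] == g.apex.frame))
            grasps.append(GraspSequence(np.stack(rows), apex_index=a_idx))
            ext.append(g.apex)
    return grasps, ext


def _stage_detect_embed(
    cfg: PipelineConfig,
    workdir: Path,
    cache: _Cache,
    fixtures: list[synthetic.SessionFixture],
    codebook: Codebook,
) -> list[CohortSession]:
    key = cfg.hash() + ":detect"
    det = cfg.detection
    out_paths = [
        workdir / "sessions" / f"session_{f.session_id}" / "grasps.npz"
        for f in fixtures
    ]
    cached = cache.fresh("detect", key, out_paths)
    sessions = []
    for f, gpath in zip(fixtures, out_paths):
        if cached:
            data = np.load(gpath, allow_pickle=False)
            n_grasps = int(data["n_grasps"])
            grasps = [
                GraspSequence(data[f"grasp_{k}"], apex_index=int(data["apex_idx"][k]))
                for k in range(n_grasps)
            ]
            ext = [
                ExtensionRecord(x=float(r[0]), y=float(r[1]), frame=int(r[2]))
                for r in data["extensions"]
            ]
        else:
            frames, _ = f.render()
            grasps, ext = detect_and_embed_session(
                frames, codebook, f.config.slit_x, det
            )
            arrays = {
                f"grasp_{k}": g.embeddings for k, g in enumerate(grasps)
            }
            np.savez_compressed(
                gpath,
                n_grasps=len(grasps),
                apex_idx=np.array([g.apex_index for g in grasps], dtype=int),
                extensions=np.array(
                    [[r.x, r.y, r.frame] for r in ext], dtype=float
                ).reshape(-1, 3),
                **arrays,
            )
        sessions.append(
            CohortSession(
                cohort=f.cohort,
                time_point=f.time_point,
                animal=f.animal,
                grasps=grasps,
                extensions=ext,
                duration_s=f.config.n_frames / f.config.frame_rate,
            )
        )
    if not cached:
        cache.update("detect", key)
        log.info("detect: %d sessions embedded", len(sessions))
    else:
        log.info("detect: cached")
    return sessions


def _stage_report(
    cfg: PipelineConfig,
    workdir: Path,
    cache: _Cache,
    sessions: list[CohortSession],
    make_plots: bool,
) -> dict:
    params = MatchingParams(
        lam=cfg.matching.lam, band=cfg.matching.band, tau=cfg.matching.tau,
        method=cfg.matching.method,
    )
    usable = [s for s in sessions if s.grasps]
    tables = cohort_report(
        usable,
        workdir / "report",
        params=params,
        alpha=cfg.analysis.alpha,
        n_intervals=cfg.analysis.n_intervals,
        Q=cfg.matching.Q,
        seed=cfg.seed,
        config_hash=cfg.hash(),
        make_plots=make_plots,
    )
    cache.update("report", cfg.hash() + ":report")
    return tables
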