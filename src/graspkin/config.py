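"""Pipeline configuration: one strict, YAML-round-trippable object.

Houses every stage default in one place — the cross-validated soft margin
C = 0.01, the candidate-set target size 1000, the codebook size 100, the
five phase intervals, and the rest of the detection / matching / analysis
knobs.  Unknown keys are rejected so a typo cannot silently fall back to
a default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SceneSection(_Strict):
    frame_height: int = 96
    frame_width: int = 128
    n_frames: int = 240
    frame_rate: float = 50.0
    pellet_x: float = 108.0
    pellet_y: float = 44.0
    slit_x: float = 76.0
    paw_scale: float = 20.0
    noise_sd: float = 0.02


class CohortSection(_Strict):
    n_animals: int = 2
    n_grasps: int = 6
    time_points: list[str] = ["baseline", "2d", "7d", "14d", "21d", "35d"]


class CandidateSection(_Strict):
    n_samples: int = 1000  # target |X| before pruning
    patch_size: int = 40
    knn_k: int = 10
    removal_fraction: float = 0.02
    rpca_tol: float = 1.0e-7
    rpca_max_iter: int = 200
    n_train_sessions: int = 2


class CodebookSection(_Strict):
    K: int = 10  # ensemble size per exemplar
    C: float = 0.01  # soft margin (cross-validated)
    negative_fraction: float = 0.5
    n_entries: int = 100  # |D|
    svm_tol: float = 1.0e-4


class DetectionSection(_Strict):
    top_k: int = 5
    threshold: float = 0.5
    stride: int = 4
    refine: int = 3
    max_jump: float = 20.0
    max_gap: int = 3
    min_len: int = 5
    smooth_window: int = 3


class MatchingSection(_Strict):
    lam: float | None = None  # default: median per-frame cost
    band: int = 10
    tau: float | None = None  # default: median per-frame cost
    Q: int = 5
    method: str = "dp"


class AnalysisSection(_Strict):
    alpha: float = 0.05
    n_intervals: int = 5
    perplexity: float = 30.0
    extension_bin_px: float = 2.0


class PipelineConfig(_Strict):
    seed: int = 0
    scene: SceneSection = SceneSection()
    cohort: CohortSection = CohortSection()
    candidates: CandidateSection = CandidateSection()
    codebook: CodebookSection = CodebookSection()
    detection: DetectionSection = DetectionSection()
    matching: MatchingSection = MatchingSection()
    analysis: AnalysisSection = AnalysisSection()

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.model_dump(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        text = (
            Path(source).read_text()
            if isinstance(source, Path) or "\n" not in str(source)
            else str(source)
        )
        return cls.model_validate(yaml.safe_load(text) or {})

    def hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def small_profile(seed: int = 0) -> PipelineConfig:
    """Desk-scale profile used by the worked example and integration runs.

    Same algorithms and study structure as the defaults, with the sample
    sizes (candidate set, ensemble, codebook, session length) reduced so a
    full five-cohort pipeline completes in minutes on one CPU.
    """
    cfg = PipelineConfig(seed=seed)
    cfg.scene.n_frames = 200
    cfg.cohort.n_animals = 2
    cfg.cohort.n_grasps = 6
    cfg.candidates.n_samples = 250
    cfg.candidates.n_train_sessions = 1
    cfg.codebook.K = 4
    cfg.codebook.negative_fraction = 0.4
    cfg.codebook.n_entries = 40
    cfg.matching.band = 6
    return cfg
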