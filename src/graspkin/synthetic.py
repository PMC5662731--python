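"""Synthetic grasping scenes with exhaustive ground truth.

Emulates the recording setup of a single-pellet grasping box filmed from
the side: a static, dimly lit background with reflections, and a fast
articulated paw that reaches through a slit toward a sugar pellet.  The paw
is modelled as a palm ellipse plus three digit lobes whose shape follows a
small set of discrete posture templates (open / pronated / closed /
supinated) blended linearly over the course of each grasp.  Cohort-level
phenotypes — shortened reaches, missing supination, compensatory movements
and graded recovery over post-stroke time points — are injected through a
:class:`CohortEffect`.

Every generated session comes with frame-level ground truth (paw centre,
posture state, grasp intervals, reach apex) so each downstream stage of the
pipeline can be scored without manual annotation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

# Canonical post-lesion recording schedule.
TIME_POINTS = ("baseline", "2d", "7d", "14d", "21d", "35d")

# Posture template ids.
OPEN, PRONATED, CLOSED, SUPINATED, COMPENSATORY = 0, 1, 2, 3, 4
STATE_NAMES = ("open", "pronated", "closed", "supinated", "compensatory")

# Shape parameters per template, in units of paw_scale:
# (palm_a, palm_b, palm_tilt_deg, digit_spread_deg, digit_dist, digit_r, fan_offset_deg)
_TEMPLATES = {
    OPEN: (0.45, 0.30, 0.0, 40.0, 0.62, 0.14, 0.0),
    PRONATED: (0.45, 0.24, -18.0, 24.0, 0.60, 0.13, -25.0),
    CLOSED: (0.40, 0.30, 0.0, 10.0, 0.38, 0.13, 0.0),
    SUPINATED: (0.45, 0.24, 28.0, 26.0, 0.58, 0.13, 30.0),
    COMPENSATORY: (0.48, 0.22, 55.0, 55.0, 0.66, 0.12, 60.0),
}

_PAW_INTENSITY = 0.88


class ConfigurationError(ValueError):
    """Raised when a scene configuration cannot be rendered."""


class FixtureError(ValueError):
    """Raised when a written session fixture is missing or corrupt."""


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and noise of one recording session.

    Coordinates are 0-based pixels with origin at the top-left; the reach
    axis is the image x-axis with the pellet to the right of the slit.
    """

    frame_size: tuple[int, int] = (96, 128)  # (H, W)
    n_frames: int = 240
    frame_rate: float = 50.0
    pellet_position: tuple[float, float] = (108.0, 44.0)  # (x, y)
    slit_x: float = 76.0
    paw_scale: float = 20.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.frame_size
        px, py = self.pellet_position
        if not (0 <= px < w and 0 <= py < h):
            raise ConfigurationError("pellet_position outside frame")
        if not (0 <= self.slit_x < w):
            raise ConfigurationError("slit_x outside [0, W)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_frames < 1 or self.frame_rate <= 0:
            raise ConfigurationError("need n_frames >= 1 and frame_rate > 0")
        # The paw (palm + extended digits) spans roughly 1.6 * paw_scale.
        if 1.6 * self.paw_scale > min(h, w):
            raise ConfigurationError(
                f"frame {self.frame_size} too small for paw_scale={self.paw_scale}"
            )


@dataclass(frozen=True)
class CohortEffect:
    """Phenotype of a cohort, scaled over time points by a recovery schedule.

    ``extension_deficit`` shortens the reach apex (pixels); a grasp loses
    its final supination with probability ``posture_substitution_rate``.
    The ``recovery_schedule`` maps time-point labels to an effect scale in
    [0, 1]; baseline is always scale 0.
    """

    kind: str = "baseline"
    extension_deficit: float = 0.0
    posture_substitution_rate: float = 0.0
    recovery_schedule: dict[str, float] = field(default_factory=dict)

    _KINDS = (
        "baseline",
        "impaired_short",
        "impaired_no_supination",
        "recovered",
        "compensating",
    )

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if not 0.0 <= self.posture_substitution_rate <= 1.0:
            raise ValueError("posture_substitution_rate must be in [0,1]")
        if any(not 0.0 <= s <= 1.0 for s in self.recovery_schedule.values()):
            raise ValueError("recovery schedule scales must be in [0,1]")
        if self.kind == "baseline" and (
            self.extension_deficit != 0 or self.posture_substitution_rate != 0
        ):
            raise ValueError("baseline effect must have zero deficit and substitution")

    def scale_at(self, time_point: str) -> float:
        if time_point == "baseline":
            return 0.0
        if time_point not in self.recovery_schedule:
            raise KeyError(f"recovery schedule missing time point {time_point!r}")
        return self.recovery_schedule[time_point]

    def substitute_state(self) -> int:
        return COMPENSATORY if self.kind == "compensating" else PRONATED


@dataclass
class GroundTruth:
    """Frame-level ground truth of one synthetic session."""

    paw_center: np.ndarray  # (n_frames, 2) float, (x, y)
    posture_state: np.ndarray  # (n_frames,) int template id
    intervals: list[tuple[int, int]]  # half-open [start, end) grasp intervals
    apex: list[tuple[float, float]]  # per-grasp apex (x, y)
    apex_frame: list[int]

    def validate(self, n_frames: int) -> None:
        prev_end = 0
        for (s, e), af in zip(self.intervals, self.apex_frame):
            if not (0 <= s < e <= n_frames):
                raise ValueError("interval outside session")
            if s < prev_end:
                raise ValueError("intervals overlap or are unordered")
            if not s <= af < e:
                raise ValueError("apex frame outside its interval")
            prev_end = e

    def to_dict(self) -> dict:
        return {
            "paw_center": np.asarray(self.paw_center).tolist(),
            "posture_state": np.asarray(self.posture_state).tolist(),
            "intervals": [list(t) for t in self.intervals],
            "apex": [list(t) for t in self.apex],
            "apex_frame": list(self.apex_frame),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            paw_center=np.asarray(d["paw_center"], dtype=float),
            posture_state=np.asarray(d["posture_state"], dtype=int),
            intervals=[tuple(t) for t in d["intervals"]],
            apex=[tuple(t) for t in d["apex"]],
            apex_frame=[int(t) for t in d["apex_frame"]],
        )


def _session_rng(seed: int, *split: int) -> np.random.Generator:
    """Counter-based split of one master seed, stable across platforms."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, split)]))


def _blend(a: tuple, b: tuple, t: float) -> tuple:
    return tuple((1 - t) * x + t * y for x, y in zip(a, b))


def render_paw_mask(
    shape: tuple[int, int], center: tuple[float, float], scale: float, params: tuple
) -> np.ndarray:
    """Render the paw (palm ellipse + 3 digit lobes) as a boolean mask."""
    palm_a, palm_b, tilt, spread, dist, digit_r, fan = params
    h, w = shape
    cx, cy = center
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dx, dy = xx - cx, yy - cy
    th = np.deg2rad(tilt)
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    mask = (u / (palm_a * scale)) ** 2 + (v / (palm_b * scale)) ** 2 <= 1.0
    for j in (-1, 0, 1):
        ang = np.deg2rad(fan + j * spread)
        gx = cx + dist * scale * np.cos(ang)
        gy = cy - dist * scale * np.sin(ang)
        mask |= (xx - gx) ** 2 + (yy - gy) ** 2 <= (digit_r * scale) ** 2
    return mask


def make_background(config: SceneConfig) -> np.ndarray:
    """Static cage background: smooth gradient, reflections, fixed texture."""
    h, w = config.frame_size
    rng = _session_rng(config.seed, 0)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    bg = 0.25 + 0.18 * xx / w + 0.05 * yy / h
    # reflections: two bright blobs near the slit / shelf
    for (bx, by, amp, sig) in (
        (config.slit_x + 8, h * 0.82, 0.22, 6.0),
        (config.slit_x - 18, h * 0.15, 0.15, 9.0),
    ):
        bg += amp * np.exp(-((xx - bx) ** 2 + (yy - by) ** 2) / (2 * sig**2))
    # fixed high-frequency texture so the low-rank assumption holds
    bg += 0.05 * gaussian_filter(rng.standard_normal((h, w)), 1.0)
    # slit edge: darker vertical strip
    bg -= 0.12 * np.exp(-((xx - config.slit_x) ** 2) / (2 * 1.2**2))
    # pellet: small bright dot on the shelf
    px, py = config.pellet_position
    bg += 0.3 * np.exp(-((xx - px) ** 2 + (yy - py) ** 2) / (2 * 1.5**2))
    return np.clip(bg, 0.0, 1.0)


def _grasp_script(final_state: int) -> list[tuple[float, int]]:
    """Keyframes (phase, template) of the canonical reach-pronate-close-retract.

    The paw closes around the apex (phase 0.5) and rotates into the final
    state (normally supination, to bring the pellet to the mouth) while
    still beyond the slit, before opening again at rest.
    """
    return [
        (0.0, OPEN),
        (0.3, PRONATED),
        (0.45, CLOSED),
        (0.58, CLOSED),
        (0.72, final_state),
        (0.86, final_state),
        (1.0, OPEN),
    ]


def _params_at(script: list[tuple[float, int]], p: float) -> tuple[tuple, int]:
    """Linearly blended template parameters and nearest-keyframe state at phase p."""
    for (p0, s0), (p1, s1) in zip(script, script[1:]):
        if p0 <= p <= p1:
            t = 0.0 if p1 == p0 else (p - p0) / (p1 - p0)
            params = _blend(_TEMPLATES[s0], _TEMPLATES[s1], t)
            return params, (s0 if t < 0.5 else s1)
    return _TEMPLATES[script[-1][1]], script[-1][1]


def generate_session(
    config: SceneConfig,
    effect: CohortEffect | None = None,
    n_grasps: int = 6,
    effect_scale: float = 1.0,
    return_masks: bool = False,
) -> tuple[np.ndarray, GroundTruth] | tuple[np.ndarray, GroundTruth, np.ndarray]:
    """Render one session: ``(frames, ground_truth)``.

    Frames are float64 in [0, 1], shape ``(n_frames, H, W)``.  The paw sits
    at a rest position left of the slit between grasps; each grasp follows
    a smooth out-and-back trajectory whose apex targets the pellet minus
    the (scaled) extension deficit of the cohort effect.  With
    ``return_masks`` the boolean per-frame paw masks are returned as well.
    """
    effect = effect or CohortEffect()
    if n_grasps < 0:
        raise ValueError("n_grasps must be >= 0")
    h, w = config.frame_size
    rng = _session_rng(config.seed, 1)
    bg = make_background(config)

    deficit = effect.extension_deficit * effect_scale
    sub_rate = effect.posture_substitution_rate * effect_scale
    px, py = config.pellet_position
    rest = (config.slit_x - 2.2 * config.paw_scale, py + 6.0)
    if px - deficit <= config.slit_x + 3:
        raise ConfigurationError("extension deficit leaves apex short of the slit")

    # place grasps on the timeline with idle gaps
    lengths = rng.integers(18, 27, size=n_grasps)
    min_gap = 6
    needed = int(lengths.sum()) + min_gap * (n_grasps + 1) if n_grasps else 0
    if needed > config.n_frames:
        raise ConfigurationError(
            f"{n_grasps} grasps do not fit in {config.n_frames} frames"
        )
    slack = config.n_frames - needed
    cuts = np.sort(rng.integers(0, slack + 1, size=n_grasps)) if n_grasps else []
    starts = []
    t = min_gap
    prev_cut = 0
    for gi in range(n_grasps):
        t += int(cuts[gi]) - prev_cut
        prev_cut = int(cuts[gi])
        starts.append(t)
        t += int(lengths[gi]) + min_gap

    centers = np.tile(np.asarray(rest), (config.n_frames, 1))
    states = np.full(config.n_frames, OPEN, dtype=int)
    intervals: list[tuple[int, int]] = []
    per_frame_params: dict[int, tuple] = {}

    for gi in range(n_grasps):
        L = int(lengths[gi])
        s0 = starts[gi]
        apex_x = px - deficit + rng.normal(0.0, 1.0)
        apex_x = min(apex_x, w - 0.85 * config.paw_scale - 1)
        apex_y = py + rng.normal(0.0, 0.8)
        final_state = SUPINATED
        y_lift = 0.0
        if rng.random() < sub_rate:
            final_state = effect.substitute_state()
            if effect.kind == "compensating":
                y_lift = 0.25 * config.paw_scale * effect_scale
        script = _grasp_script(final_state)
        phases = np.arange(L) / (L - 1)
        bump = np.sin(np.pi * phases)
        xs = rest[0] + (apex_x - rest[0]) * bump
        ys = rest[1] + (apex_y - rest[1]) * bump * 0.8 - y_lift * bump
        for t_loc in range(L):
            f = s0 + t_loc
            centers[f] = (xs[t_loc], ys[t_loc])
            params, st = _params_at(script, phases[t_loc])
            states[f] = st
            per_frame_params[f] = params
        # ground-truth interval: frames beyond the slit
        beyond = np.nonzero(xs >= config.slit_x)[0]
        intervals.append((s0 + int(beyond[0]), s0 + int(beyond[-1]) + 1))

    frames = np.empty((config.n_frames, h, w))
    masks = np.empty((config.n_frames, h, w), dtype=bool)
    gt_centers = np.empty((config.n_frames, 2))
    noise_rng = _session_rng(config.seed, 2)
    for f in range(config.n_frames):
        params = per_frame_params.get(f, _TEMPLATES[OPEN])
        mask = render_paw_mask((h, w), tuple(centers[f]), config.paw_scale, params)
        masks[f] = mask
        ys_m, xs_m = np.nonzero(mask)
        gt_centers[f] = (xs_m.mean(), ys_m.mean()) if xs_m.size else centers[f]
        img = np.where(mask, _PAW_INTENSITY, bg)
        img = gaussian_filter(img, 0.7)
        img += noise_rng.normal(0.0, config.noise_sd, size=(h, w))
        frames[f] = np.clip(img, 0.0, 1.0)

    # apex = furthest extension of the rendered paw (centroid trajectory),
    # which is what a tracker measures
    apexes, apex_frames = [], []
    for (i0, i1) in intervals:
        af = i0 + int(np.argmax(gt_centers[i0:i1, 0]))
        apex_frames.append(af)
        apexes.append((float(gt_centers[af, 0]), float(gt_centers[af, 1])))

    gt = GroundTruth(
        paw_center=gt_centers,
        posture_state=states,
        intervals=intervals,
        apex=apexes,
        apex_frame=apex_frames,
    )
    gt.validate(config.n_frames)
    if return_masks:
        return frames, gt, masks
    return frames, gt


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class SessionFixture:
    """Manifest of one (cohort, animal, time point) session, lazily renderable."""

    session_id: str
    cohort: str
    animal: int
    time_point: str
    config: SceneConfig
    effect: CohortEffect
    effect_scale: float
    n_grasps: int

    def manifest(self) -> dict:
        return {
            "session_id": self.session_id,
            "cohort": self.cohort,
            "animal": self.animal,
            "time_point": self.time_point,
            "frame_rate": self.config.frame_rate,
            "pellet_position": list(self.config.pellet_position),
            "slit_x": self.config.slit_x,
            "effect_kind": self.effect.kind,
            "effect_scale": self.effect_scale,
            "n_grasps": self.n_grasps,
            "seed": self.config.seed,
        }

    def render(self) -> tuple[np.ndarray, GroundTruth]:
        return generate_session(
            self.config, self.effect, self.n_grasps, self.effect_scale
        )


def default_cohort_effects() -> dict[str, CohortEffect]:
    """The five study cohorts with their recovery schedules.

    ``recovered_training`` and ``recovered_stim`` scale their acute deficit
    to zero by 35d; ``spontaneous`` (too-short grasps) and
    ``delayed_training`` (missing supination) do not; ``compensating``
    replaces the grasp end with a distinct compensatory movement.
    """
    full = {"2d": 1.0, "7d": 0.85, "14d": 0.55, "21d": 0.25, "35d": 0.0}
    stuck = {"2d": 1.0, "7d": 1.0, "14d": 0.95, "21d": 0.9, "35d": 0.9}
    return {
        "recovered_training": CohortEffect(
            "recovered", extension_deficit=10.0, posture_substitution_rate=0.8,
            recovery_schedule=full,
        ),
        "recovered_stim": CohortEffect(
            "recovered", extension_deficit=8.0, posture_substitution_rate=0.6,
            recovery_schedule={"2d": 1.0, "7d": 0.9, "14d": 0.6, "21d": 0.3, "35d": 0.05},
        ),
        "spontaneous": CohortEffect(
            "impaired_short", extension_deficit=10.0, posture_substitution_rate=0.3,
            recovery_schedule=stuck,
        ),
        "delayed_training": CohortEffect(
            "impaired_no_supination", extension_deficit=4.0,
            posture_substitution_rate=0.9, recovery_schedule=stuck,
        ),
        "compensating": CohortEffect(
            "compensating", extension_deficit=6.0, posture_substitution_rate=0.9,
            recovery_schedule={"2d": 1.0, "7d": 1.0, "14d": 0.9, "21d": 0.85, "35d": 0.8},
        ),
    }


def generate_cohort(
    base_config: SceneConfig,
    effects: dict[str, CohortEffect],
    n_animals: int = 2,
    n_grasps: int = 6,
    time_points: tuple[str, ...] = TIME_POINTS,
    seed: int = 0,
) -> list[SessionFixture]:
    """One session fixture per (cohort, animal, time point).

    The schedule of every effect must cover the baseline and 2d anchors and
    every requested post-lesion time point.
    """
    if "baseline" not in time_points or "2d" not in time_points:
        raise ValueError("time points must include the 'baseline' and '2d' anchors")
    fixtures = []
    for ci, (name, eff) in enumerate(sorted(effects.items())):
        missing = [
            tp for tp in time_points
            if tp != "baseline" and tp not in eff.recovery_schedule
        ]
        if missing:
            raise ValueError(f"cohort {name!r}: schedule missing time points {missing}")
        for ai in range(n_animals):
            for ti, tp in enumerate(time_points):
                sseed = int(
                    np.random.SeedSequence([seed, ci, ai, ti]).generate_state(1)[0]
                    % (2**31)
                )
                cfg = dataclasses.replace(base_config, seed=sseed)
                fixtures.append(
                    SessionFixture(
                        session_id=f"{name}_a{ai}_{tp}",
                        cohort=name,
                        animal=ai,
                        time_point=tp,
                        config=cfg,
                        effect=eff,
                        effect_scale=eff.scale_at(tp),
                        n_grasps=n_grasps,
                    )
                )
    return fixtures


# ---------------------------------------------------------------------------
# sequence-level generator (no rendering)

_SEQ_BASIS_SEED = 71_235_813


def _state_basis(dim: int) -> np.ndarray:
    """Fixed, well-separated embedding vectors for the posture templates."""
    rng = np.random.default_rng(_SEQ_BASIS_SEED)
    v = rng.standard_normal((len(_TEMPLATES) + 1, dim))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return 3.0 * v  # last row = reach-extension direction


def generate_grasp_sequences(
    n_grasps: int,
    effect: CohortEffect | None = None,
    effect_scale: float = 1.0,
    rng: np.random.Generator | None = None,
    dim: int = 20,
    length_range: tuple[int, int] = (10, 15),
    noise_sd: float = 0.15,
    deficit_ref: float = 20.0,
) -> list["np.ndarray"]:
    """Grasp sequences directly in posture-embedding space.

    Emulates what the video pipeline produces for a grasp — an M x D matrix
    of per-frame posture embeddings following the canonical grasp script —
    without rendering any frames.  Used for cohort-level statistics at
    sample sizes where full video synthesis would be wasteful.  The reach
    apex sits at the middle frame of every sequence.
    """
    effect = effect or CohortEffect()
    rng = rng or np.random.default_rng(0)
    basis = _state_basis(dim)
    reach_dir = basis[-1]
    amp = max(0.0, 1.0 - effect.extension_deficit * effect_scale / deficit_ref)
    sub_rate = effect.posture_substitution_rate * effect_scale
    out = []
    for _ in range(n_grasps):
        m = int(rng.integers(length_range[0], length_range[1] + 1))
        final_state = SUPINATED
        if rng.random() < sub_rate:
            final_state = effect.substitute_state()
        script = _grasp_script(final_state)
        phases = np.arange(m) / (m - 1)
        seq = np.empty((m, dim))
        for t, p in enumerate(phases):
            # blend of state basis vectors with the same keyframe weights
            for (p0, s0), (p1, s1) in zip(script, script[1:]):
                if p0 <= p <= p1:
                    u = 0.0 if p1 == p0 else (p - p0) / (p1 - p0)
                    vec = (1 - u) * basis[s0] + u * basis[s1]
                    break
            seq[t] = vec + amp * np.sin(np.pi * p) * reach_dir
        seq += rng.normal(0.0, noise_sd, size=seq.shape)
        out.append(seq)
    return out


def generate_extension_records(
    n: int,
    pellet_position: tuple[float, float],
    shift_x: float = 0.0,
    sd: float = 3.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Furthest-extension apex samples ``(n, 2)`` around the pellet.

    ``shift_x`` displaces the apex distribution along the reach axis
    (negative = too-short grasps).
    """
    rng = rng or np.random.default_rng(0)
    px, py = pellet_position
    return np.column_stack(
        [rng.normal(px + shift_x, sd, n), rng.normal(py, sd, n)]
    )


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixture(
    path: str | Path,
    frames: np.ndarray,
    truth: GroundTruth,
    manifest: dict,
) -> Path:
    """Write ``session/frames/%06d.png`` + ``truth.json`` + ``manifest.yaml``."""
    path = Path(path)
    fdir = path / "frames"
    fdir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        img = np.clip(np.round(frame * 255.0), 0, 255).astype(np.uint8)
        iio.imwrite(fdir / f"{i:06d}.png", img)
    (path / "truth.json").write_text(json.dumps(truth.to_dict()))
    (path / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path


def read_fixture(path: str | Path) -> tuple[np.ndarray, GroundTruth, dict]:
    """Read a session fixture back; frames return as float in [0, 1]."""
    path = Path(path)
    fdir = path / "frames"
    if not fdir.is_dir():
        raise FixtureError(f"fixture at {path} is missing member 'frames/'")
    files = sorted(fdir.glob("*.png"))
    if not files:
        raise FixtureError(f"fixture at {path} has an empty 'frames/' directory")
    frames = np.stack([iio.imread(f).astype(float) / 255.0 for f in files])
    tpath = path / "truth.json"
    if not tpath.is_file():
        raise FixtureError(f"fixture at {path} is missing member 'truth.json'")
    try:
        truth = GroundTruth.from_dict(json.loads(tpath.read_text()))
    except (KeyError, ValueError) as exc:
        raise FixtureError(f"fixture at {path}: corrupt truth.json ({exc})") from exc
    mpath = path / "manifest.yaml"
    if not mpath.is_file():
        raise FixtureError(f"fixture at {path} is missing member 'manifest.yaml'")
    manifest = yaml.safe_load(mpath.read_text())
    if len(frames) != len(truth.paw_center):
        raise FixtureError(
            f"fixture at {path}: {len(frames)} frames but "
            f"{len(truth.paw_center)} ground-truth entries"
        )
    return frames, truth, manifest
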