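"""Study-level analytics: triangulation, recovery tests, extension maps.

Sessions are located in a 2-D triangulation plane from their mean
sequence-level distances to two anchor sets (pre-lesion baseline grasps
and acute 2-days-post grasps).  Recovery at a time point is declared by a
two-sample Kolmogorov-Smirnov test on per-grasp distances to the baseline
prototype set.  Furthest-extension distributions under perturbation
conditions (light-off vs light-on) are compared via their x-marginals.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, ks_2samp

from .detection import ExtensionRecord
from .embedding import GraspSequence, phase_deviation_bars
from .matching import (
    MatchingParams,
    SequenceCodebook,
    build_sequence_dictionary,
    embed_sequence_level,
    sequence_distance,
)


@dataclass
class CohortSession:
    """A labelled set of grasps from one (animal, cohort, time point)."""

    cohort: str
    time_point: str
    animal: int = 0
    grasps: list[GraspSequence] = field(default_factory=list)
    extensions: list[ExtensionRecord] = field(default_factory=list)
    condition: str | None = None  # e.g. light_off / light_on
    duration_s: float | None = None

    def arrays(self) -> list[np.ndarray]:
        return [g.embeddings for g in self.grasps]


@dataclass
class TriangulationPoint:
    d_base: float
    d_2d: float
    anchor_separation: float
    x: float
    y: float
    clamped: bool


def _mean_cross_f_distance(
    fa: np.ndarray, fb: np.ndarray
) -> float:
    """Mean Euclidean distance between two sets of sequence-level embeddings."""
    diff = fa[:, None, :] - fb[None, :, :]
    return float(np.linalg.norm(diff, axis=2).mean())


def triangulate_point(d_base: float, d_2d: float, c: float) -> TriangulationPoint:
    """Planar location from two anchor distances (anchors at (0,0) and (c,0)).

    When the triangle inequality fails (possible only through estimation
    noise; the distances are means of metrics), y is clamped to 0 and the
    point flagged — output coordinates are always finite.
    """
    if not np.isfinite([d_base, d_2d, c]).all():
        raise ValueError("non-finite triangulation inputs")
    if c <= 0:
        raise ValueError("degenerate anchors: reference sets coincide")
    x = (d_base**2 - d_2d**2 + c**2) / (2 * c)
    y2 = d_base**2 - x**2
    return TriangulationPoint(
        d_base=float(d_base),
        d_2d=float(d_2d),
        anchor_separation=float(c),
        x=float(x),
        y=float(np.sqrt(max(y2, 0.0))),
        clamped=bool(y2 < -1e-12),
    )


def session_triangulation(
    session_grasps: list[np.ndarray],
    baseline_refs: list[np.ndarray],
    day2_refs: list[np.ndarray],
    params: MatchingParams | None = None,
    dictionary: SequenceCodebook | None = None,
    Q: int | None = None,
    seed: int = 0,
) -> TriangulationPoint:
    """Locate a session relative to the baseline and 2d anchors.

    All grasps are embedded against one sequence dictionary built from the
    pooled references; d_base and d_2d are the mean Euclidean distances of
    the session's sequence-level embeddings to each reference set.  The
    anchors sit at (0, 0) and (c, 0) with c the mean cross-distance
    between the reference sets; the session is placed by triangulation,
    with y clamped to 0 (and flagged) when the triangle inequality fails.
    """
    if not baseline_refs or not day2_refs:
        raise ValueError("both reference sets must be non-empty")
    for g in session_grasps:
        for r in baseline_refs + day2_refs:
            if g is r:
                raise ValueError("references must exclude the session's own grasps")
    if dictionary is None:
        pool = list(baseline_refs) + list(day2_refs)
        q = Q or min(8, len(pool))
        dictionary = build_sequence_dictionary(pool, q, params=params, seed=seed)
    f_sess = np.stack([embed_sequence_level(g, dictionary) for g in session_grasps])
    f_base = np.stack([embed_sequence_level(g, dictionary) for g in baseline_refs])
    f_2d = np.stack([embed_sequence_level(g, dictionary) for g in day2_refs])
    d_base = _mean_cross_f_distance(f_sess, f_base)
    d_2d = _mean_cross_f_distance(f_sess, f_2d)
    c = _mean_cross_f_distance(f_base, f_2d)
    return triangulate_point(d_base, d_2d, c)


@dataclass
class RecoveryTest:
    statistic: float
    pvalue: float
    n_test: int
    n_ref: int
    alpha: float
    significant: bool


def _distance_to_prototypes(
    seq: np.ndarray, dictionary: SequenceCodebook, exclude: int | None = None
) -> float:
    """Mean d_sym to the prototype set, optionally leaving one prototype out."""
    vals = [
        sequence_distance(seq, proto, dictionary.params, symmetric=True)
        for qi, proto in enumerate(dictionary.prototypes)
        if qi != exclude
    ]
    if not vals:
        raise ValueError("no prototypes left after exclusion")
    return float(np.mean(vals))


def grasp_distance_samples(
    grasps: list[np.ndarray],
    dictionary: SequenceCodebook,
    leave_own_out: bool = False,
) -> np.ndarray:
    """Per-grasp mean distance to the prototype set.

    With ``leave_own_out`` a grasp that is itself a prototype is scored
    against the remaining prototypes only, so both sides of a recovery
    test measure distances to prototypes not derived from themselves.
    """
    out = []
    for g in grasps:
        exclude = None
        if leave_own_out:
            for qi, proto in enumerate(dictionary.prototypes):
                if proto is g or (
                    proto.shape == g.shape and np.array_equal(proto, g)
                ):
                    exclude = qi
                    break
        out.append(_distance_to_prototypes(g, dictionary, exclude))
    return np.asarray(out)


def recovery_ks_test(
    session_grasps: list[np.ndarray],
    baseline_grasps: list[np.ndarray],
    params: MatchingParams | None = None,
    alpha: float = 0.05,
    Q: int = 5,
    seed: int = 0,
    dictionary: SequenceCodebook | None = None,
) -> RecoveryTest:
    """Two-sample K-S test of session vs baseline grasp-distance distributions.

    Both sides are summarised by per-grasp mean distances to a baseline
    prototype set.  The prototypes are built from every second baseline
    grasp and the reference distances come from the held-out half, so
    neither sample entering the test helped select the prototypes (a
    grasp scoring the prototypes it elected would bias its own distance
    low and inflate the false-positive rate).  Significant difference
    (p < alpha) means the session has not recovered to baseline.
    """
    min_n = 5
    if len(session_grasps) < min_n or len(baseline_grasps) < 2 * min_n:
        raise ValueError(
            f"need at least {min_n} session grasps and {2 * min_n} baseline grasps"
        )
    ref_grasps = baseline_grasps[1::2]
    if dictionary is None:
        dict_grasps = baseline_grasps[::2]
        dictionary = build_sequence_dictionary(
            dict_grasps, min(Q, len(dict_grasps)), params=params, seed=seed
        )
    ref = grasp_distance_samples(ref_grasps, dictionary, leave_own_out=True)
    test = grasp_distance_samples(session_grasps, dictionary, leave_own_out=True)
    res = ks_2samp(test, ref)
    return RecoveryTest(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_test=len(test),
        n_ref=len(ref),
        alpha=alpha,
        significant=bool(res.pvalue < alpha),
    )


# ---------------------------------------------------------------------------
# furthest-extension distributions


@dataclass
class ExtensionDistributions:
    """2-D apex densities per condition, x-marginals and their difference."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    density_off: np.ndarray  # 2-D, integrates to 1
    density_on: np.ndarray
    marginal_x_off: np.ndarray  # 1-D, integrates to 1
    marginal_x_on: np.ndarray
    difference: np.ndarray  # off - on, integrates to 0
    kde_grid: np.ndarray
    kde_difference: np.ndarray
    ks_statistic: float
    ks_pvalue: float


def _records_to_xy(records: list[ExtensionRecord] | np.ndarray) -> np.ndarray:
    if isinstance(records, np.ndarray):
        return np.atleast_2d(records)
    return np.array([[r.x, r.y] for r in records])


def extension_analysis(
    off: list[ExtensionRecord] | np.ndarray,
    on: list[ExtensionRecord] | np.ndarray,
    pellet_position: tuple[float, float],
    bin_width: float = 2.0,
) -> ExtensionDistributions:
    """Compare furthest-extension distributions between two conditions.

    Apex locations are expressed relative to the pellet.  Histogram
    densities (shared 2-px bins) give exactly conserved marginals; a
    Gaussian KDE (Silverman bandwidth) provides the smooth difference
    curve, and a two-sample K-S test runs on the raw x samples.
    """
    xy_off = _records_to_xy(off) - np.asarray(pellet_position)
    xy_on = _records_to_xy(on) - np.asarray(pellet_position)
    if len(xy_off) < 5 or len(xy_on) < 5:
        raise ValueError("need at least 5 extension records per condition")
    allxy = np.vstack([xy_off, xy_on])
    if np.allclose(allxy, allxy[0]):
        raise ValueError("degenerate density: all extension records identical")

    lo = np.floor(allxy.min(axis=0) / bin_width) * bin_width - bin_width
    hi = np.ceil(allxy.max(axis=0) / bin_width) * bin_width + bin_width
    x_edges = np.arange(lo[0], hi[0] + bin_width / 2, bin_width)
    y_edges = np.arange(lo[1], hi[1] + bin_width / 2, bin_width)

    def hist2d(xy: np.ndarray) -> np.ndarray:
        h, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=(x_edges, y_edges))
        area = bin_width * bin_width
        return h / (h.sum() * area)

    d_off, d_on = hist2d(xy_off), hist2d(xy_on)
    marg_off = d_off.sum(axis=1) * bin_width  # integrate over y
    marg_on = d_on.sum(axis=1) * bin_width
    diff = marg_off - marg_on

    grid = np.linspace(lo[0], hi[0], 512)
    if np.ptp(xy_off[:, 0]) > 0 and np.ptp(xy_on[:, 0]) > 0:
        kde_diff = gaussian_kde(xy_off[:, 0])(grid) - gaussian_kde(xy_on[:, 0])(grid)
    else:
        kde_diff = np.zeros_like(grid)
    ks = ks_2samp(xy_off[:, 0], xy_on[:, 0])
    return ExtensionDistributions(
        x_edges=x_edges,
        y_edges=y_edges,
        density_off=d_off,
        density_on=d_on,
        marginal_x_off=marg_off,
        marginal_x_on=marg_on,
        difference=diff,
        kde_grid=grid,
        kde_difference=kde_diff,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
    )


def difference_extrema_separation(dist: ExtensionDistributions) -> float:
    """Distance (px) between the max and min of the smooth difference curve."""
    g = dist.kde_grid
    return float(abs(g[np.argmax(dist.kde_difference)] - g[np.argmin(dist.kde_difference)]))


# ---------------------------------------------------------------------------
# report


def _provenance(config_hash: str, seed: int) -> dict:
    return {"config_hash": config_hash, "seed": seed}


def cohort_report(
    sessions: list[CohortSession],
    out_dir: str | Path,
    params: MatchingParams | None = None,
    alpha: float = 0.05,
    n_intervals: int = 5,
    Q: int = 5,
    seed: int = 0,
    config_hash: str = "",
    make_plots: bool = True,
) -> dict[str, pd.DataFrame]:
    """Assemble the study-level report bundle (CSV tables + plots).

    Requires every cohort to provide its baseline and 2d anchor sessions.
    Produces one machine-readable table per figure panel: triangulation
    coordinates, recovery K-S verdicts, activity rates and phase bars.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not config_hash:
        config_hash = hashlib.sha256(b"graspkin-report").hexdigest()[:12]

    cohorts = sorted({s.cohort for s in sessions})
    by = {}
    for s in sessions:
        by.setdefault((s.cohort, s.time_point), []).append(s)
    missing = []
    for c in cohorts:
        for anchor in ("baseline", "2d"):
            if (c, anchor) not in by:
                missing.append((c, anchor))
    if missing:
        raise ValueError(f"missing anchor sessions: {missing}")

    all_grasps = [g for s in sessions for g in s.arrays()]
    params = (params or MatchingParams()).resolve(all_grasps)

    tri_rows, ks_rows, act_rows, bar_rows = [], [], [], []
    time_points = sorted(
        {s.time_point for s in sessions},
        key=lambda t: (t != "baseline", t),
    )
    for c in cohorts:
        base_grasps = [g for s in by[(c, "baseline")] for g in s.arrays()]
        d2_grasps = [g for s in by[(c, "2d")] for g in s.arrays()]
        pool = base_grasps + d2_grasps
        dictionary = build_sequence_dictionary(
            pool, min(2 * Q, len(pool)), params=params, seed=seed
        )
        base_half = base_grasps[::2]
        base_dict = (
            build_sequence_dictionary(
                base_half, min(Q, len(base_half)), params=params, seed=seed
            )
            if len(base_grasps) >= 10
            else None
        )
        for tp in time_points:
            if (c, tp) not in by:
                continue
            grasps = [g for s in by[(c, tp)] for g in s.arrays()]
            if tp not in ("baseline", "2d") and grasps:
                point = session_triangulation(
                    grasps, base_grasps, d2_grasps,
                    params=params, dictionary=dictionary,
                )
                tri_rows.append(
                    {
                        "cohort": c, "time_point": tp,
                        "d_base": point.d_base, "d_2d": point.d_2d,
                        "anchor_separation": point.anchor_separation,
                        "x": point.x, "y": point.y,
                        "x_norm": point.x / point.anchor_separation,
                        "y_norm": point.y / point.anchor_separation,
                        "clamped": point.clamped,
                    }
                )
                if len(grasps) >= 5 and len(base_grasps) >= 10:
                    kt = recovery_ks_test(
                        grasps, base_grasps, params=params, alpha=alpha,
                        dictionary=base_dict,
                    )
                    ks_rows.append(
                        {
                            "cohort": c, "time_point": tp,
                            "statistic": kt.statistic, "pvalue": kt.pvalue,
                            "n_test": kt.n_test, "n_ref": kt.n_ref,
                            "significant": kt.significant,
                            "pvalue_bonferroni": min(
                                1.0, kt.pvalue * max(1, len(time_points) - 2)
                            ),
                        }
                    )
            for s in by[(c, tp)]:
                if s.duration_s:
                    act_rows.append(
                        {
                            "cohort": c, "time_point": tp, "animal": s.animal,
                            "grasps_per_min": len(s.grasps) / (s.duration_s / 60.0),
                        }
                    )
        final_tp = time_points[-1]
        base_seqs = [g for s in by[(c, "baseline")] for g in s.grasps]
        if (c, final_tp) in by and final_tp != "baseline":
            test_seqs = [g for s in by[(c, final_tp)] for g in s.grasps]
            if base_seqs and test_seqs:
                bars = phase_deviation_bars(base_seqs, test_seqs, n_intervals)
                for k, v in enumerate(bars.deviations):
                    bar_rows.append(
                        {
                            "cohort": c, "time_point": final_tp,
                            "interval": k, "deviation_sd": v,
                            "baseline_sd": bars.baseline_sd[k],
                        }
                    )

    tables = {
        "triangulation": pd.DataFrame(tri_rows),
        "recovery_ks": pd.DataFrame(ks_rows),
        "activity": pd.DataFrame(act_rows),
        "phase_bars": pd.DataFrame(bar_rows),
    }
    for name, df in tables.items():
        for key, val in _provenance(config_hash, seed).items():
            df[key] = val
        df.to_csv(out / f"{name}.csv", index=False)

    if make_plots:
        _render_plots(tables, out)
    return tables


def _render_plots(tables: dict[str, pd.DataFrame], out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tri = tables["triangulation"]
    fig, ax = plt.subplots(figsize=(5, 4))
    if len(tri):
        for c, sub in tri.groupby("cohort"):
            ax.plot(sub["x_norm"], sub["y_norm"], "o-", label=c)
        ax.scatter([0, 1], [0, 0], c="k", marker="^")
        ax.annotate("baseline", (0, 0))
        ax.annotate("2d", (1, 0))
        ax.legend(fontsize=6)
    ax.set_xlabel("toward 2d  (x / c)")
    ax.set_ylabel("compensation  (y / c)")
    fig.savefig(out / "triangulation.png", dpi=120)
    plt.close(fig)

    act = tables["activity"]
    fig, ax = plt.subplots(figsize=(5, 3))
    if len(act):
        for c, sub in act.groupby("cohort"):
            m = sub.groupby("time_point")["grasps_per_min"].mean()
            ax.plot(m.index, m.values, "o-", label=c)
        ax.legend(fontsize=6)
    ax.set_ylabel("grasps / min")
    fig.savefig(out / "activity.png", dpi=120)
    plt.close(fig)

    bars = tables["phase_bars"]
    fig, ax = plt.subplots(figsize=(5, 3))
    if len(bars):
        for c, sub in bars.groupby("cohort"):
            ax.bar(
                sub["interval"] + 0.8 * list(bars["cohort"].unique()).index(c) / max(
                    1, bars["cohort"].nunique()
                ),
                sub["deviation_sd"],
                width=0.8 / max(1, bars["cohort"].nunique()),
                label=c,
            )
        ax.legend(fontsize=6)
    ax.set_xlabel("grasp phase interval")
    ax.set_ylabel("deviation (baseline SD)")
    fig.savefig(out / "phase_bars.png", dpi=120)
    plt.close(fig)
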