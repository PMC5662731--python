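"""Cohort analytics: triangulation, recovery K-S tests, extension maps,
report assembly."""

import numpy as np
import pandas as pd
import pytest

from graspkin import synthetic as syn
from graspkin.cohort import (
    CohortSession,
    cohort_report,
    difference_extrema_separation,
    extension_analysis,
    recovery_ks_test,
    session_triangulation,
    triangulate_point,
)
from graspkin.embedding import GraspSequence
from graspkin.matching import MatchingParams

PARAMS = MatchingParams(band=3)


def _grasps(n, effect=None, scale=1.0, seed=0):
    return syn.generate_grasp_sequences(
        n, effect or syn.CohortEffect(), effect_scale=scale,
        rng=np.random.default_rng(seed),
    )


class TestTriangulation:
    def test_baseline_like_session_lands_on_baseline_side(self):
        base = _grasps(30, seed=1)
        impaired = _grasps(15, syn.CohortEffect(
            "impaired_short", extension_deficit=12.0,
            posture_substitution_rate=0.8, recovery_schedule={"2d": 1.0},
        ), seed=2)
        point = session_triangulation(
            base[15:], base[:15], impaired, params=PARAMS, seed=0
        )
        assert point.x < point.anchor_separation / 2

    def test_own_grasps_in_references_rejected(self):
        base = _grasps(10, seed=3)
        with pytest.raises(ValueError, match="exclude"):
            session_triangulation(base[:5], base, base[5:], params=PARAMS)

    def test_impossible_triangle_clamped_and_flagged(self):
        point = triangulate_point(d_base=1.0, d_2d=1.0, c=5.0)
        assert point.clamped
        assert point.y == 0.0
        assert np.isfinite([point.x, point.y]).all()

    def test_degenerate_outputs_always_finite(self, rng):
        for _ in range(200):
            d1, d2, c = rng.random(3) * 10 + 1e-6
            p = triangulate_point(d1, d2, c)
            assert np.isfinite([p.x, p.y]).all()
            assert p.y >= 0

    def test_zero_anchor_separation_rejected(self):
        with pytest.raises(ValueError, match="anchors"):
            triangulate_point(1.0, 1.0, 0.0)

    def test_recovered_cohort_moves_toward_baseline(self):
        """Across the recovery schedule the triangulation x decreases."""
        eff = syn.CohortEffect(
            "recovered", extension_deficit=10.0, posture_substitution_rate=0.8,
            recovery_schedule={"2d": 1.0, "7d": 0.85, "14d": 0.55,
                               "21d": 0.25, "35d": 0.0},
        )
        rng = np.random.default_rng(11)
        base_ref = syn.generate_grasp_sequences(25, rng=rng)
        d2_ref = syn.generate_grasp_sequences(25, eff, 1.0, rng=rng)
        xs = [
            session_triangulation(
                syn.generate_grasp_sequences(40, eff, eff.scale_at(tp), rng=rng),
                base_ref, d2_ref, params=PARAMS, seed=0,
            ).x
            for tp in ("2d", "7d", "14d", "21d", "35d")
        ]
        assert all(a > b for a, b in zip(xs, xs[1:]))


class TestRecoveryKS:
    def test_reference_half_tested_against_itself_is_null(self):
        base = _grasps(40, seed=5)
        res = recovery_ks_test(base[1::2], base, params=PARAMS, Q=5, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue > 0.9
        assert not res.significant

    def test_sample_size_minimum_enforced(self):
        small = _grasps(4, seed=6)
        base = _grasps(40, seed=7)
        with pytest.raises(ValueError, match="at least 5"):
            recovery_ks_test(small, base, params=PARAMS)
        with pytest.raises(ValueError, match="10 baseline"):
            recovery_ks_test(base[:6], small, params=PARAMS)

    def test_strongly_impaired_session_detected(self):
        base = _grasps(40, seed=8)
        impaired = _grasps(20, syn.CohortEffect(
            "impaired_no_supination", posture_substitution_rate=1.0,
            extension_deficit=12.0, recovery_schedule={"2d": 1.0},
        ), seed=9)
        res = recovery_ks_test(impaired, base, params=PARAMS, Q=5, seed=0)
        assert res.significant

    def test_statistic_matches_direct_empirical_cdf_comparison(self, rng):
        """The reported statistic equals the closed-form two-sample
        sup-difference of empirical CDFs."""
        from scipy.stats import ks_2samp

        a = rng.normal(size=40)
        b = rng.normal(0.3, 1.0, size=35)
        stat = ks_2samp(a, b).statistic
        grid = np.sort(np.r_[a, b])
        cdf_a = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        cdf_b = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        assert stat == pytest.approx(np.abs(cdf_a - cdf_b).max(), abs=1e-15)


class TestExtensionAnalysis:
    def test_identical_conditions_yield_zero_difference(self, rng):
        rec = syn.generate_extension_records(30, (100.0, 40.0), rng=rng)
        dist = extension_analysis(rec, rec, (100.0, 40.0))
        assert not dist.difference.any()
        assert dist.ks_pvalue == pytest.approx(1.0)

    def test_marginalisation_conserved_bin_for_bin(self, rng):
        off = syn.generate_extension_records(40, (100.0, 40.0), rng=rng)
        on = syn.generate_extension_records(40, (100.0, 40.0), -8.0, rng=rng)
        dist = extension_analysis(off, on, (100.0, 40.0), bin_width=2.0)
        for d2, marg in ((dist.density_off, dist.marginal_x_off),
                         (dist.density_on, dist.marginal_x_on)):
            assert np.allclose(d2.sum(axis=1) * 2.0, marg)
        # densities integrate to 1, the difference to 0
        assert dist.marginal_x_off.sum() * 2.0 == pytest.approx(1.0)
        assert dist.difference.sum() * 2.0 == pytest.approx(0.0, abs=1e-12)

    def test_planted_shift_recovered_from_difference_curve(self):
        """+10 px planted shift: difference-curve extrema sit 10 +- 3 px
        apart and the K-S test flags the shift."""
        rng = np.random.default_rng(21)
        off = syn.generate_extension_records(50, (100.0, 40.0), 0.0, 3.0, rng)
        on = syn.generate_extension_records(50, (100.0, 40.0), 10.0, 3.0, rng)
        dist = extension_analysis(off, on, (100.0, 40.0))
        assert difference_extrema_separation(dist) == pytest.approx(10.0, abs=3.0)
        assert dist.ks_pvalue < 0.01

    def test_too_few_or_degenerate_records_rejected(self, rng):
        few = syn.generate_extension_records(3, (100.0, 40.0), rng=rng)
        many = syn.generate_extension_records(20, (100.0, 40.0), rng=rng)
        with pytest.raises(ValueError, match="at least 5"):
            extension_analysis(few, many, (100.0, 40.0))
        same = np.tile([[100.0, 40.0]], (10, 1))
        with pytest.raises(ValueError, match="degenerate"):
            extension_analysis(same, same, (100.0, 40.0))


def _sessions_for_report(seed=0):
    effects = {
        "recovered": syn.CohortEffect(
            "recovered", extension_deficit=10.0, posture_substitution_rate=0.8,
            recovery_schedule={"2d": 1.0, "7d": 0.6, "35d": 0.0},
        ),
        "impaired": syn.CohortEffect(
            "impaired_no_supination", extension_deficit=4.0,
            posture_substitution_rate=0.9,
            recovery_schedule={"2d": 1.0, "7d": 1.0, "35d": 0.9},
        ),
    }
    rng = np.random.default_rng(seed)
    sessions = []
    for name, eff in effects.items():
        for tp in ("baseline", "2d", "7d", "35d"):
            grasps = syn.generate_grasp_sequences(
                12, eff, eff.scale_at(tp), rng=rng
            )
            sessions.append(
                CohortSession(
                    cohort=name, time_point=tp, animal=0,
                    grasps=[GraspSequence(g, apex_index=len(g) // 2)
                            for g in grasps],
                    duration_s=120.0,
                )
            )
    return sessions


class TestCohortReport:
    def test_one_triangulation_point_per_cohort_time_point(self, tmp_path):
        tables = cohort_report(
            _sessions_for_report(), tmp_path, params=PARAMS, Q=5,
            make_plots=False,
        )
        tri = tables["triangulation"]
        assert len(tri) == 4  # 2 cohorts x {7d, 35d}
        assert set(tri["time_point"]) == {"7d", "35d"}
        assert set(tables.keys()) == {
            "triangulation", "recovery_ks", "activity", "phase_bars"
        }
        for name in tables:
            assert (tmp_path / f"{name}.csv").exists()
            assert "config_hash" in tables[name].columns
            assert "seed" in tables[name].columns

    def test_recovered_and_impaired_final_verdicts(self, tmp_path):
        tables = cohort_report(
            _sessions_for_report(), tmp_path, params=PARAMS, Q=5,
            make_plots=False,
        )
        ks = tables["recovery_ks"].set_index(["cohort", "time_point"])
        assert not ks.loc[("recovered", "35d"), "significant"]
        assert ks.loc[("impaired", "35d"), "significant"]

    def test_missing_anchor_sessions_rejected(self, tmp_path):
        sessions = [s for s in _sessions_for_report()
                    if not (s.cohort == "impaired" and s.time_point == "2d")]
        with pytest.raises(ValueError, match="anchor"):
            cohort_report(sessions, tmp_path, params=PARAMS, make_plots=False)

    def test_report_deterministic_on_rerun(self, tmp_path):
        t1 = cohort_report(_sessions_for_report(), tmp_path / "a",
                           params=PARAMS, Q=5, make_plots=False)
        t2 = cohort_report(_sessions_for_report(), tmp_path / "b",
                           params=PARAMS, Q=5, make_plots=False)
        for name in t1:
            pd.testing.assert_frame_equal(t1[name], t2[name])
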