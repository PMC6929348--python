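"""Gamma analysis, machine-log mechanical errors and Spearman correlation."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.ndimage import gaussian_filter

from texqa.delivery_accuracy import (
    CorrelationError,
    GammaCriteria,
    GammaError,
    MechanicalErrorSummary,
    align_record_to_plan,
    average_summaries,
    correlation_panel,
    gamma_analysis,
    mechanical_errors,
    spearman,
)
from texqa.plan_model import (
    Beam,
    ControlPoint,
    DeliveryRecord,
    LogBeam,
    Plan,
    Snapshot,
    uniform_geometry,
)
from texqa.synthetic import SynthLogSpec, SynthPlanSpec, generate_plan, simulate_log
from tests.conftest import brute_force_gamma, make_dose_plane


def _flat_field(value=1.0, n=30):
    return make_dose_plane(np.full((n, n), value))


class TestGammaAnalysis:
    def test_identical_planes_pass_everywhere(self):
        rng = np.random.default_rng(0)
        dose = gaussian_filter(rng.uniform(0, 2, (40, 40)), 3)
        ref = make_dose_plane(dose)
        res = gamma_analysis(ref, ref, GammaCriteria(2, 2))
        assert res.passing_rate == 100.0
        evaluated = res.gamma_map[~np.isnan(res.gamma_map)]
        np.testing.assert_allclose(evaluated, 0.0, atol=1e-12)
        assert res.n_evaluated == int(np.sum(dose >= 0.1 * dose.max()))

    def test_uniform_two_percent_offset_on_flat_field(self):
        """On a flat field there is no dose gradient, so a uniform +2% (of
        max) offset gives gamma exactly 2%/delta everywhere: all points pass
        at 2%/2mm (gamma = 1) and none at 1%/2mm (gamma = 2)."""
        ref = _flat_field(1.0)
        meas = _flat_field(1.02)
        res22 = gamma_analysis(ref, meas, GammaCriteria(2, 2))
        np.testing.assert_allclose(res22.gamma_map, 1.0, atol=1e-9)
        assert res22.passing_rate == 100.0
        res12 = gamma_analysis(ref, meas, GammaCriteria(1, 2))
        np.testing.assert_allclose(res12.gamma_map, 2.0, atol=1e-9)
        assert res12.passing_rate == 0.0

    def test_low_dose_points_are_excluded(self):
        dose = np.ones((20, 20))
        dose[:5, :] = 0.05  # below the 10% cutoff
        ref = make_dose_plane(dose)
        res = gamma_analysis(ref, ref, GammaCriteria(2, 2))
        assert res.n_evaluated == 300
        assert np.isnan(res.gamma_map[:5, :]).all()

    def test_matches_exhaustive_search_oracle(self):
        rng = np.random.default_rng(42)
        base = gaussian_filter(rng.uniform(0, 1, (50, 50)), 4)
        ref = make_dose_plane(base)
        meas = make_dose_plane(
            np.clip(base * (1 + rng.normal(0, 0.015, base.shape)), 0, None)
        )
        for crit in (GammaCriteria(2, 2), GammaCriteria(1, 1)):
            fast = gamma_analysis(ref, meas, crit).gamma_map
            slow = brute_force_gamma(ref, meas, crit)
            np.testing.assert_allclose(fast, slow, atol=1e-3)

    def test_loosening_criteria_never_decreases_passing_rate(self):
        rng = np.random.default_rng(3)
        base = gaussian_filter(rng.uniform(0, 1, (40, 40)), 3)
        ref = make_dose_plane(base)
        meas = make_dose_plane(np.clip(base * (1 + rng.normal(0, 0.02, base.shape)), 0, None))
        rates = {
            (dp, dta): gamma_analysis(ref, meas, GammaCriteria(dp, dta)).passing_rate
            for dp in (1, 2)
            for dta in (1, 2)
        }
        assert rates[(2, 2)] >= rates[(1, 2)] >= rates[(1, 1)]
        assert rates[(2, 2)] >= rates[(2, 1)] >= rates[(1, 1)]

    def test_global_normalization_is_scale_invariant(self):
        rng = np.random.default_rng(9)
        base = gaussian_filter(rng.uniform(0, 1, (30, 30)), 3)
        noisy = np.clip(base * (1 + rng.normal(0, 0.02, base.shape)), 0, None)
        r1 = gamma_analysis(make_dose_plane(base), make_dose_plane(noisy), GammaCriteria(2, 2))
        r2 = gamma_analysis(
            make_dose_plane(base * 7.3), make_dose_plane(noisy * 7.3), GammaCriteria(2, 2)
        )
        np.testing.assert_allclose(r1.gamma_map, r2.gamma_map, atol=1e-9, equal_nan=True)
        assert r1.passing_rate == r2.passing_rate

    def test_zero_reference_is_an_error(self):
        with pytest.raises(GammaError, match="no dose"):
            gamma_analysis(_flat_field(0.0), _flat_field(1.0), GammaCriteria(2, 2))

    def test_disjoint_planes_are_an_error(self):
        from texqa.delivery_accuracy import DosePlane
        from texqa.fluence import FluenceGrid

        a = _flat_field(1.0, n=10)
        far = DosePlane(FluenceGrid(1.0, 1000.0, 1000.0, 10, 10), np.ones((10, 10)))
        with pytest.raises(GammaError, match="overlap"):
            gamma_analysis(a, far, GammaCriteria(2, 2))


def _record_from_plan(plan: Plan, mlc_offset=0.0, gantry_offset=0.0, mu_offset=0.0):
    beams = []
    for beam in plan.beams:
        snaps = tuple(
            Snapshot(
                index=cp.index,
                cumulative_mu=cp.cumulative_meterset_weight * beam.total_mu + mu_offset,
                gantry_angle=(cp.gantry_angle + gantry_offset) % 360.0,
                bank_A=tuple(a + mlc_offset for a in cp.bank_A),
                bank_B=tuple(b + mlc_offset for b in cp.bank_B),
            )
            for cp in beam.control_points
        )
        beams.append(LogBeam(snapshots=snaps, geometry=beam.geometry))
    return DeliveryRecord(plan_id=plan.plan_id, beams=tuple(beams))


class TestMechanicalErrors:
    def test_identical_record_gives_zero_errors(self, small_plan):
        s = mechanical_errors(small_plan, _record_from_plan(small_plan))
        assert (s.mlc_error_mm, s.gantry_error_deg, s.mu_error) == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("offset", [0.1, -0.1, 0.5])
    def test_constant_leaf_offset_recovered_exactly(self, small_plan, offset):
        s = mechanical_errors(small_plan, _record_from_plan(small_plan, mlc_offset=offset))
        assert s.mlc_error_mm == pytest.approx(abs(offset), abs=1e-12)

    def test_gaussian_noise_recovered_as_folded_normal_mean(self):
        """Mean |N(0, sigma)| = sigma*sqrt(2/pi); checked with >= 1e4
        leaf-control-point samples."""
        plan = generate_plan(
            SynthPlanSpec(n_control_points=280, modulation_amplitude_mm=2.0, seed=5)
        )
        n_samples = 2 * 280 * plan.beams[0].geometry.n_pairs
        assert n_samples >= 10_000
        record = simulate_log(plan, SynthLogSpec(sigma_mlc_mm=0.1, sigma_gantry_deg=0,
                                                 sigma_mu=0, seed=8))
        s = mechanical_errors(plan, record)
        expected = 0.1 * math.sqrt(2 / math.pi)
        assert s.mlc_error_mm == pytest.approx(expected, rel=0.05)

    def test_gantry_difference_wraps_at_360(self, small_plan):
        record = _record_from_plan(small_plan, gantry_offset=359.0)
        s = mechanical_errors(small_plan, record)
        assert s.gantry_error_deg == pytest.approx(1.0)

    def test_mismatched_leaf_count_is_an_error(self, small_plan):
        record = _record_from_plan(small_plan)
        other = DeliveryRecord(
            record.plan_id,
            (LogBeam(record.beams[0].snapshots, geometry=uniform_geometry(3, 5.0)),),
        )
        with pytest.raises(ValueError, match="leaf count"):
            mechanical_errors(small_plan, other)

    def test_align_record_resamples_denser_log(self, small_plan):
        """A log sampled at twice the plan's control-point density, once
        aligned, agrees with the plan (linear trajectories)."""
        beam = small_plan.beams[0]
        ws = np.linspace(0, 1, 5)
        a = np.linspace(-5, 0, 5)
        snaps = tuple(
            Snapshot(i, w * beam.total_mu, 180.0 + 20 * w, (a[i], a[i]), (a[i] + 10, a[i] + 10))
            for i, w in enumerate(ws)
        )
        dense = DeliveryRecord("small", (LogBeam(snaps, geometry=beam.geometry),))
        aligned = align_record_to_plan(small_plan, dense)
        s = mechanical_errors(small_plan, aligned)
        assert s.mlc_error_mm == pytest.approx(0.0, abs=1e-9)
        assert s.mu_error == pytest.approx(0.0, abs=1e-9)


class TestAverageSummaries:
    def test_single_summary_is_identity(self):
        s = MechanicalErrorSummary(0.1, 0.2, 0.3)
        assert average_summaries([s]) == s

    def test_componentwise_mean_and_order_invariance(self):
        a = MechanicalErrorSummary(0.1, 0.0, 0.0)
        b = MechanicalErrorSummary(0.3, 0.0, 0.0)
        assert average_summaries([a, b]).mlc_error_mm == pytest.approx(0.2)
        assert average_summaries([a, b]) == average_summaries([b, a])

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            average_summaries([])


class TestSpearman:
    def test_monotone_relations(self):
        x = [1.0, 2.0, 5.0, 7.0, 11.0]
        assert spearman(x, [v**3 for v in x]).r == pytest.approx(1.0)
        assert spearman(x, [-v for v in x]).r == pytest.approx(-1.0)

    def test_rank_displacement_worked_example(self):
        # sum d^2 = 4 over n=5 untied ranks: r = 1 - 6*4/(5*24) = 0.8
        res = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.r == pytest.approx(0.8)

    def test_exact_p_matches_full_permutation_enumeration(self):
        """For n <= 9 the two-sided p-value equals the fraction of
        permutations with |r| at least as extreme (independent oracle via
        scipy.stats.permutation_test with exact enumeration)."""
        rng = np.random.default_rng(2)
        for n in (5, 6, 7):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            res = spearman(x, y)

            def stat(y_perm):
                return stats.spearmanr(x, y_perm).statistic

            oracle = stats.permutation_test(
                (y,), stat, permutation_type="pairings", alternative="two-sided",
                n_resamples=np.inf,
            )
            assert res.r == pytest.approx(oracle.statistic, abs=1e-12)
            assert res.p == pytest.approx(oracle.pvalue, abs=1e-9)

    def test_large_n_matches_scipy_t_approximation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=60)
        y = x + rng.normal(size=60)
        res = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(1, 10, 20)
        y = rng.uniform(1, 10, 20)
        base = spearman(x, y)
        assert spearman(np.log(x), y**3).r == pytest.approx(base.r, abs=1e-12)
        assert spearman(np.log(x), y**3).p == pytest.approx(base.p, rel=1e-12)

    def test_midranks_for_ties_match_scipy(self):
        x = [1, 2, 2, 3, 4, 4, 4, 5, 6, 7, 8, 9]
        y = [2, 1, 3, 3, 5, 4, 6, 7, 7, 8, 10, 9]
        assert spearman(x, y).r == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_constant_input_is_an_error(self):
        with pytest.raises(CorrelationError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_input_is_an_error(self):
        with pytest.raises(CorrelationError):
            spearman([1, 2], [3, 4])


class TestCorrelationPanel:
    def _tables(self, n_plans=12, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"p{i}" for i in range(n_plans)]
        cols = pd.MultiIndex.from_product(
            [["ASM", "entropy"], [1, 5, 10]], names=["feature", "d"]
        )
        features = pd.DataFrame(rng.normal(size=(n_plans, 6)), index=idx, columns=cols)
        return features

    def test_measure_equal_to_feature_column_gives_r_one(self):
        features = self._tables()
        measures = pd.DataFrame(
            {"m": features[("ASM", 10)].to_numpy()}, index=features.index
        )
        panel, counts = correlation_panel(features, measures)
        row = panel[(panel.feature == "ASM") & (panel.d == 10)].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.significant
        assert counts.set_index(["feature", "d"]).loc[("ASM", 10), "n_significant"] == 1

    def test_panel_covers_all_feature_measure_cells(self):
        features = self._tables()
        rng = np.random.default_rng(1)
        measures = pd.DataFrame(
            rng.normal(size=(12, 3)), index=features.index, columns=["a", "b", "c"]
        )
        panel, _ = correlation_panel(features, measures)
        assert len(panel) == 6 * 3
        assert not panel.r.isna().any()

    def test_too_few_shared_plans_is_an_error(self):
        features = self._tables(n_plans=4)
        measures = pd.DataFrame({"m": [1.0, 2.0]}, index=["p0", "p1"])
        with pytest.raises(CorrelationError, match="shared plans"):
            correlation_panel(features, measures)

    def test_nonsignificant_cells_flagged_not_dropped(self):
        features = self._tables()
        rng = np.random.default_rng(2)
        measures = pd.DataFrame({"noise": rng.normal(size=12)}, index=features.index)
        panel, _ = correlation_panel(features, measures)
        assert len(panel) == 6
        assert "significant" in panel.columns
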