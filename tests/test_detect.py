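import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

import riskaudit as ra
from riskaudit import (DetectionConfig, classify_curvature, compute_slopes,
                       detect_sign_changepoints, discontinuity_statistic,
                       linearize_component, log_likelihood, scan_artifacts,
                       scan_curve_shapes)
from riskaudit.detect import SignChangepoint, interior_threshold_indices
from conftest import make_component, make_results, table_for


def brute_force_ll(res, tab, override=None):
    """Independent per-row Bernoulli sum (python loop, no vectorization)."""
    total = 0.0
    for i in range(tab.n):
        lo = res.intercept
        for comp in res.components:
            use = comp
            if override is not None and override.feature == comp.feature:
                use = override
            lo += float(use.evaluate([tab.features[comp.feature][i]])[0])
        p = min(max(1.0 / (1.0 + np.exp(-lo)), 1e-12), 1 - 1e-12)
        y = tab.outcome[i]
        total += y * np.log(p) + (1 - y) * np.log(1 - p)
    return total


class TestLinearize:
    def test_step_becomes_ramp(self):
        c = make_component([0.0, 0.0, 2.0, 2.0])  # step at threshold index 1
        lin = linearize_component(c, 1)
        # window [t0, t2) = [1, 3); ramp from f(t0)=0 to f(t2)=2
        assert lin.evaluate([1.0])[0] == pytest.approx(0.0)
        assert lin.evaluate([2.0])[0] == pytest.approx(1.0)
        assert lin.evaluate([2.999])[0] == pytest.approx(2.0, abs=1e-3)
        # unchanged outside the window
        assert lin.evaluate([0.5])[0] == 0.0
        assert lin.evaluate([3.5])[0] == 2.0

    def test_flat_window_identity(self):
        c = make_component([1.0, 1.0, 1.0, 1.0, -2.0])
        lin = linearize_component(c, 1)
        x = np.linspace(0, 5, 101)
        np.testing.assert_allclose(lin.evaluate(x), c.evaluate(x))

    def test_endpoint_identity(self):
        c = make_component([0.3, -0.1, 0.8, 0.2, 0.6])
        lin = linearize_component(c, 2)
        # at the left window edge the interpolation equals f there exactly
        assert lin.evaluate([c.thresholds[1]])[0] == c.evaluate([c.thresholds[1]])[0]

    def test_outer_thresholds_rejected(self):
        c = make_component([0.0, 1.0, 2.0, 3.0])
        with pytest.raises(IndexError, match="interior"):
            linearize_component(c, 0)
        with pytest.raises(IndexError, match="interior"):
            linearize_component(c, 2)
        assert list(interior_threshold_indices(c)) == [1]


class TestLogLikelihood:
    def test_intercept_zero_half_ones(self):
        c = make_component([0.0, 0.0], thresholds=[1.0])
        res = make_results([c], intercept=0.0)
        n = 10
        tab = table_for(res, {"x": np.linspace(0, 2, n)}, [0, 1] * 5)
        assert log_likelihood(res, tab) == pytest.approx(n * np.log(0.5), abs=1e-12)

    def test_override_identity(self):
        c = make_component([0.2, -0.4, 0.6, 0.1])
        res = make_results([c], intercept=-0.2)
        rng = np.random.default_rng(1)
        tab = table_for(res, {"x": rng.uniform(0, 4, 200)}, rng.integers(0, 2, 200))
        lin = linearize_component(c, 1)
        same = ra.LinearizedComponent(base=c, j=1, window_lo=lin.window_lo,
                                      window_hi=lin.window_lo,  # empty window
                                      value_lo=0, value_hi=0)
        assert log_likelihood(res, tab, same) == pytest.approx(
            log_likelihood(res, tab), abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        ca = make_component([0.5, -0.3, 0.1, 0.4], feature="a")
        cb = make_component([-0.2, 0.6], thresholds=[1.5], feature="b")
        res = make_results([ca, cb], intercept=0.3)
        tab = table_for(res, {"a": rng.uniform(0, 4, 60), "b": rng.uniform(0, 3, 60)},
                        rng.integers(0, 2, 60))
        lin = linearize_component(ca, 1)
        assert log_likelihood(res, tab) == pytest.approx(
            brute_force_ll(res, tab), abs=1e-9)
        assert log_likelihood(res, tab, lin) == pytest.approx(
            brute_force_ll(res, tab, lin), abs=1e-9)


class TestDiscontinuityStatistic:
    def test_zero_for_flat_window(self):
        c = make_component([0.7, 0.7, 0.7, 0.7, -1.0])
        res = make_results([c], intercept=0.1)
        rng = np.random.default_rng(3)
        tab = table_for(res, {"x": rng.uniform(0, 5, 300)}, rng.integers(0, 2, 300))
        assert abs(discontinuity_statistic(res, tab, "x", 1)) < 1e-12

    def test_matches_brute_force_difference(self):
        rng = np.random.default_rng(4)
        c = make_component([0.0, 0.2, 1.4, 1.5, 1.2], feature="lab")
        res = make_results([c], intercept=-0.6)
        tab = table_for(res, {"lab": rng.uniform(0, 5, 150)},
                        rng.integers(0, 2, 150))
        for j in interior_threshold_indices(c):
            lin = linearize_component(c, j)
            oracle = brute_force_ll(res, tab) - brute_force_ll(res, tab, lin)
            assert discontinuity_statistic(res, tab, "lab", j) == pytest.approx(
                oracle, abs=1e-9)

    def test_invariant_to_constant_shift_with_intercept_compensation(self):
        rng = np.random.default_rng(5)
        c = make_component([0.0, 0.2, 1.4, 1.5, 1.2])
        res = make_results([c], intercept=-0.6)
        tab = table_for(res, {"x": rng.uniform(0, 5, 200)}, rng.integers(0, 2, 200))
        shift = 0.8
        c2 = make_component(c.values + shift)
        res2 = make_results([c2], intercept=-0.6 - shift)
        for j in interior_threshold_indices(c):
            assert discontinuity_statistic(res2, tab, "x", j) == pytest.approx(
                discontinuity_statistic(res, tab, "x", j), abs=1e-9)

    def test_injected_step_maximal_at_its_threshold(self):
        """A 1 log-odds step in the generating model localizes to its edge."""
        rng = np.random.default_rng(6)
        n = 20_000
        x = rng.uniform(0, 8, n)
        step_at = 4.0
        lo = -1.0 + np.where(x >= step_at, 1.0, 0.0)
        y = (rng.random(n) < expit(lo)).astype(int)
        import pandas as pd
        df = pd.DataFrame({"outcome": y, "x": x})
        res = ra.AdditiveRiskModel.from_dataframe(df, "outcome").fit(
            n_bags=0, n_rounds=150, max_bins=16, seed=7)
        tab = ra.PatientTable.from_dataframe(df, res.schema)
        comp = res.component("x")
        stats = {j: discontinuity_statistic(res, tab, "x", j)
                 for j in interior_threshold_indices(comp)}
        jbest = max(stats, key=stats.get)
        jtrue = int(np.argmin(np.abs(comp.thresholds - step_at)))
        assert stats[jbest] > 0
        assert abs(jbest - jtrue) <= 1

    def test_signed_sum_alternative_runs(self):
        rng = np.random.default_rng(8)
        c = make_component([0.0, 0.0, 2.0, 2.0])
        res = make_results([c])
        tab = table_for(res, {"x": rng.uniform(0, 4, 100)}, rng.integers(0, 2, 100))
        t = discontinuity_statistic(res, tab, "x", 1, method="signed_sum")
        assert np.isfinite(t)


class TestSlopesAndChangepoints:
    @pytest.mark.parametrize("values,expected_signs", [
        ([0.0, 1.0, 2.0, 3.0], [1, 1, 1]),          # strictly increasing
        ([0.0, 1.0, 0.0], [1, -1]),                  # symmetric tent
        ([0.0, 1.0, 1.0, 1.0, 0.0], [1, 0, 0, -1]),  # plateau interior zeros
    ])
    def test_sign_examples(self, values, expected_signs):
        seq = compute_slopes(make_component(values))
        assert seq.signs.tolist() == expected_signs

    def test_changepoint_single_flip(self):
        cps = detect_sign_changepoints([1, 1, 1, -1, -1, -1], min_run=2)
        assert len(cps) == 1
        assert (cps[0].left, cps[0].right) == (2, 3)

    def test_isolated_flip_suppressed(self):
        assert detect_sign_changepoints([1, -1, 1, 1, 1], min_run=2) == []

    def test_all_zero_empty(self):
        assert detect_sign_changepoints([0, 0, 0, 0]) == []

    def test_zeros_removed_before_detection(self):
        cps = detect_sign_changepoints([1, 1, 0, 0, -1, -1], min_run=2)
        assert len(cps) == 1
        assert (cps[0].left, cps[0].right) == (1, 4)

    def test_curvature_classification(self):
        tent = make_component([0.0, 1.0, 0.0])
        peak = detect_sign_changepoints(compute_slopes(tent), min_run=1)[0]
        assert classify_curvature(tent, peak) == "concave"
        valley = make_component([1.0, 0.0, 1.0])
        dip = detect_sign_changepoints(compute_slopes(valley), min_run=1)[0]
        assert classify_curvature(valley, dip) == "convex"

    def test_mirror_symmetry_concave_stays_concave(self):
        """x -> -x maps concave findings to concave at mirrored thresholds."""
        vals = np.array([0.0, 0.4, 1.0, 1.2, 0.7, 0.2])
        c = make_component(vals, thresholds=[1, 2, 3, 4, 5], support=(0.0, 6.0))
        mirrored = make_component(vals[::-1], thresholds=[-5, -4, -3, -2, -1],
                                  support=(-6.0, 0.0))
        r1 = scan_curve_shapes([c], DetectionConfig(min_run=1))
        r2 = scan_curve_shapes([mirrored], DetectionConfig(min_run=1))
        c1 = [m for m in r1.non_monotonicities if m.curvature == "concave"]
        c2 = [m for m in r2.non_monotonicities if m.curvature == "concave"]
        assert len(c1) == len(c2) == 1
        assert c1[0].threshold == pytest.approx(-c2[0].threshold)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.sampled_from([-1, 0, 1]), min_size=1, max_size=30),
           st.integers(1, 3))
    def test_changepoints_match_run_oracle(self, signs, min_run):
        """Every reported flip separates two >= min_run same-sign runs."""
        cps = detect_sign_changepoints(signs, min_run=min_run)
        s = np.asarray(signs)
        for cp in cps:
            assert s[cp.left] == cp.sign_before and s[cp.right] == cp.sign_after
            assert cp.sign_before == -cp.sign_after
        # independent oracle: run-length encode the nonzero subsequence
        nz = [v for v in signs if v != 0]
        runs = []
        for v in nz:
            if runs and runs[-1][0] == v:
                runs[-1][1] += 1
            else:
                runs.append([v, 1])
        expected = sum(1 for i in range(len(runs) - 1)
                       if runs[i][1] >= min_run and runs[i + 1][1] >= min_run)
        assert len(cps) == expected


class TestScan:
    def test_strict_scenario_top_discontinuity_at_protocol_threshold(
            self, strict_pipeline):
        scn, cohort, table, res, report = strict_pipeline
        top = report.ranked_discontinuities()[0]
        assert top.feature == "biomarker"
        assert top.flagged
        comp = res.component("biomarker")
        jtrue = int(np.argmin(np.abs(comp.thresholds - scn.policy.threshold)))
        assert abs(top.threshold_index - jtrue) <= 1

    def test_scan_unbagged_model_never_flags(self, strict_pipeline):
        *_, table, res, _ = strict_pipeline
        point = ra.AdditiveRiskResults(
            schema=res.schema, intercept=res.intercept, components=res.components,
            fit_config=res.fit_config, bag_models=None, n_obs=res.n_obs)
        with pytest.warns(UserWarning, match="no bootstrap bags"):
            rep = scan_artifacts(point, table)
        assert all(not d.flagged for d in rep.discontinuities)
        assert all(not m.flagged for m in rep.non_monotonicities)

    def test_report_roundtrip_and_ranking(self, strict_pipeline, tmp_path):
        *_, report = strict_pipeline
        p = tmp_path / "report.json"
        report.to_json(p)
        import json
        doc = json.loads(p.read_text())
        assert doc["format"] == "riskaudit-report"
        # ranking: non-increasing bag support; |T_d| breaks ties
        discs = doc["discontinuities"]
        for a, b in zip(discs, discs[1:]):
            assert (a["bag_support"] > b["bag_support"] - 1e-12 or
                    abs(a["statistic_median"]) >= abs(b["statistic_median"]) - 1e-12)

    def test_shape_only_report_marks_likelihoods_unavailable(self):
        c = make_component([0.0, 0.5, 1.0, 0.4, 0.1], feature="lab")
        rep = scan_curve_shapes([c], DetectionConfig(min_run=1))
        doc = rep.to_dict()
        assert doc["mode"] == "shape_only"
        assert doc["likelihood_statistics"] == "unavailable"
        assert doc["discontinuities"] == []
        assert all(not m["flagged"] for m in doc["non_monotonicities"])
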