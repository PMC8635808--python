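"""Nonparametric group comparisons, survival analysis, report assembly."""

import filecmp
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import mussdai as m
from mussdai.stats import kruskal_dunn, mann_whitney


def brute_force_mwu(x, y):
    """Independent oracle: U via pairwise comparisons, p by enumeration."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    mu = n1 * len(y) / 2.0

    def u_of(xs, ys):
        return float(sum((a > b) + 0.5 * (a == b) for a in xs for b in ys))

    u_obs = u_of(x, y)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        rest = [i for i in range(len(pooled)) if i not in idx]
        u = u_of(pooled[list(idx)], pooled[rest])
        total += 1
        hits += abs(u - mu) >= abs(u_obs - mu) - 1e-12
    return u_obs, hits / total


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        u, p = mann_whitney([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert p == 1.0

    def test_fully_separated_small_samples(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)   # 2 / C(6,3) extreme tables

    def test_separation_attains_exact_minimum(self):
        # only the observed table (all four 1s in the first sample) reaches
        # |U − μ| = 6: the mirror U = 12 needs four 9s but only three exist,
        # so the exact two-sided minimum is 1/C(7,4)
        from math import comb
        x, y = [1.0, 1.0, 1.0, 1.0], [9.0, 9.0, 9.0]
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(1 / comb(7, 4))
        assert p == pytest.approx(brute_force_mwu(x, y)[1])

    def test_exact_matches_brute_force_on_all_small_layouts(self, rng):
        for n1 in range(1, 6):
            for n2 in range(1, 6):
                x = rng.integers(0, 4, n1).astype(float)  # heavy ties
                y = rng.integers(0, 4, n2).astype(float)
                assert mann_whitney(x, y) == pytest.approx(
                    brute_force_mwu(x, y)), (x, y)

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(2, 7)))
            y = rng.normal(size=int(rng.integers(2, 7)))
            u, p = mann_whitney(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_normal_approximation_close_to_scipy_asymptotic(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(0.8, 1, 18)
        _, p = mann_whitney(x, y)   # n > 20 -> tie-corrected normal + cc
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic").pvalue
        assert p == pytest.approx(ref, rel=0.05)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestTreatedVsControls:
    def test_controls_are_pooled(self):
        by_group = {"NT": [1.0, 2.0], "PBS": [3.0], "KLH": [4.0],
                    "IFN_K": [10.0, 11.0]}
        comp = m.compare_treated_vs_controls(by_group, endpoint="SFR")
        assert comp.n == (4, 2)
        assert comp.mean[0] == pytest.approx(2.5)
        u, p = mann_whitney([1, 2, 3, 4], [10, 11])
        assert comp.p_value == pytest.approx(p)

    def test_single_side_gives_summary_without_test(self):
        comp = m.compare_treated_vs_controls({"NT": [1.0, 2.0, 3.0]})
        assert comp.p_value is None and comp.statistic is None
        assert comp.n == (3, 0)

    def test_no_data_rejected(self):
        with pytest.raises(ValueError):
            m.compare_treated_vs_controls({})


class TestKruskalDunn:
    def test_identical_constants_give_h_zero_p_one(self):
        omni, _ = kruskal_dunn({"NT": [5.0, 5.0], "PBS": [5.0, 5.0],
                                "KLH": [5.0], "IFN_K": [5.0, 5.0]})
        assert omni.statistic == 0.0 and omni.p_value == 1.0

    def test_omnibus_matches_scipy(self, rng):
        groups = {g: rng.normal(i, 1, 7) for i, g in
                  enumerate(("NT", "PBS", "KLH", "IFN_K"))}
        omni, _ = kruskal_dunn(groups)
        h, p = sps.kruskal(*groups.values())
        assert omni.statistic == pytest.approx(h)
        assert omni.p_value == pytest.approx(p)

    def test_two_group_dunn_equals_kruskal_wallis(self, rng):
        """For k=2 the Dunn z² equals the Kruskal-Wallis H statistic."""
        x = rng.integers(0, 6, 8).astype(float)   # include ties
        y = rng.integers(0, 6, 9).astype(float)
        omni, [dunn] = kruskal_dunn({"NT": x, "IFN_K": y})
        assert dunn.statistic ** 2 == pytest.approx(omni.statistic)
        assert dunn.p_value == pytest.approx(
            sps.chi2.sf(omni.statistic, df=1))

    def test_dunn_hand_computed_example(self):
        # groups (1,2), (3,4), (5,6): ranks 1..6, no ties
        # mean ranks 1.5, 3.5, 5.5; z = (1.5-5.5)/sqrt((6*7/12)*(1/2+1/2))
        _, posthoc = kruskal_dunn({"NT": [1.0, 2.0], "KLH": [3.0, 4.0],
                                   "IFN_K": [5.0, 6.0]})
        by = {c.groups[0]: c for c in posthoc}
        z_expected = -4.0 / np.sqrt((6 * 7 / 12.0) * 1.0)
        assert by["NT"].statistic == pytest.approx(z_expected)
        assert by["NT"].p_value == pytest.approx(
            2 * sps.norm.sf(abs(z_expected)))

    def test_family_adjustment_only_increases_p(self, rng):
        groups = {g: rng.normal(i * 0.5, 1, 7) for i, g in
                  enumerate(("NT", "PBS", "KLH", "IFN_K"))}
        _, raw = kruskal_dunn(groups)
        _, adj = kruskal_dunn(groups, adjust="holm")
        for a, b in zip(raw, adj):
            assert b.p_value >= a.p_value - 1e-12

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_dunn({"NT": [1.0, 2.0]})


class TestSurvival:
    def _mice(self, n_ctrl=4, n_trt=3, death=None):
        rows = []
        for i in range(n_ctrl):
            rows.append({"mouse_id": f"c{i}", "cohort": "SWE01",
                         "group": "NT", "alive_at_end": True,
                         "death_day": None})
        for i in range(n_trt):
            rows.append({"mouse_id": f"t{i}", "cohort": "SWE01",
                         "group": "IFN_K", "alive_at_end": True,
                         "death_day": None})
        return pd.DataFrame(rows)

    def _grades(self, events):
        rows = []
        for mouse, onset_week in events.items():
            for week in (0, 3, 6, 9, 12, 16):
                level = 0 if onset_week is None or week < onset_week else 2
                rows.append({"mouse_id": mouse, "kind": "PROTEINURIA",
                             "week": week, "site": None, "level": level})
        return pd.DataFrame(rows)

    def test_no_events_flat_curves_p_one(self):
        mice = self._mice()
        grades = self._grades({mid: None for mid in mice["mouse_id"]})
        surv = m.proteinuria_free_survival(grades, mice)
        assert surv.logrank_p == 1.0
        for curve in surv.curves.values():
            assert (curve.iloc[:, 0] == 1.0).all()

    def test_complete_separation_matches_hand_computed_logrank(self):
        """All 4 controls convert at week 3, treated never: one event time,
        O−E and V have closed forms."""
        mice = self._mice(n_ctrl=4, n_trt=3)
        events = {f"c{i}": 3 for i in range(4)} | {f"t{i}": None
                                                   for i in range(3)}
        surv = m.proteinuria_free_survival(self._grades(events), mice)
        # at t=21: d=4 events, 7 at risk (4 control, 3 treated)
        d, n, n1 = 4, 7, 4
        expected_ctrl = d * n1 / n
        var = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        chi2 = (4 - expected_ctrl) ** 2 / var
        assert surv.logrank_statistic == pytest.approx(chi2)
        assert surv.logrank_p == pytest.approx(sps.chi2.sf(chi2, df=1))

    def test_event_time_is_first_scheduled_week_at_threshold(self):
        mice = self._mice(n_ctrl=1, n_trt=0)
        surv = m.proteinuria_free_survival(self._grades({"c0": 9}), mice)
        assert surv.table.loc[0, "duration"] == 63.0  # week 9 → day 63
        assert bool(surv.table.loc[0, "event"])

    def test_threshold_config(self):
        mice = self._mice(n_ctrl=1, n_trt=0)
        grades = self._grades({"c0": 6})  # levels jump straight to 2
        low = m.proteinuria_free_survival(grades, mice, threshold=1)
        high = m.proteinuria_free_survival(grades, mice, threshold=3)
        assert bool(low.table.loc[0, "event"])
        assert not bool(high.table.loc[0, "event"])

    def test_km_curves_are_non_increasing_in_unit_interval(self, default_dataset):
        surv = m.proteinuria_free_survival(default_dataset.grades,
                                           default_dataset.mice)
        for curve in surv.curves.values():
            vals = curve.iloc[:, 0].to_numpy()
            assert (np.diff(vals) <= 1e-12).all()
            assert ((0 <= vals) & (vals <= 1)).all()

    def test_death_composite_endpoint(self):
        mice = self._mice(n_ctrl=2, n_trt=0)
        mice.loc[0, "death_day"] = 40
        mice.loc[0, "alive_at_end"] = False
        grades = self._grades({"c0": None, "c1": None})
        comp = m.proteinuria_free_survival(grades, mice, endpoint="COMPOSITE")
        assert comp.table.set_index("mouse_id").loc["c0", "duration"] == 40.0
        death_only = m.proteinuria_free_survival(grades, mice,
                                                 endpoint="DEATH")
        assert int(death_only.table["event"].sum()) == 1

    def test_single_group_curve_without_test(self):
        mice = self._mice(n_ctrl=2, n_trt=0)
        surv = m.proteinuria_free_survival(
            self._grades({"c0": 6, "c1": None}), mice)
        assert surv.logrank_p is None
        assert set(surv.curves) == {"NT"}


class TestReport:
    def test_full_run_has_row_per_endpoint_timepoint_cohort(self, default_dataset):
        tables = m.build_report(default_dataset)
        endpoints = tables["endpoints"]
        assert len(endpoints) == 2 * 7 * 3  # cohorts × tests × timepoints
        assert not tables["warnings"]

    def test_rerun_is_byte_identical(self, default_dataset, tmp_path):
        m.build_report(default_dataset, out_dir=tmp_path / "a")
        m.build_report(default_dataset, out_dir=tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert filecmp.cmp(f, tmp_path / "b" / f.name, shallow=False), f

    def test_missing_stage_is_flagged_not_fatal(self, default_dataset):
        ds = m.CohortDataset(
            mice=default_dataset.mice,
            measurements=default_dataset.measurements,
            grades=default_dataset.grades,
        )
        tables = m.build_report(ds)
        assert "histology" not in tables
        assert any("histology" in w for w in tables["warnings"])
        assert "endpoints" in tables
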