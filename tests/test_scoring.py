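"""MuSSDAI: premorbid calibration, 0–3 grading, weighted domain totals."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import mussdai as m
from mussdai.cohort import TESTS
from mussdai.scoring import (DIRECTIONS, DOMAINS, GradingScheme,
                             HIGHER_IS_WORSE, LOWER_IS_WORSE, MAX_TOTAL,
                             calibrate_schemes, compute_mussdai, grade,
                             grade_lymphadenopathy)


def oracle_grade(value, scheme):
    """Independent edge-enumeration classifier mirroring the grading text."""
    mean = scheme.premorbid_mean
    if scheme.direction == LOWER_IS_WORSE:
        e1 = scheme.ci95_low
        e2, e3 = e1 - 0.15 * mean, e1 - 0.30 * mean
        if value >= e1:          # inside CI (closed) or healthy side
            return 0
        if e2 < value < e1:
            return 1
        if e3 < value <= e2:     # bands closed at the edge nearer the mean
            return 2
        return 3
    else:
        e1 = scheme.ci95_high
        e2, e3 = e1 + 0.15 * mean, e1 + 0.30 * mean
        if value <= e1:
            return 0
        if e1 < value < e2:
            return 1
        if e2 <= value < e3:
            return 2
        return 3


def random_scheme(rng):
    test = rng.choice(list(DIRECTIONS))
    mean = float(rng.uniform(0.5, 50.0))
    half = float(rng.uniform(0.01, 0.2)) * mean
    return GradingScheme(test, mean, mean - half, mean + half,
                         DIRECTIONS[test])


def full_values(schemes, severity):
    """Values grading exactly `severity` on every functional test."""
    out = {}
    for t, s in schemes.items():
        sign = -1.0 if s.direction == LOWER_IS_WORSE else 1.0
        if severity == 0:
            out[t] = s.premorbid_mean
        elif severity == 3:
            out[t] = s.e3 + sign * 0.5 * abs(s.premorbid_mean)
        else:
            raise NotImplementedError
    return out


class TestCalibration:
    def test_ci_half_width_matches_closed_form(self, rng):
        vals = rng.normal(10.0, 1.0, size=52)
        schemes = calibrate_schemes({t: vals for t in TESTS})
        s = schemes["SFR"]
        expected = 1.959963984540054 * vals.std(ddof=1) / math.sqrt(52)
        assert (s.ci95_high - s.ci95_low) / 2 == pytest.approx(expected)
        assert expected == pytest.approx(0.272, abs=0.05)  # SD ≈ 1, n = 52

    def test_t_quantile_option_widens_interval(self, rng):
        vals = rng.normal(10.0, 1.0, size=52)
        data = {t: vals for t in TESTS}
        normal = calibrate_schemes(data)["SFR"]
        student = calibrate_schemes(data, ci_method="t")["SFR"]
        assert student.ci95_high > normal.ci95_high
        from scipy import stats as sps
        lo, hi = sps.t.interval(0.95, df=51, loc=vals.mean(),
                                scale=vals.std(ddof=1) / math.sqrt(52))
        assert (student.ci95_low, student.ci95_high) == pytest.approx((lo, hi))

    def test_direction_map(self):
        assert DIRECTIONS["VON_FREY"] == HIGHER_IS_WORSE
        assert DIRECTIONS["FORCED_SWIM_IMMOBILITY_PCT"] == HIGHER_IS_WORSE
        for t in ("SFR", "PHENOL_RED", "COLD_PLATE",
                  "OPEN_FIELD_CENTER_PCT", "SUCROSE_RATIO"):
            assert DIRECTIONS[t] == LOWER_IS_WORSE

    def test_missing_test_is_named_in_error(self):
        data = {t: [1.0, 2.0] for t in TESTS if t != "SUCROSE_RATIO"}
        with pytest.raises(ValueError, match="SUCROSE_RATIO"):
            calibrate_schemes(data)

    def test_zero_variance_degenerates_to_point_interval(self):
        schemes = calibrate_schemes({t: [5.0, 5.0, 5.0] for t in TESTS})
        s = schemes["SFR"]
        assert s.ci95_low == s.ci95_high == 5.0
        assert grade(5.0, s) == 0
        assert grade(4.999, s) >= 1  # any severity-side deviation scores

    def test_permutation_invariance(self, rng):
        vals = rng.normal(3.0, 0.5, size=52)
        a = calibrate_schemes({t: vals for t in TESTS})["SFR"]
        b = calibrate_schemes({t: rng.permutation(vals) for t in TESTS})["SFR"]
        assert (a.ci95_low, a.ci95_high) == pytest.approx(
            (b.ci95_low, b.ci95_high))


class TestGrade:
    def test_lower_is_worse_bands(self):
        s = GradingScheme("SFR", 10.0, 9.0, 11.0, LOWER_IS_WORSE)
        assert (s.e1, s.e2, s.e3) == (9.0, 7.5, 6.0)
        assert grade(10.0, s) == 0   # at the premorbid mean
        assert grade(9.0, s) == 0    # CI limit itself is inside (closed CI)
        assert grade(8.0, s) == 1
        assert grade(7.5, s) == 2    # band closed at the edge nearer the mean
        assert grade(7.0, s) == 2
        assert grade(6.0, s) == 3
        assert grade(5.9, s) == 3
        assert grade(12.5, s) == 0   # healthy side beyond the CI

    def test_higher_is_worse_bands(self):
        s = GradingScheme("VON_FREY", 0.10, 0.08, 0.12, HIGHER_IS_WORSE)
        assert grade(0.13, s) == 1   # between 0.12 and 0.135
        assert grade(0.135, s) == 2
        assert grade(0.15, s) == 3
        assert grade(0.05, s) == 0   # healthy side

    def test_non_finite_value_rejected(self):
        s = GradingScheme("SFR", 10.0, 9.0, 11.0, LOWER_IS_WORSE)
        with pytest.raises(ValueError):
            grade(float("nan"), s)

    def test_matches_edge_enumeration_oracle(self, rng):
        for _ in range(50):
            s = random_scheme(rng)
            span = 0.6 * s.premorbid_mean
            for v in np.linspace(s.premorbid_mean - span,
                                 s.premorbid_mean + span, 201):
                assert grade(float(v), s) == oracle_grade(float(v), s), (s, v)

    def test_healthy_side_always_zero(self, rng):
        for _ in range(20):
            s = random_scheme(rng)
            sign = 1.0 if s.direction == LOWER_IS_WORSE else -1.0
            for v in (s.premorbid_mean + sign * rng.uniform(0, 5, 10)):
                assert grade(float(v), s) == 0


class TestLymphAggregation:
    def test_max_rule(self):
        assert grade_lymphadenopathy(
            {"cervical": 1, "axillary": 0, "brachial": 2, "inguinal": 1}) == 2

    def test_all_sites_clear(self):
        assert grade_lymphadenopathy({s: 0 for s in
                                      ("cervical", "axillary")}) == 0

    def test_single_site(self):
        assert grade_lymphadenopathy({"inguinal": 1}) == 1

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            grade_lymphadenopathy({})

    def test_alternative_rules(self):
        sites = {"cervical": 1, "axillary": 1, "brachial": 0, "inguinal": 0}
        assert grade_lymphadenopathy(sites, rule="sum") == 2
        assert grade_lymphadenopathy(sites, rule="mean") == 0


class TestComputeMussdai:
    @pytest.fixture
    def schemes(self):
        return {t: GradingScheme(t, 10.0, 9.0, 11.0, DIRECTIONS[t])
                for t in TESTS}

    def test_all_grades_zero_gives_zero(self, schemes):
        res = compute_mussdai(full_values(schemes, 0), schemes, 0, 0)
        assert res.total == 0.0 and res.complete

    def test_all_grades_maximal_gives_65(self, schemes):
        res = compute_mussdai(full_values(schemes, 3), schemes, 2, 3)
        assert res.total == MAX_TOTAL == 65

    def test_weighted_sum_hand_example(self, schemes):
        # all functional tests at grade 0, lymph 2, proteinuria 3
        res = compute_mussdai(full_values(schemes, 0), schemes, 2, 3)
        assert res.total == 4 * 2 + 5 * 3 == 23

    def test_domain_weights_split_over_subtests(self, schemes):
        values = full_values(schemes, 0)
        s = schemes["SFR"]
        values["SFR"] = s.e3 - 1.0  # grade 3 on one glandular sub-test
        res = compute_mussdai(values, schemes, 0, 0)
        assert res.domain_scores["GLANDULAR"] == pytest.approx(1.5 * 3)
        assert res.total == pytest.approx(4.5)

    def test_missing_subtest_flags_incomplete(self, schemes):
        values = full_values(schemes, 0)
        del values["COLD_PLATE"]
        res = compute_mussdai(values, schemes, 0, 0)
        assert res.total is None
        assert res.missing_domains == ["PNS"]

    def test_missing_grades_flag_their_domains(self, schemes):
        res = compute_mussdai(full_values(schemes, 0), schemes, None, None)
        assert set(res.missing_domains) == {"LYMPHADENOPATHY", "RENAL"}

    def test_monotone_under_single_measurement_worsening(self, rng):
        schemes = {t: GradingScheme(t, 10.0, 9.0, 11.0, DIRECTIONS[t])
                   for t in TESTS}
        for _ in range(100):
            values = {t: float(rng.uniform(4.0, 16.0)) for t in TESTS}
            base = compute_mussdai(values, schemes, 1, 1).total
            t = rng.choice(list(TESTS))
            sign = (-1.0 if schemes[t].direction == LOWER_IS_WORSE else 1.0)
            worse = dict(values)
            worse[t] = values[t] + sign * float(rng.uniform(0, 5))
            assert compute_mussdai(worse, schemes, 1, 1).total >= base


class TestMussdaiScorer:
    def test_fit_transform_on_default_cohort(self, default_dataset):
        scorer = m.MussdaiScorer().fit(default_dataset)
        assert scorer.n_premorbid_ == 52
        scores = scorer.transform(default_dataset)
        assert len(scores) == 52          # no deaths at default hazard
        assert scores["total"].between(0, 65).all()
        # treatment effect points the right way in both cohorts
        for cohort, sub in scores.groupby("cohort"):
            treated = sub.loc[sub["group"] == "IFN_K", "total"].mean()
            control = sub.loc[sub["group"] != "IFN_K", "total"].mean()
            assert treated < control

    def test_unfitted_transform_rejected(self, default_dataset):
        with pytest.raises(ValueError, match="not fitted"):
            m.MussdaiScorer().transform(default_dataset)

    def test_sklearn_param_protocol(self):
        scorer = m.MussdaiScorer(ci_method="t", lymph_rule="sum")
        cloned = clone(scorer)
        assert cloned.get_params()["ci_method"] == "t"
        assert cloned.get_params()["lymph_rule"] == "sum"

    def test_dead_mice_are_excluded(self):
        ds = m.generate_cohorts(m.GeneratorConfig(
            seed=4, dropout_hazard={"control": 0.01, "treated": 0.01}))
        scores = m.MussdaiScorer().fit(ds).transform(ds)
        dead = ds.mice.loc[ds.mice["death_day"].notna()
                           & (ds.mice["death_day"] < 112), "mouse_id"]
        assert not set(dead) & set(scores["mouse_id"])

    def test_summary_identical_groups_gives_p_one(self):
        scores = pd.DataFrame({
            "mouse_id": [f"m{i}" for i in range(8)],
            "cohort": ["SWE01"] * 8,
            "group": ["NT", "PBS", "KLH", "IFN_K"] * 2,
            "total": [20.0] * 8,
            "incomplete": [False] * 8,
        })
        summary = m.summarize_mussdai(scores)
        assert summary.loc[0, "p_value"] == pytest.approx(1.0)
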