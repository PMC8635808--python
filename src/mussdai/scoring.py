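"""MuSSDAI — the murine Sjögren's syndrome disease-activity index.

The index is modelled on the human ESSDAI: five organ-specific domains
(glandular, lymphadenopathy, renal, peripheral and central nervous system)
each carry a fixed weight, and the per-mouse total is the weighted sum,
ranging 0–65.

Functional-test domains are graded 0–3 against the *premorbid* population:
the 95% confidence interval of the pooled pre-immunisation mean defines
"no activity" (grade 0), and the bands beyond the severity-side CI limit —
shifted by 15% and 30% of the premorbid mean — define grades 1, 2 and 3.
Severity direction is test-specific: a *low* salivary flow, tear length,
cold-plate count, open-field centre time or sucrose ratio is pathological,
while a *high* Von Frey withdrawal threshold or forced-swim immobility is.

Lymphadenopathy (weight 4) and renal (weight 5) domains use the palpation
and dipstick semi-quantitative scales directly (0–2 and 0–3).

:class:`MussdaiScorer` is the scikit-learn estimator view: ``fit`` calibrates
the grading schemes on the premorbid measurements, ``transform`` scores
end-of-study mice.  The module-level functions are thin wrappers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import CohortDataset, TESTS, TIMEPOINT_DAYS

__all__ = [
    "LOWER_IS_WORSE",
    "HIGHER_IS_WORSE",
    "DIRECTIONS",
    "DOMAINS",
    "MAX_TOTAL",
    "GradingScheme",
    "MussdaiResult",
    "MussdaiScorer",
    "calibrate_schemes",
    "grade",
    "grade_lymphadenopathy",
    "compute_mussdai",
    "summarize_mussdai",
    "schemes_to_frame",
]

LOWER_IS_WORSE = "LOWER_IS_WORSE"
HIGHER_IS_WORSE = "HIGHER_IS_WORSE"

# Fixed severity direction per functional test.
DIRECTIONS = {
    "SFR": LOWER_IS_WORSE,
    "PHENOL_RED": LOWER_IS_WORSE,
    "VON_FREY": HIGHER_IS_WORSE,
    "COLD_PLATE": LOWER_IS_WORSE,
    "OPEN_FIELD_CENTER_PCT": LOWER_IS_WORSE,
    "FORCED_SWIM_IMMOBILITY_PCT": HIGHER_IS_WORSE,
    "SUCROSE_RATIO": LOWER_IS_WORSE,
}

# domain -> (weight, sub-tests, sub-weight); weights split equally over
# sub-tests so each domain's maximum is weight × 3.
DOMAINS = {
    "GLANDULAR": (3, ("SFR", "PHENOL_RED"), 1.5),
    "PNS": (5, ("VON_FREY", "COLD_PLATE"), 2.5),
    "CNS": (6, ("FORCED_SWIM_IMMOBILITY_PCT", "OPEN_FIELD_CENTER_PCT",
                "SUCROSE_RATIO"), 2.0),
}
LYMPH_WEIGHT = 4   # grade range 0–2
RENAL_WEIGHT = 5   # grade range 0–3
MAX_TOTAL = 65     # 3·3 + 5·3 + 6·3 + 4·2 + 5·3


@dataclass(frozen=True)
class GradingScheme:
    """Premorbid calibration of one functional test.

    ``e1`` is the severity-side CI95 limit; ``e2``/``e3`` shift it by 15%/30%
    of the premorbid mean further in the severity direction.
    """

    test: str
    premorbid_mean: float
    ci95_low: float
    ci95_high: float
    direction: str

    @property
    def e1(self) -> float:
        return self.ci95_low if self.direction == LOWER_IS_WORSE else self.ci95_high

    @property
    def e2(self) -> float:
        s = -1.0 if self.direction == LOWER_IS_WORSE else 1.0
        return self.e1 + s * 0.15 * self.premorbid_mean

    @property
    def e3(self) -> float:
        s = -1.0 if self.direction == LOWER_IS_WORSE else 1.0
        return self.e1 + s * 0.30 * self.premorbid_mean


def calibrate_schemes(premorbid: pd.DataFrame | dict,
                      ci_method: str = "normal") -> dict[str, GradingScheme]:
    """Calibrate one grading scheme per test from pooled premorbid values.

    Parameters
    ----------
    premorbid
        Either a tidy frame with ``test`` and ``value`` columns (PRE rows of
        the measurements table, both cohorts pooled) or a mapping
        test -> array of values.
    ci_method
        ``"normal"`` uses mean ± 1.96·SD/√n; ``"t"`` the t(n−1) quantile.
    """
    if isinstance(premorbid, pd.DataFrame):
        groups = {t: premorbid.loc[premorbid["test"] == t, "value"].to_numpy(float)
                  for t in premorbid["test"].unique()}
    else:
        groups = {t: np.asarray(v, dtype=float) for t, v in premorbid.items()}
    missing = [t for t in TESTS if t not in groups or len(groups[t]) == 0]
    if missing:
        raise ValueError(f"missing premorbid data for test(s): {missing}")

    schemes = {}
    for test in TESTS:
        vals = groups[test]
        if len(vals) < 2:
            raise ValueError(f"{test}: need ≥ 2 premorbid values to calibrate")
        n = len(vals)
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1)) / math.sqrt(n)
        if ci_method == "normal":
            q = 1.959963984540054  # Φ⁻¹(0.975)
        elif ci_method == "t":
            q = float(sps.t.ppf(0.975, df=n - 1))
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
        half = q * sem
        schemes[test] = GradingScheme(test, mean, mean - half, mean + half,
                                      DIRECTIONS[test])
    return schemes


def grade(value: float, scheme: GradingScheme) -> int:
    """Grade a single end-of-study value 0–3 against its premorbid scheme.

    Grade 0 covers the CI95 (closed) and anything beyond it on the healthy
    side.  Past the severity-side limit, bands are closed at the edge nearer
    the premorbid mean: grade 1 on (e2, e1), grade 2 on [e3→e2] closed at e2,
    grade 3 at and beyond e3.
    """
    if not np.isfinite(value):
        raise ValueError(f"{scheme.test}: non-finite value {value!r}")
    e1, e2, e3 = scheme.e1, scheme.e2, scheme.e3
    if scheme.direction == LOWER_IS_WORSE:
        if value >= scheme.ci95_low:
            return 0
        if value > e2:
            return 1
        if value > e3:
            return 2
        return 3
    else:
        if value <= scheme.ci95_high:
            return 0
        if value < e2:
            return 1
        if value < e3:
            return 2
        return 3


def grade_lymphadenopathy(site_grades: dict, rule: str = "max") -> int:
    """Aggregate per-site palpation grades (0–2) into the domain grade.

    The four measured areas are cervical, axillary, brachial and inguinal;
    the default takes the worst finding (ESSDAI-style), with ``sum``
    (capped at 2) and ``mean`` (rounded) as alternatives.
    """
    if not site_grades:
        raise ValueError("no lymph node sites graded")
    levels = [int(v) for v in site_grades.values()]
    if any(v not in (0, 1, 2) for v in levels):
        raise ValueError("lymph node grades must be in {0, 1, 2}")
    if rule == "max":
        return max(levels)
    if rule == "sum":
        return min(2, sum(levels))
    if rule == "mean":
        return int(round(float(np.mean(levels))))
    raise ValueError(f"unknown lymph aggregation rule {rule!r}")


@dataclass
class MussdaiResult:
    mouse_id: str
    test_grades: dict
    domain_scores: dict
    total: float | None
    missing_domains: list

    @property
    def complete(self) -> bool:
        return not self.missing_domains


def compute_mussdai(values: dict, schemes: dict[str, GradingScheme],
                    lymph_grade: int | None, proteinuria_grade: int | None,
                    mouse_id: str = "") -> MussdaiResult:
    """Score one mouse from its final-timepoint test values and grades.

    ``values`` maps functional test name -> end-of-study value.  A missing
    sub-test, lymph or dipstick grade leaves the affected domain in
    ``missing_domains`` and the total absent.
    """
    test_grades: dict = {}
    domain_scores: dict = {}
    missing: list = []

    for domain, (_w, subtests, subw) in DOMAINS.items():
        score = 0.0
        ok = True
        for test in subtests:
            v = values.get(test)
            if v is None or (isinstance(v, float) and not np.isfinite(v)):
                ok = False
                continue
            g = grade(float(v), schemes[test])
            test_grades[test] = g
            score += subw * g
        if ok:
            domain_scores[domain] = score
        else:
            missing.append(domain)

    if lymph_grade is None:
        missing.append("LYMPHADENOPATHY")
    else:
        if lymph_grade not in (0, 1, 2):
            raise ValueError("lymphadenopathy grade must be in {0, 1, 2}")
        domain_scores["LYMPHADENOPATHY"] = LYMPH_WEIGHT * lymph_grade
    if proteinuria_grade is None:
        missing.append("RENAL")
    else:
        if proteinuria_grade not in (0, 1, 2, 3):
            raise ValueError("proteinuria grade must be in {0, 1, 2, 3}")
        domain_scores["RENAL"] = RENAL_WEIGHT * proteinuria_grade

    total = float(sum(domain_scores.values())) if not missing else None
    return MussdaiResult(mouse_id, test_grades, domain_scores, total, missing)


class MussdaiScorer(TransformerMixin, BaseEstimator):
    """Calibrate MuSSDAI grading on the premorbid population and score mice.

    Parameters
    ----------
    ci_method : {"normal", "t"}, default="normal"
        CI95 of the premorbid mean: normal (±1.96·SEM) or Student-t quantile.
    lymph_rule : {"max", "sum", "mean"}, default="max"
        Aggregation of the four lymph node site grades.
    final_timepoint : str, default="WK16"
        Timepoint slot whose measurements are scored.

    Attributes
    ----------
    schemes_ : dict[str, GradingScheme]
        Per-test calibration (premorbid mean, CI95, severity direction).
    n_premorbid_ : int
        Number of premorbid mice pooled into the calibration.
    """

    def __init__(self, ci_method: str = "normal", lymph_rule: str = "max",
                 final_timepoint: str = "WK16"):
        self.ci_method = ci_method
        self.lymph_rule = lymph_rule
        self.final_timepoint = final_timepoint

    def fit(self, X, y=None):
        """Calibrate schemes from PRE-timepoint measurements.

        ``X`` may be a :class:`~mussdai.cohort.CohortDataset` or a tidy frame
        with ``test``/``value`` columns (premorbid rows only).
        """
        if isinstance(X, CohortDataset):
            pre = X.measurements[X.measurements["timepoint"] == "PRE"]
            self.n_premorbid_ = pre["mouse_id"].nunique()
        else:
            pre = X
            self.n_premorbid_ = (pre["mouse_id"].nunique()
                                 if "mouse_id" in pre.columns else len(pre))
        self.schemes_ = calibrate_schemes(pre[["test", "value"]],
                                          ci_method=self.ci_method)
        return self

    def transform(self, X: CohortDataset) -> pd.DataFrame:
        """Score every eligible mouse at the final timepoint.

        Mice dead before the final test day are excluded (the index is an
        end-of-study snapshot of survivors).  Returns one row per mouse with
        every test grade, domain score, the total and an ``incomplete`` flag.
        """
        if not hasattr(self, "schemes_"):
            raise ValueError("MussdaiScorer is not fitted; call fit() first")
        if not isinstance(X, CohortDataset):
            raise TypeError("transform expects a CohortDataset")
        final_day = TIMEPOINT_DAYS[self.final_timepoint]
        meas = X.measurements
        meas = meas[meas["timepoint"] == self.final_timepoint]
        grades = X.grades

        rows = []
        for _, mouse in X.mice.iterrows():
            mid = mouse["mouse_id"]
            dd = mouse.get("death_day")
            if pd.notna(dd) and float(dd) < final_day:
                continue
            sub = meas[meas["mouse_id"] == mid]
            values = dict(zip(sub["test"], sub["value"]))

            g = grades[grades["mouse_id"] == mid]
            lymph = g[g["kind"] == "LYMPH_NODE"]
            lymph_grade = None
            if len(lymph):
                last_week = lymph["week"].max()
                lw = lymph[lymph["week"] == last_week]
                lymph_grade = grade_lymphadenopathy(
                    dict(zip(lw["site"], lw["level"])), rule=self.lymph_rule)
            prot = g[g["kind"] == "PROTEINURIA"]
            prot_grade = None
            if len(prot):
                prot_grade = int(prot.loc[prot["week"].idxmax(), "level"])

            res = compute_mussdai(values, self.schemes_, lymph_grade,
                                  prot_grade, mouse_id=mid)
            row = {"mouse_id": mid, "cohort": mouse["cohort"],
                   "group": mouse["group"]}
            for t in TESTS:
                row[f"grade_{t}"] = res.test_grades.get(t)
            for d in list(DOMAINS) + ["LYMPHADENOPATHY", "RENAL"]:
                row[f"score_{d}"] = res.domain_scores.get(d)
            row["total"] = res.total
            row["incomplete"] = not res.complete
            rows.append(row)
        return pd.DataFrame(rows)


def summarize_mussdai(scores: pd.DataFrame) -> pd.DataFrame:
    """Group means ± SEM of the index plus treated-vs-pooled-controls tests.

    One row per cohort: control and treated n/mean/SEM and the Mann-Whitney
    two-sided p (absent when a side is empty).  Incomplete mice are dropped.
    """
    from .stats import compare_treated_vs_controls

    ok = scores[~scores["incomplete"] & scores["total"].notna()]
    rows = []
    for cohort, sub in ok.groupby("cohort"):
        by_group = {g: grp["total"].to_numpy(float)
                    for g, grp in sub.groupby("group")}
        comp = compare_treated_vs_controls(by_group, endpoint="MuSSDAI")
        rows.append({
            "cohort": cohort,
            "n_control": comp.n[0], "mean_control": comp.mean[0],
            "sem_control": comp.sem[0],
            "n_treated": comp.n[1], "mean_treated": comp.mean[1],
            "sem_treated": comp.sem[1],
            "statistic": comp.statistic, "p_value": comp.p_value,
        })
    return pd.DataFrame(rows)


def schemes_to_frame(schemes: dict[str, GradingScheme]) -> pd.DataFrame:
    """Persistable audit table of calibrated schemes and their bin edges."""
    return pd.DataFrame([
        {"test": s.test, "premorbid_mean": s.premorbid_mean,
         "ci95_low": s.ci95_low, "ci95_high": s.ci95_high,
         "direction": s.direction, "e1": s.e1, "e2": s.e2, "e3": s.e3}
        for s in schemes.values()
    ])
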