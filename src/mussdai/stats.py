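"""Group-comparison statistics and report assembly for the trial.

Primary comparisons are nonparametric, mirroring small-group preclinical
practice: treated (IFN-K) versus pooled controls (NT+PBS+KLH within cohort)
by the two-sided Mann-Whitney U test; the four groups jointly by
Kruskal-Wallis followed by Dunn's mean-rank post-hoc tests; and
proteinuria-free survival by Kaplan-Meier curves with log-rank tests.

The Mann-Whitney p-value is exact — enumerated over all index subsets with
midranks for ties — whenever n1+n2 ≤ 20, and a tie-corrected,
continuity-corrected normal approximation beyond.  Dunn's test is the
standard mean-rank z with tie correction (two-sided normal p, optional
family-wise adjustment, off by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import (CONTROL_GROUPS, PROTEINURIA_WEEKS, STUDY_END_DAY,
                     TREATED_GROUP, CohortDataset)

__all__ = [
    "GroupComparison",
    "SurvivalAnalysis",
    "mann_whitney",
    "compare_treated_vs_controls",
    "kruskal_dunn",
    "proteinuria_free_survival",
    "build_report",
]


@dataclass
class GroupComparison:
    endpoint: str
    groups: tuple
    n: tuple
    mean: tuple
    sem: tuple
    statistic: float | None
    p_value: float | None
    method: str
    timepoint: str | None = None


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _tie_term(pooled: np.ndarray) -> float:
    """Σ(t³ − t) over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def mann_whitney(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first sample, p).

    ``method="exact"`` (automatic for n1+n2 ≤ 20) enumerates all
    C(n1+n2, n1) midrank assignments; the two-sided p is the probability of
    a U at least as far from its null mean n1·n2/2 as observed, which handles
    ties exactly (identical samples give p = 1).  Larger layouts use the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0

    if method == "auto":
        method = "exact" if n1 + n2 <= 20 else "normal"
    if method == "exact":
        n = n1 + n2
        dev = abs(u1 - mu)
        hits = total = 0
        offset = n1 * (n1 + 1) / 2.0
        for idx in combinations(range(n), n1):
            u = ranks[list(idx)].sum() - offset
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
        p = hits / total
    elif method == "normal":
        n = n1 + n2
        tie = _tie_term(pooled)
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
        if sigma2 <= 0:
            return u1, 1.0  # all values tied
        z = (abs(u1 - mu) - 0.5) / math.sqrt(sigma2)
        z = max(z, 0.0)
        p = 2.0 * float(sps.norm.sf(z))
    else:
        raise ValueError(f"unknown method {method!r}")
    return u1, min(max(p, np.nextafter(0, 1)), 1.0)


def _summary(vals: np.ndarray) -> tuple[int, float, float]:
    n = len(vals)
    mean = float(vals.mean()) if n else math.nan
    sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
    return n, mean, sem


def compare_treated_vs_controls(values_by_group: dict, endpoint: str = "",
                                treated: str = TREATED_GROUP,
                                controls=CONTROL_GROUPS,
                                timepoint: str | None = None,
                                method: str = "auto") -> GroupComparison:
    """Pooled-controls vs treated Mann-Whitney with per-side mean ± SEM.

    With only one side present, the summary is returned without a test
    (statistic and p absent).
    """
    ctrl = np.concatenate([np.asarray(values_by_group.get(g, []), dtype=float)
                           for g in controls]) if values_by_group else np.array([])
    trt = np.asarray(values_by_group.get(treated, []), dtype=float)
    if len(ctrl) == 0 and len(trt) == 0:
        raise ValueError("no data in either side")
    nc, mc, sc = _summary(ctrl)
    nt, mt, st = _summary(trt)
    stat = p = None
    if nc and nt:
        stat, p = mann_whitney(ctrl, trt, method=method)
    return GroupComparison(endpoint, ("controls", treated), (nc, nt),
                           (mc, mt), (sc, st), stat, p, "MANN_WHITNEY",
                           timepoint)


def kruskal_dunn(values_by_group: dict, endpoint: str = "",
                 treated: str = TREATED_GROUP, adjust: str | None = None
                 ) -> tuple[GroupComparison, list[GroupComparison]]:
    """Kruskal-Wallis omnibus plus Dunn tests of treated vs each other group.

    All-tied data yields H = 0, p = 1 by convention.  ``adjust`` applies a
    family-wise correction to the Dunn p-values ("bonferroni" or "holm",
    default none).
    """
    groups = {g: np.asarray(v, dtype=float)
              for g, v in values_by_group.items() if len(v)}
    if len(groups) < 2:
        raise ValueError("need ≥ 2 non-empty groups")
    labels = sorted(groups)
    samples = [groups[g] for g in labels]
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*samples)
    omnibus = GroupComparison(endpoint, tuple(labels),
                              tuple(len(s) for s in samples),
                              tuple(float(s.mean()) for s in samples),
                              tuple(_summary(s)[2] for s in samples),
                              float(h), float(p), "KRUSKAL_WALLIS")

    # Dunn: mean-rank z with tie correction over the pooled ranking
    ranks = _midranks(pooled)
    n_total = len(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for g, s in zip(labels, samples):
        mean_ranks[g] = float(ranks[start:start + len(s)].mean())
        sizes[g] = len(s)
        start += len(s)
    tie = _tie_term(pooled)
    var_base = n_total * (n_total + 1) / 12.0
    tie_adj = tie / (12.0 * (n_total - 1)) if n_total > 1 else 0.0

    posthoc = []
    others = [g for g in labels if g != treated]
    raw_ps = []
    for g in others:
        if treated not in groups:
            break
        se2 = (var_base - tie_adj) * (1.0 / sizes[g] + 1.0 / sizes[treated])
        if se2 <= 0:
            z, pv = 0.0, 1.0
        else:
            z = (mean_ranks[g] - mean_ranks[treated]) / math.sqrt(se2)
            pv = 2.0 * float(sps.norm.sf(abs(z)))
        raw_ps.append(min(pv, 1.0))
        posthoc.append(GroupComparison(
            endpoint, (g, treated), (sizes[g], sizes[treated]),
            (float(groups[g].mean()), float(groups[treated].mean())),
            (_summary(groups[g])[2], _summary(groups[treated])[2]),
            float(z), min(pv, 1.0), "DUNN"))
    if adjust and posthoc:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(raw_ps, method=adjust)[1]
        for comp, q in zip(posthoc, adj):
            comp.p_value = float(q)
    return omnibus, posthoc


# ---------------------------------------------------------------------------
# survival


@dataclass
class SurvivalAnalysis:
    table: pd.DataFrame          # mouse_id, group, cohort, duration, event
    curves: dict = field(default_factory=dict)  # group -> KM survival frame
    logrank_statistic: float | None = None
    logrank_p: float | None = None


def proteinuria_free_survival(grades: pd.DataFrame, mice: pd.DataFrame,
                              threshold: int = 1,
                              endpoint: str = "COMPOSITE",
                              by: str = "group") -> SurvivalAnalysis:
    """Kaplan-Meier proteinuria-free survival with a log-rank test.

    Onset is the first scheduled dipstick week with grade ≥ ``threshold``
    (0.3 g/l at the default), recorded at that week's day (week × 7).
    ``endpoint`` selects death only, proteinuria onset only, or the composite
    (first of either, the default); event-free mice are censored at day 122
    or at death for the proteinuria-only endpoint.
    """
    if not len(mice):
        raise ValueError("no mice")
    if endpoint not in ("DEATH", "PROTEINURIA_ONSET", "COMPOSITE"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    prot = grades[grades["kind"] == "PROTEINURIA"]
    rows = []
    for _, mouse in mice.iterrows():
        mid = mouse["mouse_id"]
        death = mouse.get("death_day")
        death = float(death) if pd.notna(death) else None
        sub = prot[(prot["mouse_id"] == mid)
                   & (prot["level"] >= threshold)]
        onset = float(sub["week"].min()) * 7.0 if len(sub) else None
        duration, event = STUDY_END_DAY, False
        if endpoint == "DEATH":
            if death is not None:
                duration, event = death, True
        elif endpoint == "PROTEINURIA_ONSET":
            if onset is not None:
                duration, event = onset, True
            elif death is not None:
                duration, event = death, False  # censored at death
        else:  # COMPOSITE
            times = [t for t in (onset, death) if t is not None]
            if times:
                duration, event = min(times), True
        rows.append({"mouse_id": mid, "group": mouse["group"],
                     "cohort": mouse["cohort"], "duration": duration,
                     "event": event})
    table = pd.DataFrame(rows)

    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    curves = {}
    for g, sub in table.groupby(by):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["duration"], sub["event"], label=str(g))
        curves[g] = kmf.survival_function_

    stat = p = None
    if table[by].nunique() >= 2:
        if table["event"].sum() == 0:
            stat, p = 0.0, 1.0  # no events anywhere: curves identical at 1
        else:
            res = multivariate_logrank_test(table["duration"], table[by],
                                            table["event"])
            stat, p = float(res.test_statistic), float(res.p_value)
    return SurvivalAnalysis(table, curves, stat, p)


# ---------------------------------------------------------------------------
# report assembly


def _endpoint_rows(meas: pd.DataFrame, mice: pd.DataFrame) -> pd.DataFrame:
    group_of = mice.set_index("mouse_id")["group"]
    cohort_of = mice.set_index("mouse_id")["cohort"]
    df = meas.copy()
    df["group"] = df["mouse_id"].map(group_of)
    df["cohort"] = df["mouse_id"].map(cohort_of)
    rows = []
    for (cohort, test, tp), sub in df.groupby(["cohort", "test", "timepoint"],
                                              sort=True):
        by_group = {g: grp["value"].to_numpy(float)
                    for g, grp in sub.groupby("group")}
        comp = compare_treated_vs_controls(by_group, endpoint=test,
                                           timepoint=tp)
        row = {"cohort": cohort, "endpoint": test, "timepoint": tp,
               "n_control": comp.n[0], "mean_control": comp.mean[0],
               "sem_control": comp.sem[0], "n_treated": comp.n[1],
               "mean_treated": comp.mean[1], "sem_treated": comp.sem[1],
               "mw_p": comp.p_value}
        if len(by_group) >= 2:
            omni, _ = kruskal_dunn(by_group, endpoint=test)
            row["kw_p"] = omni.p_value
        else:
            row["kw_p"] = None
        rows.append(row)
    return pd.DataFrame(rows)


def build_report(dataset: CohortDataset, out_dir: str | Path | None = None
                 ) -> dict:
    """Assemble per-endpoint summary tables for a full trial dataset.

    Returns a dict of DataFrames (``endpoints``, ``mussdai``,
    ``mussdai_summary``, ``histology``, ``signature``, ``survival``) plus a
    ``warnings`` list naming skipped stages; written as CSVs and a
    ``summary.txt`` when ``out_dir`` is given.  Deterministic: identical
    inputs give byte-identical files.
    """
    from .histology import score_histology
    from .scoring import MussdaiScorer, summarize_mussdai
    from .signature import delta_delta_ct

    tables: dict = {}
    warn: list[str] = []

    if len(dataset.measurements):
        tables["endpoints"] = _endpoint_rows(dataset.measurements, dataset.mice)
        scorer = MussdaiScorer().fit(dataset)
        scores = scorer.transform(dataset)
        tables["mussdai"] = scores.sort_values("mouse_id").reset_index(drop=True)
        if len(scores) and scores["total"].notna().any():
            tables["mussdai_summary"] = summarize_mussdai(scores)
    else:
        warn.append("no measurements: endpoint and MuSSDAI tables skipped")

    if len(dataset.histology):
        hs = score_histology(dataset.histology)
        group_of = dataset.mice.set_index("mouse_id")["group"]
        cohort_of = dataset.mice.set_index("mouse_id")["cohort"]
        hs["group"] = hs["mouse_id"].map(group_of)
        hs["cohort"] = hs["mouse_id"].map(cohort_of)
        tables["histology"] = hs.sort_values(["cohort", "organ", "mouse_id"]
                                             ).reset_index(drop=True)
    else:
        warn.append("no histology: histology table skipped")

    if len(dataset.ct):
        cohort_of = dataset.mice.set_index("mouse_id")["cohort"]
        ct = dataset.ct.copy()
        ct["cohort"] = ct["mouse_id"].map(cohort_of)
        sig = []
        for cohort, sub in ct.groupby("cohort", sort=True):
            res = delta_delta_ct(sub.drop(columns="cohort"))
            res.insert(0, "cohort", cohort)
            sig.append(res)
        tables["signature"] = pd.concat(sig, ignore_index=True)
    else:
        warn.append("no CT data: signature table skipped")

    if len(dataset.curves):
        from .serology import nc50_table, titer_table

        tables["titers"] = titer_table(dataset.curves, "ELISA_IFNA",
                                       od_max_floor=1.0)
        if (dataset.curves["assay"] == "NEUTRALIZATION").any():
            tables["nc50"] = nc50_table(dataset.curves)
    else:
        warn.append("no curves: titer/NC50 tables skipped")

    if len(dataset.grades) or dataset.mice["death_day"].notna().any():
        surv = proteinuria_free_survival(dataset.grades, dataset.mice)
        tables["survival"] = surv.table.sort_values("mouse_id"
                                                    ).reset_index(drop=True)
        tables["survival_logrank_p"] = surv.logrank_p
    else:
        warn.append("no grades or deaths: survival analysis skipped")

    tables["warnings"] = warn
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        lines = ["Trial report", "============"]
        for name, obj in tables.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(out_dir / f"{name}.csv", index=False,
                           lineterminator="\n", float_format="%.10g")
                lines.append(f"{name}: {len(obj)} rows -> {name}.csv")
            elif name == "survival_logrank_p" and obj is not None:
                lines.append(f"proteinuria-free survival log-rank p = {obj:.4g}")
        for w in warn:
            lines.append(f"WARNING: {w}")
        (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    return tables
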