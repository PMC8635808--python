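"""Seeded synthetic-cohort generator emulating the trial design.

The generator reproduces the study template — two adjuvant cohorts (SWE01,
ISA51) of 26 female MRL/lpr mice, four parallel groups (NT n=6, PBS n=6,
KLH n=7, IFN-K n=7), a 122-day follow-up with the behavioural battery at
−2/+8/+16 weeks (sucrose on its own −1/+9/+17-week clock) — and emits a
fully validated :class:`~mussdai.cohort.CohortDataset`.

It is phenomenological, not mechanistic: premorbid values are drawn from one
shared distribution for all groups; follow-up values add a configurable
per-(test, group, timepoint) shift plus Gaussian noise on the native scale,
truncated to each test's legal range (counts rounded to integers).  Assay
curves are monotone sigmoids in log dilution whose half-maximal response sits
at the configured titer/NC50; qPCR CTs are Gaussian about a per-group
ΔCT-shifted mean; gland foci are Poisson with rate = intensity × section
area and log-normal section areas.

Default effect magnitudes are set from the SWE01 cohort's printed group
means so the defaults are *plausible*, but they are configuration, not
ground truth.  Same seed ⇒ identical dataset.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (CohortDataset, COHORTS, GROUPS, LYMPH_SITES,
                     PROTEINURIA_WEEKS, STUDY_END_DAY, SUCROSE_DAYS, TESTS,
                     TIMEPOINT_DAYS, TREATED_GROUP, validate_dataset)

__all__ = ["GeneratorConfig", "generate_cohorts", "generate_dilution_curve"]

# -- defaults ---------------------------------------------------------------

DEFAULT_GROUP_SIZES = {"NT": 6, "PBS": 6, "KLH": 7, "IFN_K": 7}

# premorbid (pre-immunisation) population per test: (mean, SD), native units
DEFAULT_PREMORBID = {
    "SFR": (4.5, 0.8),                    # ml of saliva / g body weight
    "PHENOL_RED": (4.0, 0.8),             # mm of wetted thread
    "VON_FREY": (0.02, 0.008),            # g force at paw withdrawal
    "COLD_PLATE": (9.0, 1.5),             # paw lifts / 5 min
    "OPEN_FIELD_CENTER_PCT": (20.0, 5.0),  # % time in centre zone
    "FORCED_SWIM_IMMOBILITY_PCT": (40.0, 8.0),  # % time immobile
    "SUCROSE_RATIO": (2.0, 0.3),          # sucrose/water intake ratio
}

# per-(test, group-class, timepoint) shifts added to the premorbid mean;
# magnitudes follow the SWE01 cohort's printed group means.  Glandular and
# PNS endpoints separate treated from controls; CNS endpoints and sucrose
# worsen equally in all groups (no treatment effect was seen there).
DEFAULT_EFFECTS = {
    "SFR": {"control": {"WK8": -2.5, "WK16": -2.2},
            "treated": {"WK8": -1.1, "WK16": -0.5}},
    "PHENOL_RED": {"control": {"WK8": -2.7, "WK16": -3.2},
                   "treated": {"WK8": -0.7, "WK16": -1.4}},
    "VON_FREY": {"control": {"WK8": 0.13, "WK16": 0.87},
                 "treated": {"WK8": 0.01, "WK16": 0.17}},
    "COLD_PLATE": {"control": {"WK8": -5.3, "WK16": -4.6},
                   "treated": {"WK8": -0.3, "WK16": 0.1}},
    "OPEN_FIELD_CENTER_PCT": {"control": {"WK8": -8.0, "WK16": -8.0},
                              "treated": {"WK8": -8.0, "WK16": -8.0}},
    "FORCED_SWIM_IMMOBILITY_PCT": {"control": {"WK8": 12.0, "WK16": 12.0},
                                   "treated": {"WK8": 12.0, "WK16": 12.0}},
    "SUCROSE_RATIO": {"control": {"WK8": -0.5, "WK16": -0.5},
                      "treated": {"WK8": -0.5, "WK16": -0.5}},
}

BLEED_DAYS = (-11, 38, 66, 94, 122)

# geometric-mean endpoint titers per group per bleed day (reciprocal
# dilutions); 30 is far below the lowest tested dilution, i.e. seronegative
DEFAULT_ELISA_IFNA_TITERS = {
    "NT": {d: 30.0 for d in BLEED_DAYS},
    "PBS": {d: 30.0 for d in BLEED_DAYS},
    "KLH": {-11: 30.0, 38: 30.0, 66: 30.0, 94: 1682.0, 122: 1643.0},
    "IFN_K": {-11: 30.0, 38: 27172.0, 66: 25631.0, 94: 25386.0, 122: 16313.0},
}
DEFAULT_ELISA_KLH_TITERS = {
    "NT": {d: 30.0 for d in BLEED_DAYS},
    "PBS": {d: 30.0 for d in BLEED_DAYS},
    "KLH": {-11: 30.0, 38: 20000.0, 66: 20000.0, 94: 20000.0, 122: 20000.0},
    "IFN_K": {-11: 30.0, 38: 20000.0, 66: 20000.0, 94: 20000.0, 122: 20000.0},
}
DEFAULT_NC50 = {
    "NT": {d: 2.0 for d in BLEED_DAYS},
    "PBS": {d: 2.0 for d in BLEED_DAYS},
    "KLH": {d: 2.0 for d in BLEED_DAYS},
    "IFN_K": {-11: 2.0, 38: 287.0, 66: 2226.0, 94: 2168.0, 122: 2363.0},
}

ELISA_DILUTIONS = tuple(100.0 * 2 ** k for k in range(12))   # 100 .. 204800
NEUT_DILUTIONS = tuple(20.0 * 2 ** k for k in range(10))     # 20 .. 10240

# interferon-response panel: gene -> (baseline CT in controls, ΔCT shift in
# the treated group; positive shift = fewer transcripts = downregulated).
# Shifts of the named classical IFN-inducible genes follow the printed
# log2 fold changes; Ifna4 is the stable (reference) gene; Ifnb1 sits below
# the 2-fold cutoff.
DEFAULT_GENE_PANEL = {
    "Ifna4": (24.0, 0.0),
    "Mx1": (22.0, 6.9), "Cxcl10": (23.0, 6.62), "Isg15": (21.0, 6.27),
    "Ccl2": (24.0, 6.02), "Stat1": (22.5, 5.57), "Oas1a": (23.5, 5.54),
    "Tlr7": (25.0, 5.4), "Irf7": (22.0, 4.8), "Ifit1": (21.5, 4.5),
    "Ifit3": (22.5, 4.2), "Usp18": (24.5, 3.9), "Oasl1": (25.5, 3.6),
    "Ifi27": (26.0, 3.3), "Isg20": (24.0, 3.0), "Stat2": (23.0, 2.8),
    "Ifitm3": (20.5, 2.6), "Bst2": (21.0, 2.4), "Ifih1": (25.0, 2.2),
    "Ddx58": (24.5, 2.1), "Ifnb1": (28.0, 0.5),
}

DEFAULT_FOCUS_INTENSITY = {   # expected foci per mm² of gland
    "SMG": {"control": 0.85, "treated": 0.22},
    "LG": {"control": 2.90, "treated": 0.44},
}
DEFAULT_BAFF_SPOTS = {"KLH": 27.3, "IFN_K": 18.5}  # mean spots per ×40 field

DEFAULT_LYMPH_PROBS = {  # P(site grade = 0,1,2)
    "control": (0.2, 0.4, 0.4),
    "treated": (0.5, 0.4, 0.1),
}
# proteinuria: P(onset during follow-up) and onset-week distribution; the
# trial found no group difference, so the default is group-independent
DEFAULT_PROTEINURIA = {
    "onset_prob": {"control": 0.6, "treated": 0.6},
    "onset_weeks": (6, 9, 12, 16),
    "onset_week_probs": (0.15, 0.25, 0.3, 0.3),
}


def _cls(group: str) -> str:
    return "treated" if group == TREATED_GROUP else "control"


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic trial; defaults emulate the study design.

    ``effects``/``lymph_probs``/... may be keyed either by group name
    (NT/PBS/KLH/IFN_K) or by class ("control"/"treated"); a group-name key
    wins.  ``mouse_sd_frac`` adds an optional per-mouse random intercept
    (fraction of each test's SD; default off, longitudinal correlation is
    not described for the design being emulated).
    """

    seed: int = 0
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    premorbid: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_PREMORBID))
    effects: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_EFFECTS))
    noise_sd: dict | None = None          # per test; None -> premorbid SDs
    mouse_sd_frac: float = 0.0
    # assay curves
    top_od: float = 2.5
    slope: float = 2.0
    od_noise_sd: float = 0.05
    titer_scatter_log10: float = 0.15     # per-mouse lognormal scatter
    n_replicates: int = 2
    elisa_dilutions: tuple = ELISA_DILUTIONS
    neut_dilutions: tuple = NEUT_DILUTIONS
    elisa_ifna_titers: dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_ELISA_IFNA_TITERS))
    elisa_klh_titers: dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_ELISA_KLH_TITERS))
    nc50: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_NC50))
    cells_only_response: float = 1.2
    virus_only_response: float = 0.2
    # qPCR signature
    gene_panel: dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_GENE_PANEL))
    ct_replicate_sd: float = 0.2
    ct_sample_offset_sd: float = 0.3      # per-sample RNA-input offset
    ct_replicates: int = 2
    # histology
    focus_intensity: dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_FOCUS_INTENSITY))
    section_range: tuple = (2, 6)
    area_log_mean: float = 0.693          # log(2 mm²)
    area_log_sd: float = 0.3
    vessel_mean: float = 8.0
    vessel_infiltration_prob: float = 0.25
    bronchiole_mean: float = 6.0
    bronchiole_infiltration_prob: float = 0.2
    baff_spots: dict = field(default_factory=lambda: dict(DEFAULT_BAFF_SPOTS))
    # grades
    lymph_probs: dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_LYMPH_PROBS))
    proteinuria: dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_PROTEINURIA))
    # dropout (per-day death hazard per group/class; 0 = all reach day 122)
    dropout_hazard: dict = field(
        default_factory=lambda: {"control": 0.0, "treated": 0.0})
    # which tables to generate
    include_measurements: bool = True
    include_grades: bool = True
    include_curves: bool = True
    include_ct: bool = True
    include_histology: bool = True

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be ≥ 1")
        for test, (_m, sd) in self.premorbid.items():
            if sd < 0:
                raise ValueError(f"{test}: premorbid SD must be ≥ 0")
        if self.noise_sd is not None and any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise SDs must be ≥ 0")
        for probs in self.lymph_probs.values():
            if not np.isclose(sum(probs), 1.0):
                raise ValueError("lymph grade probabilities must sum to 1")
        for p in self.proteinuria["onset_prob"].values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("onset probabilities must be in [0, 1]")

    @classmethod
    def null(cls, **overrides) -> "GeneratorConfig":
        """A no-effect configuration: every group shares one distribution.

        Zeroes the measurement shifts and equalises grades, assays, the gene
        panel and histology across groups, for type-I-error calibration.
        """
        effects = {t: {"control": {"WK8": 0.0, "WK16": 0.0},
                       "treated": {"WK8": 0.0, "WK16": 0.0}}
                   for t in TESTS}
        null_titers = {g: {d: 30.0 for d in BLEED_DAYS} for g in GROUPS}
        null_nc50 = {g: {d: 2.0 for d in BLEED_DAYS} for g in GROUPS}
        panel = {g: (ct, 0.0) for g, (ct, _s) in DEFAULT_GENE_PANEL.items()}
        defaults = dict(
            effects=effects,
            elisa_ifna_titers=null_titers,
            elisa_klh_titers=copy.deepcopy(null_titers),
            nc50=null_nc50,
            gene_panel=panel,
            focus_intensity={"SMG": {"control": 0.85, "treated": 0.85},
                             "LG": {"control": 2.90, "treated": 2.90}},
            baff_spots={"KLH": 20.0, "IFN_K": 20.0},
            lymph_probs={"control": (0.4, 0.4, 0.2),
                         "treated": (0.4, 0.4, 0.2)},
        )
        defaults.update(overrides)
        return cls(**defaults)

    def _group_param(self, mapping: dict, group: str):
        if group in mapping:
            return mapping[group]
        return mapping[_cls(group)]

    def noise_for(self, test: str) -> float:
        if self.noise_sd is not None and test in self.noise_sd:
            return float(self.noise_sd[test])
        return float(self.premorbid[test][1])

    # -- (de)serialisation for the CLI config file -------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = copy.deepcopy(d)
        for key in ("premorbid", "section_range", "elisa_dilutions",
                    "neut_dilutions"):
            if key in d and isinstance(d[key], (list, tuple)):
                d[key] = tuple(d[key])
        if "premorbid" in d and isinstance(d["premorbid"], dict):
            d["premorbid"] = {k: tuple(v) for k, v in d["premorbid"].items()}
        if "gene_panel" in d:
            d["gene_panel"] = {k: tuple(v) for k, v in d["gene_panel"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# curve synthesis


def _sigmoid_fraction(dilutions: np.ndarray, location: float,
                      slope: float) -> np.ndarray:
    """Monotone-decreasing sigmoid in log dilution, = 1/2 at ``location``."""
    return 1.0 / (1.0 + (dilutions / location) ** slope)


def generate_dilution_curve(assay: str, true_value: float, noise_sd: float,
                            dilutions, rng=None, *, mouse_id: str = "m",
                            day: int = 0, top_od: float = 2.5,
                            slope: float = 2.0, n_replicates: int = 2,
                            cells_only: float = 1.2,
                            virus_only: float = 0.2) -> pd.DataFrame:
    """Synthesise one serial-dilution curve as tidy rows.

    The noiseless ELISA response is ``top_od`` × a sigmoid in log reciprocal
    dilution that crosses half its plateau exactly at ``true_value``; the
    neutralization response interpolates between the virus-only and
    cells-only controls with the 50% point at ``true_value``.  Gaussian noise
    (SD ``noise_sd``) is added per replicate well and responses are floored
    at 0.
    """
    dil = np.asarray(dilutions, dtype=float)
    if len(dil) < 2 or (np.diff(dil) <= 0).any() or (dil <= 0).any():
        raise ValueError("dilutions must be ≥ 2 strictly increasing positives")
    if true_value <= 0:
        raise ValueError("true titer/NC50 must be > 0")
    rng = np.random.default_rng(0) if rng is None else rng
    frac = _sigmoid_fraction(dil, true_value, slope)
    if assay in ("ELISA_IFNA", "ELISA_KLH"):
        clean = top_od * frac
        cells = virus = np.nan
    elif assay == "NEUTRALIZATION":
        clean = virus_only + frac * (cells_only - virus_only)
        cells, virus = cells_only, virus_only
    else:
        raise ValueError(f"unknown assay {assay!r}")
    rows = []
    for d, mu in zip(dil, clean):
        for rep in range(1, n_replicates + 1):
            resp = mu + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"mouse_id": mouse_id, "assay": assay, "day": day,
                         "reciprocal_dilution": d, "replicate": rep,
                         "response": max(0.0, float(resp)),
                         "cells_only_response": cells,
                         "virus_only_response": virus})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort synthesis

_ROUND_TESTS = {"COLD_PLATE"}
_CLIP = {
    "SFR": (0.0, None), "PHENOL_RED": (0.0, None), "VON_FREY": (0.008, 1.0),
    "COLD_PLATE": (0.0, None), "OPEN_FIELD_CENTER_PCT": (0.0, 100.0),
    "FORCED_SWIM_IMMOBILITY_PCT": (0.0, 100.0), "SUCROSE_RATIO": (0.0, None),
}


def _truncate(test: str, value: float) -> float:
    lo, hi = _CLIP[test]
    v = min(value, hi) if hi is not None else value
    v = max(v, lo)
    if test in _ROUND_TESTS:
        v = float(round(v))
    return v


def generate_cohorts(config: GeneratorConfig | None = None,
                     validate: bool = True) -> CohortDataset:
    """Generate the full two-cohort trial dataset from a seeded config.

    The same seed always yields the identical dataset (single
    ``numpy.random.default_rng`` stream consumed in a fixed order).  The
    output passes the cohort data-model validation.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)

    mice_rows, meas_rows, grade_rows = [], [], []
    curve_frames, ct_rows, hist_rows = [], [], []

    for cohort in COHORTS:
        for group in GROUPS:
            n = int(cfg.group_sizes[group])
            for i in range(1, n + 1):
                mid = f"{cohort}-{group}-{i:02d}"
                cls = _cls(group)

                # death (default hazard 0: everyone reaches day 122)
                hazard = float(cfg._group_param(cfg.dropout_hazard, group))
                death_day = None
                if hazard > 0:
                    t = rng.exponential(1.0 / hazard)
                    if t <= STUDY_END_DAY:
                        death_day = int(max(1.0, np.ceil(t)))
                mice_rows.append({
                    "mouse_id": mid, "cohort": cohort, "group": group,
                    "alive_at_end": death_day is None,
                    "death_day": death_day,
                })

                # per-mouse random intercept (off by default)
                intercepts = {}
                for test in TESTS:
                    sd = cfg.premorbid[test][1] * cfg.mouse_sd_frac
                    intercepts[test] = rng.normal(0.0, sd) if sd > 0 else 0.0

                if cfg.include_measurements:
                    for test in TESTS:
                        mean, pre_sd = cfg.premorbid[test]
                        eff = cfg._group_param(cfg.effects[test], group)
                        days = SUCROSE_DAYS if test == "SUCROSE_RATIO" \
                            else TIMEPOINT_DAYS
                        for tp in ("PRE", "WK8", "WK16"):
                            day = days[tp]
                            if death_day is not None and day > death_day:
                                continue
                            shift = 0.0 if tp == "PRE" else float(eff[tp])
                            sd = pre_sd if tp == "PRE" else cfg.noise_for(test)
                            noise = rng.normal(0.0, sd) if sd > 0 else 0.0
                            value = _truncate(
                                test, mean + shift + intercepts[test] + noise)
                            meas_rows.append({
                                "mouse_id": mid, "test": test,
                                "timepoint": tp, "day": day, "value": value,
                            })

                if cfg.include_grades:
                    probs = cfg._group_param(cfg.lymph_probs, group)
                    if death_day is None or death_day >= 112:
                        for site in LYMPH_SITES:
                            lvl = int(rng.choice(3, p=probs))
                            grade_rows.append({
                                "mouse_id": mid, "kind": "LYMPH_NODE",
                                "week": 16, "site": site, "level": lvl,
                            })
                    p_onset = float(cfg._group_param(
                        cfg.proteinuria["onset_prob"], group))
                    onset = None
                    if p_onset > 0 and rng.uniform() < p_onset:
                        onset = int(rng.choice(
                            cfg.proteinuria["onset_weeks"],
                            p=cfg.proteinuria["onset_week_probs"]))
                    for week in PROTEINURIA_WEEKS:
                        if death_day is not None and week * 7 > death_day:
                            continue
                        if onset is None or week < onset:
                            lvl = 0
                        else:
                            steps = sum(1 for w in PROTEINURIA_WEEKS
                                        if onset <= w <= week)
                            lvl = min(3, steps)
                        grade_rows.append({
                            "mouse_id": mid, "kind": "PROTEINURIA",
                            "week": week, "site": None, "level": lvl,
                        })

                if cfg.include_curves:
                    specs = (
                        ("ELISA_IFNA", cfg.elisa_ifna_titers,
                         cfg.elisa_dilutions),
                        ("ELISA_KLH", cfg.elisa_klh_titers,
                         cfg.elisa_dilutions),
                        ("NEUTRALIZATION", cfg.nc50, cfg.neut_dilutions),
                    )
                    for assay, locs, dils in specs:
                        day_map = cfg._group_param(locs, group)
                        for day in sorted(day_map):
                            if death_day is not None and day > death_day:
                                continue
                            loc = float(day_map[day]) * 10 ** rng.normal(
                                0.0, cfg.titer_scatter_log10)
                            curve_frames.append(generate_dilution_curve(
                                assay, loc, cfg.od_noise_sd, dils, rng,
                                mouse_id=mid, day=int(day),
                                top_od=cfg.top_od, slope=cfg.slope,
                                n_replicates=cfg.n_replicates,
                                cells_only=cfg.cells_only_response,
                                virus_only=cfg.virus_only_response))

                if cfg.include_ct and death_day is None:
                    offset = rng.normal(0.0, cfg.ct_sample_offset_sd) \
                        if cfg.ct_sample_offset_sd > 0 else 0.0
                    # sorted so the RNG stream is independent of dict order
                    for gene in sorted(cfg.gene_panel):
                        baseline, shift = cfg.gene_panel[gene]
                        mu = baseline + offset
                        if group == TREATED_GROUP:
                            mu += shift
                        for rep in range(1, cfg.ct_replicates + 1):
                            ct = mu + (rng.normal(0.0, cfg.ct_replicate_sd)
                                       if cfg.ct_replicate_sd > 0 else 0.0)
                            ct_rows.append({
                                "mouse_id": mid, "group": group,
                                "gene": gene, "replicate": rep,
                                "ct": float(np.clip(ct, 0.0, 45.0)),
                            })

                if cfg.include_histology and death_day is None:
                    lo, hi = cfg.section_range
                    for organ in ("SMG", "LG"):
                        lam = float(cfg._group_param(
                            cfg.focus_intensity[organ], group))
                        n_sec = int(rng.integers(lo, hi + 1))
                        for sec in range(1, n_sec + 1):
                            area = float(rng.lognormal(cfg.area_log_mean,
                                                       cfg.area_log_sd))
                            foci = int(rng.poisson(lam * area))
                            hist_rows.append({
                                "mouse_id": mid, "organ": organ,
                                "section": sec, "focus_count": foci,
                                "section_area_mm2": area,
                            })
                    n_sec = int(rng.integers(lo, hi + 1))
                    for sec in range(1, n_sec + 1):
                        tv = int(rng.poisson(cfg.vessel_mean)) + 2
                        tb = int(rng.poisson(cfg.bronchiole_mean)) + 2
                        hist_rows.append({
                            "mouse_id": mid, "organ": "LUNG", "section": sec,
                            "infiltrated_vessels": int(rng.binomial(
                                tv, cfg.vessel_infiltration_prob)),
                            "total_vessels": tv,
                            "infiltrated_bronchioles": int(rng.binomial(
                                tb, cfg.bronchiole_infiltration_prob)),
                            "total_bronchioles": tb,
                        })
                    if group in cfg.baff_spots:
                        mu = float(cfg.baff_spots[group])
                        for fld in range(1, 4):
                            hist_rows.append({
                                "mouse_id": mid, "organ": "SMG_BAFF",
                                "section": fld,
                                "baff_spots": int(rng.poisson(mu)),
                            })

    empty = CohortDataset()
    ds = CohortDataset(
        mice=pd.DataFrame(mice_rows),
        measurements=(pd.DataFrame(meas_rows) if meas_rows
                      else empty.measurements),
        grades=pd.DataFrame(grade_rows) if grade_rows else empty.grades,
        curves=(pd.concat(curve_frames, ignore_index=True) if curve_frames
                else empty.curves),
        ct=pd.DataFrame(ct_rows) if ct_rows else empty.ct,
        histology=pd.DataFrame(hist_rows) if hist_rows else empty.histology,
    )
    if validate:
        validate_dataset(ds)
    return ds
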