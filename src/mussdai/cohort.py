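"""Trial data model: domain enums, tidy CSV readers/writers and validation.

The trial follows two adjuvant cohorts (SWE01, ISA51) of 26 female MRL/lpr
mice each, randomised to four parallel groups (NT n=6, PBS n=6, KLH n=7,
IFN-K n=7) and followed for 122 days.  All downstream stages (index scoring,
serology, interferon signature, histology, statistics) consume the
:class:`CohortDataset` produced here.

Tables are tidy (long) CSVs, one row per observation; the documented schemas
live in ``docs/schemas.md``.  Timepoints are stored both symbolically
(PRE/WK8/WK16) and as integer study days: the behavioural battery runs at
days −14/56/112, the sucrose-preference test on its own −7/63/119 clock
mapped onto the same three slots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "COHORTS",
    "GROUPS",
    "CONTROL_GROUPS",
    "TREATED_GROUP",
    "TESTS",
    "TIMEPOINTS",
    "TIMEPOINT_DAYS",
    "SUCROSE_DAYS",
    "ASSAYS",
    "GRADE_KINDS",
    "LYMPH_SITES",
    "ORGANS",
    "PROTEINURIA_WEEKS",
    "STUDY_END_DAY",
    "CohortDataset",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "validate_dataset",
]

COHORTS = ("SWE01", "ISA51")
GROUPS = ("NT", "PBS", "KLH", "IFN_K")
CONTROL_GROUPS = ("NT", "PBS", "KLH")
TREATED_GROUP = "IFN_K"

TESTS = (
    "SFR",
    "PHENOL_RED",
    "VON_FREY",
    "COLD_PLATE",
    "OPEN_FIELD_CENTER_PCT",
    "FORCED_SWIM_IMMOBILITY_PCT",
    "SUCROSE_RATIO",
)

TIMEPOINTS = ("PRE", "WK8", "WK16")
# Behavioural clock: 2 weeks before / 8 and 16 weeks after first immunisation.
TIMEPOINT_DAYS = {"PRE": -14, "WK8": 56, "WK16": 112}
# The sucrose test runs one week later (−1/+9/+17 weeks) on the same slots.
SUCROSE_DAYS = {"PRE": -7, "WK8": 63, "WK16": 119}

ASSAYS = ("ELISA_IFNA", "ELISA_KLH", "NEUTRALIZATION")
GRADE_KINDS = ("LYMPH_NODE", "PROTEINURIA")
LYMPH_SITES = ("cervical", "axillary", "brachial", "inguinal")
ORGANS = ("SMG", "LG", "LUNG", "SMG_BAFF")
PROTEINURIA_WEEKS = (0, 3, 6, 9, 12, 16)
STUDY_END_DAY = 122

# Native-unit sanity bounds per behavioural test (min, max); None = unbounded.
_VALUE_BOUNDS = {
    "SFR": (0.0, None),
    "PHENOL_RED": (0.0, None),
    "VON_FREY": (0.008, 1.0),
    "COLD_PLATE": (0.0, None),
    "OPEN_FIELD_CENTER_PCT": (0.0, 100.0),
    "FORCED_SWIM_IMMOBILITY_PCT": (0.0, 100.0),
    "SUCROSE_RATIO": (0.0, None),
}

_FILES = {
    "mice": "mice.csv",
    "measurements": "measurements.csv",
    "grades": "grades.csv",
    "curves": "curves.csv",
    "ct": "ct.csv",
    "histology": "histology.csv",
}

_COLUMNS = {
    "mice": ["mouse_id", "cohort", "group", "alive_at_end", "death_day"],
    "measurements": ["mouse_id", "test", "timepoint", "day", "value"],
    "grades": ["mouse_id", "kind", "week", "site", "level"],
    "curves": [
        "mouse_id", "assay", "day", "reciprocal_dilution", "replicate",
        "response", "cells_only_response", "virus_only_response",
    ],
    "ct": ["mouse_id", "group", "gene", "replicate", "ct"],
    "histology": [
        "mouse_id", "organ", "section", "focus_count", "section_area_mm2",
        "infiltrated_vessels", "total_vessels",
        "infiltrated_bronchioles", "total_bronchioles", "baff_spots",
    ],
}


class CohortValidationError(ValueError):
    """Raised when a dataset violates the trial data model.

    The message names the offending table and, where possible, the row.
    """


def _empty(table: str) -> pd.DataFrame:
    return pd.DataFrame(columns=_COLUMNS[table])


@dataclass
class CohortDataset:
    """All tables of one trial run (both cohorts)."""

    mice: pd.DataFrame = field(default_factory=lambda: _empty("mice"))
    measurements: pd.DataFrame = field(default_factory=lambda: _empty("measurements"))
    grades: pd.DataFrame = field(default_factory=lambda: _empty("grades"))
    curves: pd.DataFrame = field(default_factory=lambda: _empty("curves"))
    ct: pd.DataFrame = field(default_factory=lambda: _empty("ct"))
    histology: pd.DataFrame = field(default_factory=lambda: _empty("histology"))

    def n_mice(self, cohort: str | None = None) -> int:
        m = self.mice
        if cohort is not None:
            m = m[m["cohort"] == cohort]
        return len(m)

    def groups_of(self) -> pd.Series:
        """mouse_id -> group label."""
        return self.mice.set_index("mouse_id")["group"]

    def equals(self, other: "CohortDataset") -> bool:
        for name in _FILES:
            a = _canonical(getattr(self, name), name)
            b = _canonical(getattr(other, name), name)
            if not a.equals(b):
                return False
        return True


def _canonical(df: pd.DataFrame, table: str) -> pd.DataFrame:
    """Column-ordered, row-sorted, dtype-normalised view for comparison/IO."""
    out = df.copy()
    for col in _COLUMNS[table]:
        if col not in out.columns:
            out[col] = np.nan
    out = out[_COLUMNS[table]]
    for col in out.columns:
        try:
            out[col] = pd.to_numeric(out[col]).astype(float)
        except (ValueError, TypeError):
            out[col] = out[col].astype("string")
    sort_cols = [c for c in _COLUMNS[table] if c not in ("value", "response", "ct")]
    out = out.sort_values(sort_cols, kind="mergesort", na_position="last")
    return out.reset_index(drop=True)


def write_cohort(dataset: CohortDataset, directory: str | Path) -> dict[str, Path]:
    """Write every table as a tidy CSV; returns table name -> path.

    Output is deterministic (fixed column order, stable sort), so re-writing
    the same dataset is byte-stable.  Missing optional values are written as
    empty cells.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, fname in _FILES.items():
        path = directory / fname
        df = _canonical(getattr(dataset, name), name)
        df.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")
        paths[name] = path
    return paths


def read_cohort(directory: str | Path, validate: bool = True) -> CohortDataset:
    """Read a dataset written by :func:`write_cohort` and validate it.

    Missing table files are treated as empty tables (a roster-only directory
    is a valid, measurement-free dataset), but ``mice.csv`` must exist.
    """
    directory = Path(directory)
    mice_path = directory / _FILES["mice"]
    if not mice_path.exists():
        raise CohortValidationError(f"{mice_path}: mouse roster file is missing")
    tables = {}
    for name, fname in _FILES.items():
        path = directory / fname
        if path.exists():
            df = pd.read_csv(path, float_precision="round_trip")
            if df.empty and list(df.columns) != _COLUMNS[name]:
                df = _empty(name)
            tables[name] = df
        else:
            tables[name] = _empty(name)
    ds = CohortDataset(**tables)
    if validate:
        validate_dataset(ds)
    return ds


# ---------------------------------------------------------------------------
# validation


def _fail(table: str, msg: str, rows=None) -> None:
    loc = f" (rows {sorted(rows)[:5]})" if rows is not None and len(rows) else ""
    raise CohortValidationError(f"{_FILES[table]}: {msg}{loc}")


def _check_columns(df: pd.DataFrame, table: str) -> None:
    missing = [c for c in _COLUMNS[table] if c not in df.columns]
    if missing:
        _fail(table, f"missing required columns {missing}")


def _check_enum(df: pd.DataFrame, table: str, col: str, allowed, required=True) -> None:
    vals = df[col].dropna() if not required else df[col]
    bad = ~vals.isin(allowed)
    if required:
        bad |= vals.isna()
    if bad.any():
        _fail(table, f"unknown {col} value(s) {sorted(set(vals[bad].astype(str)))}",
              vals.index[bad])


def validate_dataset(ds: CohortDataset) -> None:
    """Check every invariant of the data model; raise on the first violation."""
    for name in _FILES:
        _check_columns(getattr(ds, name), name)

    mice = ds.mice
    _check_enum(mice, "mice", "cohort", COHORTS)
    _check_enum(mice, "mice", "group", GROUPS)
    if mice["mouse_id"].duplicated().any():
        _fail("mice", "duplicate mouse_id",
              mice.index[mice["mouse_id"].duplicated()])
    dd = pd.to_numeric(mice["death_day"], errors="coerce")
    bad = mice["death_day"].notna() & (dd.isna() | (dd < 0) | (dd > STUDY_END_DAY))
    if bad.any():
        _fail("mice", f"death_day outside [0, {STUDY_END_DAY}]", mice.index[bad])
    known = set(mice["mouse_id"])
    death_day = mice.set_index("mouse_id")["death_day"]

    meas = ds.measurements
    if len(meas):
        _check_enum(meas, "measurements", "test", TESTS)
        _check_enum(meas, "measurements", "timepoint", TIMEPOINTS)
        _check_refs(meas, "measurements", known)
        dup = meas.duplicated(subset=["mouse_id", "test", "timepoint"])
        if dup.any():
            _fail("measurements", "duplicate (mouse, test, timepoint) rows",
                  meas.index[dup])
        v = pd.to_numeric(meas["value"], errors="coerce")
        if not np.isfinite(v).all():
            _fail("measurements", "non-finite value", meas.index[~np.isfinite(v)])
        for test, (lo, hi) in _VALUE_BOUNDS.items():
            sel = meas["test"] == test
            bad = sel & ((v < lo) | ((v > hi) if hi is not None else False))
            if bad.any():
                _fail("measurements",
                      f"{test} value outside [{lo}, {hi}]", meas.index[bad])
        # measurements after a mouse's death are impossible
        day = pd.to_numeric(meas["day"], errors="coerce")
        dth = meas["mouse_id"].map(death_day)
        bad = dth.notna() & (day > pd.to_numeric(dth, errors="coerce"))
        if bad.any():
            _fail("measurements", "measurement after death_day", meas.index[bad])

    grades = ds.grades
    if len(grades):
        _check_enum(grades, "grades", "kind", GRADE_KINDS)
        _check_refs(grades, "grades", known)
        lymph = grades["kind"] == "LYMPH_NODE"
        _check_enum(grades.loc[lymph], "grades", "site", LYMPH_SITES)
        lvl = pd.to_numeric(grades["level"], errors="coerce")
        bad = lymph & ~lvl.isin([0, 1, 2])
        if bad.any():
            _fail("grades", "LYMPH_NODE level outside {0,1,2}", grades.index[bad])
        prot = grades["kind"] == "PROTEINURIA"
        bad = prot & ~lvl.isin([0, 1, 2, 3])
        if bad.any():
            _fail("grades", "PROTEINURIA level outside {0,1,2,3}", grades.index[bad])

    curves = ds.curves
    if len(curves):
        _check_enum(curves, "curves", "assay", ASSAYS)
        _check_refs(curves, "curves", known)
        dil = pd.to_numeric(curves["reciprocal_dilution"], errors="coerce")
        if (dil <= 0).any() or dil.isna().any():
            _fail("curves", "reciprocal_dilution must be > 0",
                  curves.index[(dil <= 0) | dil.isna()])
        resp = pd.to_numeric(curves["response"], errors="coerce")
        if (resp < 0).any() or resp.isna().any():
            _fail("curves", "response must be ≥ 0",
                  curves.index[(resp < 0) | resp.isna()])
        for key, sub in curves.groupby(["mouse_id", "assay", "day"]):
            dils = np.sort(sub["reciprocal_dilution"].unique())
            if len(dils) < 2:
                _fail("curves", f"curve {key} has < 2 dilution points")
        neut = curves[curves["assay"] == "NEUTRALIZATION"]
        if len(neut):
            for col in ("cells_only_response", "virus_only_response"):
                if neut[col].isna().any():
                    _fail("curves", f"NEUTRALIZATION rows missing {col}",
                          neut.index[neut[col].isna()])

    ct = ds.ct
    if len(ct):
        _check_refs(ct, "ct", known)
        v = pd.to_numeric(ct["ct"], errors="coerce")
        present = ct["ct"].notna()
        bad = present & (v.isna() | (v < 0) | (v > 45))
        if bad.any():
            _fail("ct", "CT values must be finite cycles in [0, 45]", ct.index[bad])

    hist = ds.histology
    if len(hist):
        _check_enum(hist, "histology", "organ", ORGANS)
        _check_refs(hist, "histology", known)
        for (mouse, organ), sub in hist.groupby(["mouse_id", "organ"]):
            n = len(sub)
            if organ in ("SMG", "LG"):
                if not 2 <= n <= 12:
                    _fail("histology",
                          f"{mouse}/{organ}: {n} sections (expected 2–12, "
                          "2–6 per left/right organ)")
                foci = pd.to_numeric(sub["focus_count"], errors="coerce")
                area = pd.to_numeric(sub["section_area_mm2"], errors="coerce")
                if foci.isna().any() or (foci < 0).any() or \
                        (foci != foci.round()).any():
                    _fail("histology", f"{mouse}/{organ}: focus_count must be "
                          "a non-negative integer")
                if area.isna().any() or (area <= 0).any():
                    _fail("histology", f"{mouse}/{organ}: section_area_mm2 must be > 0")
            elif organ == "LUNG":
                for inf_col, tot_col in (
                    ("infiltrated_vessels", "total_vessels"),
                    ("infiltrated_bronchioles", "total_bronchioles"),
                ):
                    inf = pd.to_numeric(sub[inf_col], errors="coerce")
                    tot = pd.to_numeric(sub[tot_col], errors="coerce")
                    if inf.isna().any() or tot.isna().any() or (inf < 0).any():
                        _fail("histology", f"{mouse}/LUNG: missing or negative "
                              f"{inf_col}/{tot_col}")
                    if (inf > tot).any():
                        _fail("histology",
                              f"{mouse}/LUNG: {inf_col} exceeds {tot_col}")
            elif organ == "SMG_BAFF":
                if n != 3:
                    _fail("histology",
                          f"{mouse}/SMG_BAFF: {n} fields (exactly 3 required)")
                spots = pd.to_numeric(sub["baff_spots"], errors="coerce")
                if spots.isna().any() or (spots < 0).any():
                    _fail("histology", f"{mouse}/SMG_BAFF: baff_spots must be ≥ 0")


def _check_refs(df: pd.DataFrame, table: str, known: set) -> None:
    bad = ~df["mouse_id"].isin(known)
    if bad.any():
        _fail(table, f"unknown mouse_id {sorted(set(df.loc[bad, 'mouse_id']))[:5]}",
              df.index[bad])
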