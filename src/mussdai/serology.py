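"""Serology estimators: endpoint ELISA titers, neutralization NC50, ELISpot
summaries and autoantibody positivity thresholds.

Endpoint titers follow the half-maximal interpolation convention: per serum
and bleed day, duplicate wells are averaged per dilution, OD.max is the
maximum mean OD of the series, and the titer is the reciprocal dilution where
the straight line through the two points bracketing OD.max/2 crosses
OD.max/2.  Serial dilutions are geometric, so the two-point line is drawn on
the log10(reciprocal dilution) axis by default (``interp_axis="linear"``
preserves the literal linear reading).

NC50 is the reciprocal serum dilution giving 50% neutralization of
virus-mediated cell mortality in a cytopathic-effect inhibition bioassay:
neutralization(d) = (response(d) − virus_only) / (cells_only − virus_only),
clamped to [0, 1] for crossing detection, with the 0.5 crossing interpolated
the same way.

Estimates outside the tested dilution range are never extrapolated; they are
reported as censored (``below_range`` / ``above_range``) with the bounding
dilution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DilutionCurve",
    "TiterResult",
    "NC50Result",
    "ElispotResult",
    "compute_titer",
    "compute_nc50",
    "summarize_elispot",
    "autoantibody_threshold",
    "curves_from_frame",
    "titer_table",
    "nc50_table",
]

BELOW_RANGE = "below_range"
ABOVE_RANGE = "above_range"


@dataclass
class DilutionCurve:
    """One serum's serial-dilution series on one bleed day.

    ``points`` maps strictly increasing reciprocal dilutions to ≥1 replicate
    responses each (duplicate wells are the trial's default).  Neutralization
    curves carry the plate controls: untouched cells (``cells_only_response``)
    and virus without serum (``virus_only_response``).
    """

    mouse_id: str
    assay: str
    day: int
    points: list[tuple[float, list[float]]]
    cells_only_response: float | None = None
    virus_only_response: float | None = None

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("a dilution curve needs at least 2 points")
        dils = [d for d, _ in self.points]
        if any(d <= 0 for d in dils):
            raise ValueError("reciprocal dilutions must be > 0")
        if any(b <= a for a, b in zip(dils, dils[1:])):
            raise ValueError("reciprocal dilutions must be strictly increasing")
        if any(len(reps) < 1 for _, reps in self.points):
            raise ValueError("every dilution point needs ≥ 1 replicate")

    @property
    def dilutions(self) -> np.ndarray:
        return np.array([d for d, _ in self.points], dtype=float)

    @property
    def mean_responses(self) -> np.ndarray:
        """Replicates averaged per point (done before any interpolation)."""
        return np.array([float(np.mean(reps)) for _, reps in self.points])


@dataclass
class TiterResult:
    mouse_id: str
    day: int
    titer: float | None
    censored: str | None  # None | below_range | above_range
    od_max: float
    half_max: float


@dataclass
class NC50Result:
    mouse_id: str
    day: int
    nc50: float | None
    censored: str | None
    neutralization: list[float] = field(default_factory=list)


def _interp_crossing(d_lo: float, d_hi: float, y_lo: float, y_hi: float,
                     target: float, axis: str) -> float:
    """Reciprocal dilution where the two-point line crosses ``target``.

    y_lo is the response at the lower dilution (≥ target ≥ y_hi).
    """
    if y_lo == y_hi:
        return d_hi  # flat segment sitting on the target: take the far edge
    t = (y_lo - target) / (y_lo - y_hi)
    if axis == "log":
        return float(10 ** (math.log10(d_lo) + t * (math.log10(d_hi) - math.log10(d_lo))))
    if axis == "linear":
        return float(d_lo + t * (d_hi - d_lo))
    raise ValueError(f"unknown interp_axis {axis!r}")


def compute_titer(curve: DilutionCurve, interp_axis: str = "log",
                  od_max_floor: float | None = None) -> TiterResult:
    """Endpoint titer by two-point interpolation of OD.max/2.

    Replicates are averaged per dilution first.  The bracketing pair is the
    first adjacent pair past the (last occurrence of the) maximum whose means
    straddle OD.max/2; if the series re-crosses the half-maximum further out,
    a warning is emitted and the crossing adjacent to OD.max is used.

    ``od_max_floor`` marks blank-level plates: if every mean OD is below half
    the floor, the serum has no measurable signal and the titer is censored
    ``below_range``.
    """
    means = curve.mean_responses
    dils = curve.dilutions
    od_max = float(means.max())
    half = od_max / 2.0

    if od_max_floor is not None and bool((means < od_max_floor / 2.0).all()):
        return TiterResult(curve.mouse_id, curve.day, None, BELOW_RANGE,
                           od_max, half)

    i_max = int(np.flatnonzero(means == od_max)[-1])
    # downward crossings of the half-max past the maximum; strict on the
    # near side so a point exactly at half-max counts once (t = 1, exact)
    crossings = [
        i for i in range(i_max, len(means) - 1)
        if means[i] > half >= means[i + 1]
    ]
    if not crossings:
        # signal never decays to half-max within the tested range
        return TiterResult(curve.mouse_id, curve.day, None, ABOVE_RANGE,
                           od_max, half)
    if len(crossings) > 1:
        warnings.warn(
            f"{curve.mouse_id} day {curve.day}: non-monotone series crosses "
            "OD.max/2 more than once; using the crossing adjacent to OD.max",
            stacklevel=2,
        )
    i = crossings[0]
    titer = _interp_crossing(dils[i], dils[i + 1], means[i], means[i + 1],
                             half, interp_axis)
    return TiterResult(curve.mouse_id, curve.day, titer, None, od_max, half)


def compute_nc50(curve: DilutionCurve, interp_axis: str = "log") -> NC50Result:
    """50% neutralization capacity of a cytopathic-effect inhibition curve."""
    cells = curve.cells_only_response
    virus = curve.virus_only_response
    if cells is None or virus is None:
        raise ValueError("NC50 requires cells_only and virus_only controls")
    if cells <= virus:
        raise ValueError(
            "degenerate controls: cells_only_response must exceed "
            "virus_only_response"
        )
    means = curve.mean_responses
    frac = (means - virus) / (cells - virus)
    clamped = np.clip(frac, 0.0, 1.0)
    dils = curve.dilutions

    if bool((clamped < 0.5).all()):
        return NC50Result(curve.mouse_id, curve.day, None, BELOW_RANGE,
                          frac.tolist())
    if bool((clamped >= 0.5).all()):
        return NC50Result(curve.mouse_id, curve.day, None, ABOVE_RANGE,
                          frac.tolist())
    # neutralization decays with dilution: first downward 0.5 crossing,
    # strict on the near side so an exact grid-point 0.5 is returned as-is
    for i in range(len(clamped) - 1):
        if clamped[i] > 0.5 >= clamped[i + 1]:
            nc50 = _interp_crossing(dils[i], dils[i + 1], clamped[i],
                                    clamped[i + 1], 0.5, interp_axis)
            return NC50Result(curve.mouse_id, curve.day, nc50, None,
                              frac.tolist())
    # pathological (noise-only) non-monotone curve with no downward crossing:
    # report the last dilution still at ≥ 50% neutralization
    j = int(np.flatnonzero(clamped >= 0.5)[-1])
    return NC50Result(curve.mouse_id, curve.day, float(dils[j]), None,
                      frac.tolist())


# ---------------------------------------------------------------------------
# ELISpot & autoantibodies


@dataclass
class ElispotResult:
    mouse_id: str
    condition: str
    replicates: list[float]
    mean_spots: float
    background_subtracted: float | None


ELISPOT_CONDITIONS = ("NONE", "CONA", "KLH", "IFNA", "IFN_K")


def summarize_elispot(replicates_by_condition: dict[str, list[float]],
                      mouse_id: str = "") -> list[ElispotResult]:
    """Mean spot counts per stimulation condition with background subtraction.

    ``background_subtracted = max(0, mean − mean(NONE))``; without an
    unstimulated (NONE) condition the subtraction is omitted with a warning.
    """
    for cond, reps in replicates_by_condition.items():
        if len(reps) < 1:
            raise ValueError(f"condition {cond}: at least one replicate required")
    background = None
    if "NONE" in replicates_by_condition:
        background = float(np.mean(replicates_by_condition["NONE"]))
    else:
        warnings.warn("no unstimulated (NONE) condition: background "
                      "subtraction omitted", stacklevel=2)
    out = []
    for cond, reps in replicates_by_condition.items():
        mean = float(np.mean(reps))
        sub = max(0.0, mean - background) if background is not None else None
        out.append(ElispotResult(mouse_id, cond, list(map(float, reps)), mean, sub))
    return out


def autoantibody_threshold(control_titers) -> float:
    """Positivity threshold: control mean + 5 sample standard deviations.

    Calibrated on healthy control sera (the trial used 6-month-old C57Bl/6
    mice, n=5); a sample is positive when its titer is strictly greater than
    the threshold.  Sample SD uses the n−1 denominator.
    """
    vals = np.asarray(list(control_titers), dtype=float)
    if len(vals) < 2:
        raise ValueError("at least 2 control titers required")
    return float(vals.mean() + 5.0 * vals.std(ddof=1))


# ---------------------------------------------------------------------------
# table-level drivers


def curves_from_frame(curves: pd.DataFrame, assay: str | None = None
                      ) -> list[DilutionCurve]:
    """Group tidy curve rows into :class:`DilutionCurve` objects."""
    df = curves if assay is None else curves[curves["assay"] == assay]
    out = []
    for (mouse, asy, day), sub in df.groupby(["mouse_id", "assay", "day"],
                                             sort=True):
        pts = [
            (float(dil), [float(r) for r in grp["response"]])
            for dil, grp in sub.groupby("reciprocal_dilution", sort=True)
        ]
        cells = virus = None
        if asy == "NEUTRALIZATION":
            cells = float(sub["cells_only_response"].iloc[0])
            virus = float(sub["virus_only_response"].iloc[0])
        out.append(DilutionCurve(mouse, asy, int(day), pts, cells, virus))
    return out


def titer_table(curves: pd.DataFrame, assay: str = "ELISA_IFNA",
                interp_axis: str = "log",
                od_max_floor: float | None = None) -> pd.DataFrame:
    """Endpoint titers for every (mouse, day) curve of one ELISA assay."""
    rows = []
    for c in curves_from_frame(curves, assay):
        r = compute_titer(c, interp_axis=interp_axis, od_max_floor=od_max_floor)
        rows.append({
            "mouse_id": r.mouse_id, "assay": assay, "day": r.day,
            "titer": r.titer, "censored": r.censored,
            "od_max": r.od_max, "half_max": r.half_max,
        })
    return pd.DataFrame(rows, columns=["mouse_id", "assay", "day", "titer",
                                       "censored", "od_max", "half_max"])


def nc50_table(curves: pd.DataFrame, interp_axis: str = "log") -> pd.DataFrame:
    """NC50 for every (mouse, day) neutralization curve."""
    rows = []
    for c in curves_from_frame(curves, "NEUTRALIZATION"):
        r = compute_nc50(c, interp_axis=interp_axis)
        rows.append({"mouse_id": r.mouse_id, "day": r.day,
                     "nc50": r.nc50, "censored": r.censored})
    return pd.DataFrame(rows, columns=["mouse_id", "day", "nc50", "censored"])
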