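"""Histopathology scores from section-level counts.

Foci (aggregates of ≥50 mononuclear cells, identified upstream on stained
sections) are summarised as the focus score — foci per mm² of gland tissue —
pooled over all examined sections of both left and right organs
(Σ foci / Σ area, unbiased under varying section areas).  Lung involvement is
summarised as perivascular and peribronchiolar infiltration ratios, and local
BAFF production as the mean immunostained spot count over three
non-overlapping ×40 fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FocusScore", "LungScore", "focus_score", "lung_scores",
           "baff_spots", "score_histology"]


@dataclass
class FocusScore:
    mouse_id: str
    organ: str  # SMG or LG
    total_foci: int
    total_area_mm2: float
    score: float  # foci per mm²
    per_section: list[float]


@dataclass
class LungScore:
    mouse_id: str
    perivascular_ratio: float
    peribronchiolar_ratio: float


def focus_score(sections: pd.DataFrame, method: str = "pooled") -> FocusScore:
    """Focus score for one (mouse, organ in {SMG, LG}) block of section rows.

    ``method="pooled"`` (default) computes Σ foci / Σ area; ``"mean"``
    averages the per-section densities instead.
    """
    if not len(sections):
        raise ValueError("no sections")
    foci = sections["focus_count"].to_numpy(float)
    area = sections["section_area_mm2"].to_numpy(float)
    if (area <= 0).any():
        raise ValueError("section areas must be > 0")
    total_area = float(area.sum())
    per_section = (foci / area).tolist()
    if method == "pooled":
        score = float(foci.sum()) / total_area
    elif method == "mean":
        score = float(np.mean(per_section))
    else:
        raise ValueError(f"unknown focus score method {method!r}")
    return FocusScore(str(sections["mouse_id"].iloc[0]),
                      str(sections["organ"].iloc[0]),
                      int(foci.sum()), total_area, score, per_section)


def lung_scores(sections: pd.DataFrame) -> LungScore:
    """Infiltration ratios for one mouse's lung sections, counts pooled."""
    if not len(sections):
        raise ValueError("no sections")
    iv = float(sections["infiltrated_vessels"].sum())
    tv = float(sections["total_vessels"].sum())
    ib = float(sections["infiltrated_bronchioles"].sum())
    tb = float(sections["total_bronchioles"].sum())
    if tv <= 0 or tb <= 0:
        raise ValueError("total vessel/bronchiole counts must be > 0")
    if iv > tv or ib > tb:
        raise ValueError("infiltrated counts exceed totals")
    return LungScore(str(sections["mouse_id"].iloc[0]), iv / tv, ib / tb)


def baff_spots(fields: pd.DataFrame | list) -> float:
    """Mean BAFF-positive spot count over exactly 3 microscope fields."""
    if isinstance(fields, pd.DataFrame):
        counts = fields["baff_spots"].to_numpy(float)
    else:
        counts = np.asarray(fields, dtype=float)
    if len(counts) != 3:
        raise ValueError(f"expected exactly 3 fields, got {len(counts)}")
    if (counts < 0).any():
        raise ValueError("spot counts must be ≥ 0")
    return float(counts.mean())


def score_histology(histology: pd.DataFrame, focus_method: str = "pooled"
                    ) -> pd.DataFrame:
    """One row per (mouse, organ) with its score(s).

    Columns: mouse_id, organ, focus_score, perivascular_ratio,
    peribronchiolar_ratio, baff_mean_spots (only the relevant one filled).
    """
    rows = []
    for (mouse, organ), sub in histology.groupby(["mouse_id", "organ"],
                                                 sort=True):
        row = {"mouse_id": mouse, "organ": organ, "focus_score": np.nan,
               "perivascular_ratio": np.nan, "peribronchiolar_ratio": np.nan,
               "baff_mean_spots": np.nan}
        if organ in ("SMG", "LG"):
            row["focus_score"] = focus_score(sub, method=focus_method).score
        elif organ == "LUNG":
            ls = lung_scores(sub)
            row["perivascular_ratio"] = ls.perivascular_ratio
            row["peribronchiolar_ratio"] = ls.peribronchiolar_ratio
        elif organ == "SMG_BAFF":
            row["baff_mean_spots"] = baff_spots(sub)
        rows.append(row)
    return pd.DataFrame(rows, columns=["mouse_id", "organ", "focus_score",
                                       "perivascular_ratio",
                                       "peribronchiolar_ratio",
                                       "baff_mean_spots"])
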