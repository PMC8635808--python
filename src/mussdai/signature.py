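"""Type 1 interferon signature: ΔΔCT fold-change/fold-regulation analysis.

qPCR cycle thresholds (CT) from an interferon-response gene panel are
normalised to a reference gene selected for stable expression (lowest CT
standard deviation across all samples, both groups pooled — the trial's
arrays auto-selected IFNA4 this way).  Per gene,

    ΔCT(sample)  = CT(gene) − CT(reference)
    ΔΔCT         = mean ΔCT(test group) − mean ΔCT(control group)
    fold change  = 2^(−ΔΔCT)
    fold regulation = fold change if ≥ 1 else −1 / fold change

A gene is called UP/DOWN regulated when |fold regulation| ≥ 2 (inclusive
cutoff).  Per-gene p-values come from a two-sample t-test on the per-sample
2^(−ΔCT) values (Welch's unequal-variance variant by default, since the
control pool is 2–3× the treated group).

:class:`IFNSignatureAnalyzer` is the estimator view; :func:`delta_delta_ct`
is the functional wrapper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .cohort import CONTROL_GROUPS, TREATED_GROUP

__all__ = [
    "SignatureResult",
    "IFNSignatureAnalyzer",
    "select_reference_gene",
    "delta_delta_ct",
    "count_regulated",
]


@dataclass
class SignatureResult:
    gene: str
    mean_dct_test: float
    mean_dct_control: float
    ddct: float
    fold_change: float
    fold_regulation: float
    log2_fold_change: float
    p_value: float | None
    regulated: str  # UP | DOWN | NONE


def _collapse_replicates(ct: pd.DataFrame) -> pd.DataFrame:
    """Average replicate wells to one CT per (mouse, gene); genes × samples."""
    per_sample = ct.dropna(subset=["ct"]).groupby(
        ["gene", "mouse_id"])["ct"].mean()
    return per_sample.unstack("mouse_id")


def select_reference_gene(ct: pd.DataFrame, pin: str | None = None) -> str:
    """Most stably expressed gene: minimal CT SD across all samples pooled.

    ``pin`` bypasses the selection with a named gene.  Genes missing in any
    sample are ineligible; all-missing columns are excluded.
    """
    mat = _collapse_replicates(ct)
    if pin is not None:
        if pin not in mat.index:
            raise ValueError(f"pinned reference gene {pin!r} not in panel")
        return pin
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("reference selection needs ≥ 2 genes and ≥ 2 samples")
    complete = mat.dropna(axis=0)
    if complete.empty:
        raise ValueError("no gene measured in every sample")
    sds = complete.std(axis=1, ddof=1)
    return str(sds.idxmin())


def _welch_or_student(x: np.ndarray, y: np.ndarray, welch: bool) -> float | None:
    if len(x) < 2 or len(y) < 2:
        return None
    if np.var(x) == 0 and np.var(y) == 0:
        return 1.0 if x.mean() == y.mean() else np.nextafter(0, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = float(sps.ttest_ind(x, y, equal_var=not welch).pvalue)
    return min(max(p, np.nextafter(0, 1)), 1.0)


def delta_delta_ct(ct: pd.DataFrame, reference_gene: str | None = None,
                   test_group: str = TREATED_GROUP,
                   control_groups=CONTROL_GROUPS, cutoff: float = 2.0,
                   welch: bool = True, fdr: bool = False) -> pd.DataFrame:
    """ΔΔCT analysis of a tidy CT table (mouse_id, group, gene, replicate, ct).

    Control samples are pooled across ``control_groups`` (NT+PBS+KLH by
    default).  Missing CTs (undetermined wells) exclude the sample for that
    gene only — never imputed.  Returns one row per non-reference gene with
    all :class:`SignatureResult` fields; ``fdr=True`` adds a
    Benjamini-Hochberg ``q_value`` column.
    """
    if reference_gene is None:
        reference_gene = select_reference_gene(ct)
    mat = _collapse_replicates(ct)
    if reference_gene not in mat.index:
        raise ValueError(f"reference gene {reference_gene!r} not in panel")
    ref = mat.loc[reference_gene]
    if ref.isna().any():
        raise ValueError("reference gene missing in some samples")
    dct = mat.sub(ref, axis=1)

    group_of = ct.drop_duplicates("mouse_id").set_index("mouse_id")["group"]
    test_ids = [m for m in mat.columns if group_of.get(m) == test_group]
    ctrl_ids = [m for m in mat.columns if group_of.get(m) in set(control_groups)]
    if not test_ids or not ctrl_ids:
        raise ValueError("both test and control groups need ≥ 1 sample")

    rows = []
    for gene in mat.index:
        if gene == reference_gene:
            continue
        t = dct.loc[gene, test_ids].dropna().to_numpy(float)
        c = dct.loc[gene, ctrl_ids].dropna().to_numpy(float)
        if len(t) == 0 or len(c) == 0:
            continue
        ddct = float(t.mean() - c.mean())
        fc = float(2.0 ** (-ddct))
        fr = fc if fc >= 1 else -1.0 / fc
        regulated = "NONE"
        if abs(fr) >= cutoff:
            regulated = "UP" if fr > 0 else "DOWN"
        p = _welch_or_student(2.0 ** (-t), 2.0 ** (-c), welch)
        rows.append({
            "gene": gene, "mean_dct_test": float(t.mean()),
            "mean_dct_control": float(c.mean()), "ddct": ddct,
            "fold_change": fc, "fold_regulation": fr,
            "log2_fold_change": -ddct, "p_value": p, "regulated": regulated,
        })
    out = pd.DataFrame(rows).sort_values("gene").reset_index(drop=True)
    if fdr and len(out):
        from statsmodels.stats.multitest import multipletests

        mask = out["p_value"].notna()
        q = np.full(len(out), np.nan)
        if mask.any():
            q[mask.to_numpy()] = multipletests(
                out.loc[mask, "p_value"], method="fdr_bh")[1]
        out["q_value"] = q
    return out


def count_regulated(results: pd.DataFrame, direction: str) -> int:
    """Number of genes called in the given direction (``UP`` or ``DOWN``)."""
    if direction not in ("UP", "DOWN", "NONE"):
        raise ValueError("direction must be UP, DOWN or NONE")
    return int((results["regulated"] == direction).sum())


class IFNSignatureAnalyzer(BaseEstimator):
    """Estimator view of the ΔΔCT signature analysis.

    Parameters
    ----------
    reference_gene : str or None
        Pin a reference; None auto-selects the most stable gene.
    test_group, control_groups
        Group labels; controls are pooled.
    cutoff : float, default=2.0
        Inclusive fold-regulation threshold for the UP/DOWN call.
    welch : bool, default=True
        Unequal-variance t-test (False = classic Student).
    fdr : bool, default=False
        Add Benjamini-Hochberg q-values.

    Attributes
    ----------
    reference_gene_ : str
        The reference actually used.
    results_ : pandas.DataFrame
        One row per gene with ΔΔCT, fold change/regulation, p and call.
    """

    def __init__(self, reference_gene: str | None = None,
                 test_group: str = TREATED_GROUP,
                 control_groups=CONTROL_GROUPS, cutoff: float = 2.0,
                 welch: bool = True, fdr: bool = False):
        self.reference_gene = reference_gene
        self.test_group = test_group
        self.control_groups = control_groups
        self.cutoff = cutoff
        self.welch = welch
        self.fdr = fdr

    def fit(self, X: pd.DataFrame, y=None):
        """Run the analysis on a tidy CT table."""
        self.reference_gene_ = (self.reference_gene
                                or select_reference_gene(X))
        self.results_ = delta_delta_ct(
            X, reference_gene=self.reference_gene_,
            test_group=self.test_group, control_groups=self.control_groups,
            cutoff=self.cutoff, welch=self.welch, fdr=self.fdr)
        return self

    def count(self, direction: str) -> int:
        if not hasattr(self, "results_"):
            raise ValueError("not fitted")
        return count_regulated(self.results_, direction)
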