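"""Cross-platform concordance and plasma-solute statistics.

Two independent checks of the expression findings: (1) Pearson
concordance between microarray and NanoString fold-change estimates for a
panel of verification genes, and (2) descriptive and inferential
statistics on patient plasma indoxyl-sulfate concentrations drawn
immediately before and after one hemodialysis session, stratified by
residual renal function (RRF).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import log2_from_signed

logger = logging.getLogger(__name__)

__all__ = [
    "RatioConvention",
    "ConcordanceResult",
    "SoluteSummary",
    "concordance",
    "solute_summary",
    "paired_compare",
    "group_compare",
]

RATIO_COLUMNS = (
    "microarray_pre",
    "microarray_post",
    "nanostring_pre",
    "nanostring_post",
)


class RatioConvention(str, enum.Enum):
    SIGNED = "signed"
    LOG2 = "log2"


class InsufficientDataError(ValueError):
    pass


@dataclass
class ConcordanceResult:
    r_pre: float
    r_post: float
    n: int
    convention: RatioConvention


def concordance(
    table: pd.DataFrame, convention: RatioConvention | str = RatioConvention.SIGNED
) -> ConcordanceResult:
    """Pearson concordance of the two platforms' fold-change estimates.

    ``table`` needs the four signed-ratio columns ``microarray_pre``,
    ``microarray_post``, ``nanostring_pre``, ``nanostring_post``
    (pre/control and post/control per platform, |v| >= 1).  SIGNED
    correlates the tabulated signed ratios as printed; LOG2 first maps
    v -> sign(v) * log2|v|.
    """
    convention = RatioConvention(convention)
    missing = [c for c in RATIO_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"ratio table missing columns: {missing}")
    if len(table) < 3:
        raise InsufficientDataError(
            f"need >= 3 genes for concordance, got {len(table)}"
        )
    vals = table[list(RATIO_COLUMNS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite ratio values")
    if convention == RatioConvention.LOG2:
        vals = np.sign(vals) * np.log2(np.abs(vals))
    if np.any(vals.std(axis=0) == 0):
        raise ValueError("zero variance in a ratio column")
    r_pre = stats.pearsonr(vals[:, 0], vals[:, 2]).statistic
    r_post = stats.pearsonr(vals[:, 1], vals[:, 3]).statistic
    return ConcordanceResult(
        r_pre=float(r_pre), r_post=float(r_post), n=len(table), convention=convention
    )


@dataclass
class SoluteSummary:
    """Group means and dialytic reductions of plasma indoxyl sulfate."""

    pre_mean: float
    post_mean: float
    rrf_pre_mean: float | None
    rrf_post_mean: float | None
    anuric_pre_mean: float | None
    anuric_post_mean: float | None
    mean_fractional_reduction: float
    per_patient_reduction: pd.Series
    n_patients: int
    n_flagged: int  # dialysis pairs with post >= pre (flagged, not rejected)
    free_is_mean: float | None = None
    free_frac_of_mean_total: float | None = None
    mean_free_fraction: float | None = None

    def as_dict(self) -> dict:
        d = {
            "pre_mean": self.pre_mean,
            "post_mean": self.post_mean,
            "rrf_pre_mean": self.rrf_pre_mean,
            "rrf_post_mean": self.rrf_post_mean,
            "anuric_pre_mean": self.anuric_pre_mean,
            "anuric_post_mean": self.anuric_post_mean,
            "mean_fractional_reduction": self.mean_fractional_reduction,
            "n_patients": self.n_patients,
            "n_flagged": self.n_flagged,
        }
        if self.free_is_mean is not None:
            d.update(
                free_is_mean=self.free_is_mean,
                free_frac_of_mean_total=self.free_frac_of_mean_total,
                mean_free_fraction=self.mean_free_fraction,
            )
        return d


def solute_summary(table: pd.DataFrame) -> SoluteSummary:
    """Mean pre/post-dialysis IS concentrations, overall and by RRF stratum.

    ``table`` needs columns ``rrf`` (boolean), ``pre_is`` and ``post_is``
    (ug/ml).  Per-patient fractional reduction is (pre - post)/pre.
    Dialysis pairs with post >= pre are counted in ``n_flagged`` (and
    logged) but retained.  When a ``free_is`` column (pre-dialysis free,
    unbound IS) is present, its mean and two free-fraction conventions
    (mean(free)/mean(total) and mean of per-patient free/total) are
    reported descriptively.
    """
    if len(table) == 0:
        raise InsufficientDataError("empty solute table")
    for col in ("pre_is", "post_is"):
        if col not in table.columns:
            raise ValueError(f"solute table missing column {col!r}")
        if (table[col] <= 0).any():
            raise ValueError(f"non-positive concentration in {col!r}")
    pre = table["pre_is"].astype(float)
    post = table["post_is"].astype(float)
    flagged = int((post >= pre).sum())
    if flagged:
        logger.warning("%d patient(s) with post_is >= pre_is", flagged)
    reduction = (pre - post) / pre

    def _stratum(mask) -> tuple[float | None, float | None]:
        if mask is None or not mask.any():
            return None, None
        return float(pre[mask].mean()), float(post[mask].mean())

    rrf = table["rrf"].astype(bool) if "rrf" in table.columns else None
    rrf_pre, rrf_post = _stratum(rrf if rrf is not None else None)
    an_pre, an_post = _stratum(~rrf if rrf is not None else None)

    free_mean = free_of_mean = mean_free_frac = None
    if "free_is" in table.columns and table["free_is"].notna().any():
        free = table["free_is"].astype(float).dropna()
        free_mean = float(free.mean())
        free_of_mean = float(free.mean() / pre.loc[free.index].mean())
        mean_free_frac = float((free / pre.loc[free.index]).mean())

    return SoluteSummary(
        pre_mean=float(pre.mean()),
        post_mean=float(post.mean()),
        rrf_pre_mean=rrf_pre,
        rrf_post_mean=rrf_post,
        anuric_pre_mean=an_pre,
        anuric_post_mean=an_post,
        mean_fractional_reduction=float(reduction.mean()),
        per_patient_reduction=reduction,
        n_patients=len(table),
        n_flagged=flagged,
        free_is_mean=free_mean,
        free_frac_of_mean_total=free_of_mean,
        mean_free_fraction=mean_free_frac,
    )


def paired_compare(table: pd.DataFrame, method: str = "t") -> tuple[float, float]:
    """Paired two-sided test of pre- vs post-dialysis IS per patient.

    Default is the paired t-test; ``method="wilcoxon"`` gives the
    signed-rank alternative.  All-zero differences return (0.0, 1.0).
    """
    pairs = table[["pre_is", "post_is"]].dropna()
    if len(pairs) < 3:
        raise InsufficientDataError("need >= 3 complete pre/post pairs")
    diff = pairs["pre_is"].to_numpy(float) - pairs["post_is"].to_numpy(float)
    if np.allclose(diff, 0):
        return 0.0, 1.0
    if method == "wilcoxon":
        res = stats.wilcoxon(diff)
    elif method == "t":
        res = stats.ttest_rel(pairs["pre_is"], pairs["post_is"])
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def group_compare(table: pd.DataFrame, column: str = "pre_is") -> tuple[float, float]:
    """Welch two-sample t comparing RRF vs anuric patients on one column."""
    if "rrf" not in table.columns:
        raise ValueError("solute table lacks 'rrf' column")
    rrf_mask = table["rrf"].astype(bool)
    a = table.loc[rrf_mask, column].dropna().to_numpy(float)
    b = table.loc[~rrf_mask, column].dropna().to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each stratum needs >= 2 patients")
    if a.std() == 0 and b.std() == 0:
        return (0.0, 1.0) if np.isclose(a.mean(), b.mean()) else (np.inf, 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
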