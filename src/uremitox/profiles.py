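"""Condition-level summaries, ratio conventions and template matching.

The reporter-cell design contrasts six plasma exposures against normal
control plasma.  All internal arithmetic is in log2 space; the signed-ratio
convention used in printed fold-change tables (v >= 1 up, v <= -1 down,
-1.2 meaning a 1.2-fold decrease) is exposed through
:func:`signed_from_log2` / :func:`log2_from_signed` and the
:meth:`FoldChangeTable.signed` view.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .containers import (
    Condition,
    ConfigurationError,
    ExpressionMatrix,
)

__all__ = [
    "ConditionProfile",
    "FoldChangeTable",
    "Template",
    "condition_means",
    "fold_changes",
    "signed_from_log2",
    "log2_from_signed",
    "ptm_match",
    "load_templates",
]


@dataclass
class ConditionProfile:
    """Per-gene mean log2 expression per condition, with replicate counts."""

    means: pd.DataFrame  # genes x conditions (column names are Condition values)
    replicate_counts: dict[str, int]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.means.index)

    def conditions(self) -> list[str]:
        return list(self.means.columns)


@dataclass
class FoldChangeTable:
    """Per-gene log2 ratio of each condition against CONTROL.

    The CONTROL column is identically zero in log2 view (1.0 in signed view).
    """

    log2_ratios: pd.DataFrame  # genes x conditions

    def __post_init__(self) -> None:
        if Condition.CONTROL.value in self.log2_ratios.columns:
            ctrl = self.log2_ratios[Condition.CONTROL.value]
            if not np.allclose(ctrl, 0.0, atol=1e-12):
                raise ConfigurationError("CONTROL log2 ratio column must be zero")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.log2_ratios.index)

    def column(self, condition: Condition | str) -> pd.Series:
        key = Condition(condition).value
        if key not in self.log2_ratios.columns:
            raise ConfigurationError(f"fold-change table lacks condition {key}")
        return self.log2_ratios[key]

    def signed(self) -> pd.DataFrame:
        """Signed-ratio view: |v| >= 1, negative meaning fold decrease."""
        return self.log2_ratios.apply(signed_from_log2)


def signed_from_log2(lam):
    """Map a log2 ratio to the signed-ratio convention.

    ``0 -> 1.0``, ``1 -> 2.0``, ``-1 -> -2.0``; the range excludes (-1, 1).
    Accepts scalars or arrays; odd and strictly increasing in log2 space.
    """
    arr = np.asarray(lam, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite log2 ratio")
    out = np.where(arr >= 0, np.exp2(arr), -np.exp2(-arr))
    if np.isscalar(lam) or arr.ndim == 0:
        return float(out)
    return out


def log2_from_signed(v):
    """Inverse of :func:`signed_from_log2`; domain |v| >= 1."""
    arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite signed ratio")
    if np.any(np.abs(arr) < 1.0):
        raise ValueError("signed ratio must satisfy |v| >= 1")
    out = np.where(arr >= 0, np.log2(np.abs(arr)), -np.log2(np.abs(arr)))
    if np.isscalar(v) or arr.ndim == 0:
        return float(out)
    return out


def condition_means(matrix: ExpressionMatrix) -> ConditionProfile:
    """Arithmetic mean log2 expression per gene per condition.

    Mirrors how replicate arrays of one exposure are averaged before any
    ratio is taken (e.g. the mean over the ten uremic-plasma replicates).
    """
    conds = matrix.sheet.conditions()
    if not conds:
        raise ConfigurationError("sample sheet defines no conditions")
    cols = {}
    counts = {}
    for cond in conds:
        samples = matrix.sheet.samples_for(cond)
        sub = matrix.values[samples]
        cols[cond.value] = sub.mean(axis=1)
        counts[cond.value] = len(samples)
    means = pd.DataFrame(cols, index=matrix.values.index)
    return ConditionProfile(means=means, replicate_counts=counts)


def fold_changes(profile: ConditionProfile) -> FoldChangeTable:
    """log2 ratio of every condition mean against the CONTROL mean."""
    ctrl_key = Condition.CONTROL.value
    if ctrl_key not in profile.means.columns:
        raise ConfigurationError("profile lacks CONTROL condition")
    ratios = profile.means.sub(profile.means[ctrl_key], axis=0)
    return FoldChangeTable(log2_ratios=ratios)


@dataclass
class Template:
    """An expected expression pattern over conditions (or samples).

    Defined at condition level (one value per condition, broadcast to the
    samples of that condition) unless ``per_sample`` values are supplied.
    """

    name: str
    condition_values: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.condition_values.values()), dtype=float)
        if vals.size == 0 or np.var(vals) == 0:
            raise ValueError(f"template {self.name!r} has zero variance")
        self.condition_values = {
            Condition(k).value: float(v) for k, v in self.condition_values.items()
        }

    def to_condition_vector(self, conditions) -> np.ndarray:
        keys = [Condition(c).value for c in conditions]
        missing = [k for k in keys if k not in self.condition_values]
        if missing:
            raise ConfigurationError(
                f"template {self.name!r} lacks conditions {missing}"
            )
        return np.array([self.condition_values[k] for k in keys], dtype=float)

    def to_sample_vector(self, sheet) -> np.ndarray:
        return np.array(
            [self.condition_values[c] for c in sheet.frame["condition"]], dtype=float
        )


def ptm_match(data, template: Template) -> pd.DataFrame:
    """Pavlidis-style template matching.

    Correlates each gene's profile with a template pattern and converts the
    Pearson r to a two-sided significance through the t transform
    ``t = r * sqrt((n - 2) / (1 - r^2))`` on n - 2 degrees of freedom.

    Parameters
    ----------
    data : ExpressionMatrix or ConditionProfile
        Matched per sample (matrix) or per condition mean (profile).
    template : Template

    Returns
    -------
    DataFrame indexed by gene id with columns ``r``, ``p`` and ``flagged``
    (True where the gene has zero variance; such genes carry NaN r/p and
    must be excluded from selection).
    """
    if isinstance(data, ExpressionMatrix):
        t = template.to_sample_vector(data.sheet)
        X = data.values.to_numpy(dtype=float)
        index = data.values.index
    elif isinstance(data, ConditionProfile):
        t = template.to_condition_vector(data.conditions())
        X = data.means.to_numpy(dtype=float)
        index = data.means.index
    else:
        raise TypeError("data must be ExpressionMatrix or ConditionProfile")
    n = t.size
    if X.shape[1] != n:
        raise ValueError(
            f"template length {n} does not match data width {X.shape[1]}"
        )
    if np.var(t) == 0:
        raise ValueError("constant template")
    if n < 3:
        raise ValueError("need at least 3 points for template matching")

    tc = t - t.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    gene_ss = np.einsum("ij,ij->i", Xc, Xc)
    flagged = gene_ss == 0
    denom = np.sqrt(gene_ss * (tc @ tc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ tc) / denom
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    r[flagged] = np.nan
    p[flagged] = np.nan
    return pd.DataFrame({"r": r, "p": p, "flagged": flagged}, index=index)


def load_templates(path) -> list[Template]:
    """Read template definitions from a small YAML/JSON config.

    Layout: ``{name: {condition: expected value, ...}, ...}``.
    """
    with open(path) as fh:
        text = fh.read()
    data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    if not isinstance(data, dict):
        raise ValueError("template config must map names to condition values")
    return [Template(name=k, condition_values=v) for k, v in data.items()]
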