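"""Dialyzable vs dialysis-resistant classification of dysregulated genes.

The core procedure: a gene is *dysregulated* when its pre-dialysis /
control expression ratio deviates from unity by at least a fractional
boundary theta (10% by default, 20% as the stricter alternative).  A
dysregulated gene *returned to baseline* when its post-dialysis ratio falls
back strictly within the boundary, and *remained dysregulated* otherwise.
Two follow-up questions quantify mechanism:

* mimicry -- what share of the dialysis-resistant genes cross the same
  boundary in the same direction when control plasma is spiked with
  indoxyl sulfate (the candidate non-dialyzable toxin);
* reversal -- what share of the dysregulation disappears when probenecid,
  an organic-anion-transport inhibitor, is added to the uremic plasma.

The boundary is applied log-symmetrically by default: up iff
log2 ratio >= log2(1 + theta), down iff <= -log2(1 + theta) (linear ratio
<= 1/(1+theta)).  A linear-down alternative (ratio <= 1 - theta) is
available via ``boundary_rule="linear"``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import Condition, ConfigurationError, ExpressionMatrix
from .profiles import (
    FoldChangeTable,
    Template,
    condition_means,
    fold_changes,
    ptm_match,
)

__all__ = [
    "AnalysisConfig",
    "DysregulationPartition",
    "MimicryResult",
    "ReversalResult",
    "classify",
    "mimicry",
    "reversal",
    "boundary_sweep",
    "DialyzabilityModel",
    "DialyzabilityResults",
]


class MimicryRule(str, enum.Enum):
    SAME_DIRECTION_THRESHOLD = "same_direction_threshold"


class BoundaryRule(str, enum.Enum):
    LOG_SYMMETRIC = "log_symmetric"
    LINEAR = "linear"


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and rule choices for the classification.

    theta : fractional deviation defining dysregulation (0 < theta < 1);
        0.10 is the primary boundary, 0.20 the stricter alternative.
    mimicry_rule : how IS-mimicry is decided (same-direction boundary
        crossing in the IS-spiked condition).
    boundary_rule : log-symmetric (down iff ratio <= 1/(1+theta)) or
        linear (down iff ratio <= 1-theta).
    """

    theta: float = 0.10
    mimicry_rule: MimicryRule = MimicryRule.SAME_DIRECTION_THRESHOLD
    boundary_rule: BoundaryRule = BoundaryRule.LOG_SYMMETRIC

    def __post_init__(self) -> None:
        if not 0 < self.theta < 1:
            raise ConfigurationError(f"theta must be in (0, 1), got {self.theta}")

    @property
    def up_cut(self) -> float:
        """log2 boundary for up-dysregulation (inclusive)."""
        return float(np.log2(1.0 + self.theta))

    @property
    def down_cut(self) -> float:
        """log2 boundary for down-dysregulation (inclusive)."""
        if self.boundary_rule == BoundaryRule.LINEAR:
            return float(np.log2(1.0 - self.theta))
        return -self.up_cut


@dataclass
class DysregulationPartition:
    """The returned/remained x up/down partition of dysregulated genes.

    Direction labels come from the pre-dialysis ratio.  Genes dysregulated
    only post-dialysis are excluded from the four headline sets and listed
    in ``post_only_up`` / ``post_only_down``.
    """

    returned_up: set[str]
    returned_down: set[str]
    remained_up: set[str]
    remained_down: set[str]
    theta: float
    post_only_up: set[str] = field(default_factory=set)
    post_only_down: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        sets = [self.returned_up, self.returned_down, self.remained_up, self.remained_down]
        union = set().union(*sets)
        if sum(len(s) for s in sets) != len(union):
            raise ValueError("partition sets must be pairwise disjoint")

    @property
    def n_returned(self) -> int:
        return len(self.returned_up) + len(self.returned_down)

    @property
    def n_remained(self) -> int:
        return len(self.remained_up) + len(self.remained_down)

    @property
    def n_dysregulated(self) -> int:
        return self.n_returned + self.n_remained

    def counts(self) -> dict[str, int]:
        return {
            "theta": self.theta,
            "n_dysregulated": self.n_dysregulated,
            "n_returned": self.n_returned,
            "n_remained": self.n_remained,
            "n_returned_up": len(self.returned_up),
            "n_returned_down": len(self.returned_down),
            "n_remained_up": len(self.remained_up),
            "n_remained_down": len(self.remained_down),
            "n_post_only_up": len(self.post_only_up),
            "n_post_only_down": len(self.post_only_down),
        }


@dataclass
class MimicryResult:
    """Share of dialysis-resistant genes reproduced by IS-spiked control plasma."""

    frac_up_mimicked: float | None
    frac_down_mimicked: float | None
    mimicked_up: set[str]
    mimicked_down: set[str]


@dataclass
class ReversalResult:
    """Share of dysregulation abolished by probenecid, per plain condition."""

    frac_reversed: dict[str, float | None]  # keys PRE, POST
    reversed_genes: dict[str, set[str]]


def _within(vals: pd.Series, config: AnalysisConfig) -> pd.Series:
    """Strictly inside the boundary (neither up nor down dysregulated)."""
    return (vals < config.up_cut) & (vals > config.down_cut)


def classify(fc: FoldChangeTable, config: AnalysisConfig | None = None) -> DysregulationPartition:
    """Partition genes into returned/remained x up/down at boundary theta.

    A gene is dysregulated-up iff its PRE log2 ratio >= log2(1+theta)
    (ties at the boundary count as dysregulated, per "at least" a theta
    difference), down iff <= the down boundary; a dysregulated gene
    returned iff its POST ratio lies strictly within the open boundary
    interval, else it remained.
    """
    config = config or AnalysisConfig()
    pre = fc.column(Condition.PRE)
    post = fc.column(Condition.POST)

    up = pre >= config.up_cut
    down = pre <= config.down_cut
    returned = _within(post, config)

    idx = fc.log2_ratios.index
    part = DysregulationPartition(
        returned_up=set(idx[up & returned]),
        remained_up=set(idx[up & ~returned]),
        returned_down=set(idx[down & returned]),
        remained_down=set(idx[down & ~returned]),
        theta=config.theta,
    )
    post_dys_up = (post >= config.up_cut) & ~(up | down)
    post_dys_down = (post <= config.down_cut) & ~(up | down)
    part.post_only_up = set(idx[post_dys_up])
    part.post_only_down = set(idx[post_dys_down])
    return part


def mimicry(
    partition: DysregulationPartition,
    fc: FoldChangeTable,
    config: AnalysisConfig | None = None,
) -> MimicryResult:
    """Fraction of remained (dialysis-resistant) genes mimicked by IS.

    A remained-up gene is mimicked iff its IS-spiked-control log2 ratio
    crosses the up boundary; symmetrically for remained-down.  Fractions
    are None when the corresponding remained set is empty.
    """
    config = config or AnalysisConfig()
    is_col = fc.column(Condition.CONTROL_IS)

    def _frac(remained: set[str], crossing: pd.Series):
        members = [g for g in fc.gene_ids if g in remained]
        mimicked = {g for g in members if bool(crossing.loc[g])}
        frac = len(mimicked) / len(members) if members else None
        return frac, mimicked

    frac_up, mim_up = _frac(partition.remained_up, is_col >= config.up_cut)
    frac_down, mim_down = _frac(partition.remained_down, is_col <= config.down_cut)
    return MimicryResult(
        frac_up_mimicked=frac_up,
        frac_down_mimicked=frac_down,
        mimicked_up=mim_up,
        mimicked_down=mim_down,
    )


def reversal(
    fc_plain: FoldChangeTable,
    fc_prob: FoldChangeTable | None = None,
    config: AnalysisConfig | None = None,
) -> ReversalResult:
    """Fraction of dysregulation abolished by probenecid.

    For each of PRE and POST: among genes dysregulated in that condition,
    the fraction whose matching probenecid-condition ratio lies strictly
    within the boundary.  ``fc_prob`` defaults to ``fc_plain`` when the
    probenecid columns live in the same table.
    """
    config = config or AnalysisConfig()
    fc_prob = fc_prob if fc_prob is not None else fc_plain
    pairs = {
        Condition.PRE.value: Condition.PRE_PROB,
        Condition.POST.value: Condition.POST_PROB,
    }
    fracs: dict[str, float | None] = {}
    rev_sets: dict[str, set[str]] = {}
    for plain_key, prob_cond in pairs.items():
        plain = fc_plain.column(plain_key)
        prob = fc_prob.column(prob_cond)
        dys = (plain >= config.up_cut) | (plain <= config.down_cut)
        genes = list(plain.index[dys])
        inside = _within(prob, config)
        rev = {g for g in genes if bool(inside.loc[g])}
        fracs[plain_key] = len(rev) / len(genes) if genes else None
        rev_sets[plain_key] = rev
    return ReversalResult(frac_reversed=fracs, reversed_genes=rev_sets)


def boundary_sweep(
    fc: FoldChangeTable,
    thetas,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Partition counts at each boundary theta; one row per theta.

    Total dysregulated is non-increasing in theta (set containment).
    """
    thetas = list(thetas)
    if not thetas:
        raise ConfigurationError("empty theta list")
    base = config or AnalysisConfig()
    rows = []
    for theta in thetas:
        part = classify(fc, replace(base, theta=float(theta)))
        rows.append(part.counts())
    return pd.DataFrame(rows).set_index("theta")


# ---------------------------------------------------------------------------
# Model / Results front end


class DialyzabilityModel:
    """Dialyzability analysis of a reporter-cell expression experiment.

    Wraps the full chain condition means -> fold changes -> boundary
    classification -> IS mimicry -> probenecid reversal behind a fit()
    returning :class:`DialyzabilityResults`.

    Parameters
    ----------
    matrix : ExpressionMatrix
        log2 expression with a sample sheet covering at least CONTROL,
        PRE and POST; CONTROL_IS and the probenecid conditions enable the
        mimicry and reversal stages.
    config : AnalysisConfig, optional
    ptm_templates : list of Template, optional
        When given, genes are pre-filtered to those whose condition-mean
        profile matches at least one template with r >= ``ptm_min_r``
        before the boundary is applied (template-matching-first ordering).
    ptm_min_r : float, default 0.9
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        config: AnalysisConfig | None = None,
        ptm_templates: list[Template] | None = None,
        ptm_min_r: float = 0.9,
    ) -> None:
        self.matrix = matrix
        self.config = config or AnalysisConfig()
        self.ptm_templates = ptm_templates
        self.ptm_min_r = float(ptm_min_r)
        conds = {c.value for c in matrix.sheet.conditions()}
        for needed in (Condition.CONTROL, Condition.PRE, Condition.POST):
            if needed.value not in conds:
                raise ConfigurationError(f"matrix lacks condition {needed.value}")
        if len(matrix.sheet.samples_for(Condition.CONTROL)) < 2:
            raise ConfigurationError("CONTROL needs >= 2 samples for ratios")

    @classmethod
    def from_files(cls, matrix_path, sheet_path, **kwargs) -> "DialyzabilityModel":
        from . import io

        matrix = io.read_expression(matrix_path, sheet=io.read_sample_sheet(sheet_path))
        return cls(matrix, **kwargs)

    def fit(self) -> "DialyzabilityResults":
        profile = condition_means(self.matrix)
        ptm_table = None
        if self.ptm_templates:
            ptm_table = pd.DataFrame(
                {
                    tpl.name: ptm_match(profile, tpl)["r"]
                    for tpl in self.ptm_templates
                }
            )
            best = ptm_table.max(axis=1)
            keep = best.index[best.fillna(-np.inf) >= self.ptm_min_r]
            profile = type(profile)(
                means=profile.means.loc[keep], replicate_counts=profile.replicate_counts
            )
        fc = fold_changes(profile)
        part = classify(fc, self.config)
        conds = {c.value for c in self.matrix.sheet.conditions()}
        mim = (
            mimicry(part, fc, self.config)
            if Condition.CONTROL_IS.value in conds
            else None
        )
        rev = (
            reversal(fc, config=self.config)
            if {Condition.PRE_PROB.value, Condition.POST_PROB.value} <= conds
            else None
        )
        return DialyzabilityResults(
            model=self,
            profile=profile,
            fold_change=fc,
            partition=part,
            mimicry=mim,
            reversal=rev,
            ptm=ptm_table,
        )


@dataclass
class DialyzabilityResults:
    """Fitted dialyzability classification with mimicry/reversal estimates."""

    model: DialyzabilityModel
    profile: object
    fold_change: FoldChangeTable
    partition: DysregulationPartition
    mimicry: MimicryResult | None
    reversal: ReversalResult | None
    ptm: pd.DataFrame | None = None

    def sweep(self, thetas=(0.10, 0.20)) -> pd.DataFrame:
        return boundary_sweep(self.fold_change, thetas, self.model.config)

    def summary(self) -> str:
        c = self.partition.counts()
        cfg = self.model.config
        lines = [
            "Dialyzability classification",
            "=" * 60,
            f"genes analyzed:          {len(self.fold_change.gene_ids)}",
            f"boundary theta:          {cfg.theta:.2f} ({cfg.boundary_rule.value})",
            f"dysregulated (pre):      {c['n_dysregulated']}",
            f"  returned post-dialysis:{c['n_returned']:>6}"
            f"  (up {c['n_returned_up']}, down {c['n_returned_down']})",
            f"  remained dysregulated: {c['n_remained']:>6}"
            f"  (up {c['n_remained_up']}, down {c['n_remained_down']})",
            f"  dysregulated post-only:{c['n_post_only_up'] + c['n_post_only_down']:>6}",
        ]
        if self.mimicry is not None:
            fu, fd = self.mimicry.frac_up_mimicked, self.mimicry.frac_down_mimicked
            lines += [
                "Indoxyl-sulfate mimicry of dialysis-resistant genes",
                f"  up-regulated:   {self._pct(fu)}",
                f"  down-regulated: {self._pct(fd)}",
            ]
        if self.reversal is not None:
            fr = self.reversal.frac_reversed
            lines += [
                "Probenecid reversal of dysregulation",
                f"  pre-dialysis:   {self._pct(fr.get('PRE'))}",
                f"  post-dialysis:  {self._pct(fr.get('POST'))}",
            ]
        return "\n".join(lines)

    @staticmethod
    def _pct(x) -> str:
        return "n/a" if x is None else f"{100 * x:.1f}%"

    def to_report(self) -> dict:
        """JSON-ready report (counts, fractions and configuration echo)."""
        rep = {
            "config": {
                "theta": self.model.config.theta,
                "boundary_rule": self.model.config.boundary_rule.value,
                "mimicry_rule": self.model.config.mimicry_rule.value,
            },
            "counts": self.partition.counts(),
        }
        if self.mimicry is not None:
            rep["mimicry"] = {
                "frac_up_mimicked": self.mimicry.frac_up_mimicked,
                "frac_down_mimicked": self.mimicry.frac_down_mimicked,
            }
        if self.reversal is not None:
            rep["reversal"] = {
                k: v for k, v in self.reversal.frac_reversed.items()
            }
        return rep
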