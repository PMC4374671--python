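"""Synthetic cohorts with planted ground truth.

Generates expression matrices over the six plasma exposure conditions with
per-gene condition effects planted by class (dialyzable-responsive,
dialysis-resistant with or without indoxyl-sulfate mimicry, up or down,
probenecid-reversible), a NanoString-like noisy re-measurement of selected
genes, and per-patient solute concentrations with RRF/anuric group
structure.  Every downstream stage is testable against the planted truth
without any download.

Noise model: additive Gaussian in log2 space (multiplicative in linear
space), the standard picture for normalized array intensities; it keeps
ratio statistics analytically checkable.  Patient-level plasma identity is
collapsed -- each uremic sample is one independent replicate of its
condition, matching how condition averages are formed downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    CONDITION_ORDER,
    Condition,
    ConfigurationError,
    ExpressionMatrix,
    SampleSheet,
)
from .profiles import signed_from_log2
from .validation import RATIO_COLUMNS

__all__ = [
    "GeneClass",
    "SimulationConfig",
    "SoluteSimConfig",
    "TruthAssignment",
    "generate_truth",
    "generate_expression",
    "generate_nanostring",
    "generate_solutes",
    "generate_group_contrast",
    "paper_like_config",
]


class GeneClass(str, enum.Enum):
    """Planted response classes.

    Dialyzable genes are dysregulated by pre-dialysis plasma only (the
    responsible solutes are cleared by one session); resistant genes stay
    dysregulated post-dialysis, and the MIM subclasses additionally
    respond, with the same sign, to IS-spiked control plasma.
    """

    NULL = "NULL"
    DIALYZABLE_UP = "DIALYZABLE_UP"
    DIALYZABLE_DOWN = "DIALYZABLE_DOWN"
    RESISTANT_MIM_UP = "RESISTANT_MIM_UP"
    RESISTANT_MIM_DOWN = "RESISTANT_MIM_DOWN"
    RESISTANT_NONMIM_UP = "RESISTANT_NONMIM_UP"
    RESISTANT_NONMIM_DOWN = "RESISTANT_NONMIM_DOWN"

    @property
    def direction(self) -> int:
        if self is GeneClass.NULL:
            return 0
        return 1 if self.value.endswith("_UP") else -1

    @property
    def resistant(self) -> bool:
        return self.value.startswith("RESISTANT")

    @property
    def mimicked(self) -> bool:
        return "_MIM_" in self.value

    def affected_conditions(self) -> tuple[Condition, ...]:
        if self is GeneClass.NULL:
            return ()
        conds = [Condition.PRE]
        if self.resistant:
            conds.append(Condition.POST)
        if self.mimicked:
            conds.append(Condition.CONTROL_IS)
        return tuple(conds)


# default replicate roster: control 5, control+IS 5, pre 10, post 10,
# pre+probenecid 5, post+probenecid 5
DEFAULT_REPLICATES: dict[Condition, int] = {
    Condition.CONTROL: 5,
    Condition.CONTROL_IS: 5,
    Condition.PRE: 10,
    Condition.POST: 10,
    Condition.PRE_PROB: 5,
    Condition.POST_PROB: 5,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth cohort parameters.

    effect_log2 : mean per-gene |log2 condition effect| (0.45 ~ 1.37-fold,
        comfortably above the 10% boundary yet overlapping it under
        default replicate noise).
    effect_jitter_log2 : sd of the per-gene effect magnitude around
        effect_log2 (truncated to stay positive).
    replicate_sd_log2 : per-sample Gaussian noise sd in log2 space.
    probenecid_reversible : non-NULL genes lose their effect in both
        probenecid conditions (the default); otherwise the probenecid
        columns mirror the matching plain conditions.
    """

    n_genes: int
    class_counts: dict = field(default_factory=dict)
    effect_log2: float = 0.45
    effect_jitter_log2: float = 0.1
    replicate_sd_log2: float = 0.15
    baseline_mean_log2: float = 8.0
    baseline_sd_log2: float = 2.0
    replicates_per_condition: dict = field(
        default_factory=lambda: dict(DEFAULT_REPLICATES)
    )
    probenecid_reversible: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.effect_log2 <= 0:
            raise ConfigurationError("effect_log2 must be positive")
        for name in ("effect_jitter_log2", "replicate_sd_log2", "baseline_sd_log2"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        counts = {GeneClass(k): int(v) for k, v in self.class_counts.items()}
        if any(v < 0 for v in counts.values()):
            raise ConfigurationError("class counts must be nonnegative")
        total = sum(counts.values())
        if total > self.n_genes:
            raise ConfigurationError(
                f"class counts sum to {total} > n_genes {self.n_genes}"
            )
        counts[GeneClass.NULL] = counts.get(GeneClass.NULL, 0) + (
            self.n_genes - total
        )
        object.__setattr__(self, "class_counts", counts)
        object.__setattr__(
            self,
            "replicates_per_condition",
            {Condition(k): int(v) for k, v in self.replicates_per_condition.items()},
        )


@dataclass
class TruthAssignment:
    """Per-gene class labels and true per-condition log2 effect vectors."""

    classes: pd.Series  # gene_id -> GeneClass value (str)
    effects: pd.DataFrame  # genes x conditions, log2 effect

    def genes_in(self, *gene_classes: GeneClass) -> list[str]:
        wanted = {c.value for c in gene_classes}
        return list(self.classes.index[self.classes.isin(wanted)])

    @property
    def n_dialyzable(self) -> int:
        return len(self.genes_in(GeneClass.DIALYZABLE_UP, GeneClass.DIALYZABLE_DOWN))

    @property
    def n_resistant(self) -> int:
        return len(
            self.genes_in(
                GeneClass.RESISTANT_MIM_UP,
                GeneClass.RESISTANT_MIM_DOWN,
                GeneClass.RESISTANT_NONMIM_UP,
                GeneClass.RESISTANT_NONMIM_DOWN,
            )
        )

    def planted_mimicry_fraction(self, direction: int) -> float | None:
        """Share of resistant genes of one direction that are *_MIM_*."""
        if direction > 0:
            mim = self.genes_in(GeneClass.RESISTANT_MIM_UP)
            non = self.genes_in(GeneClass.RESISTANT_NONMIM_UP)
        else:
            mim = self.genes_in(GeneClass.RESISTANT_MIM_DOWN)
            non = self.genes_in(GeneClass.RESISTANT_NONMIM_DOWN)
        total = len(mim) + len(non)
        return len(mim) / total if total else None

    def to_json_dict(self) -> dict:
        return {
            "classes": self.classes.to_dict(),
            "effects": {
                g: {c: float(v) for c, v in row.items() if v != 0.0}
                for g, row in self.effects.iterrows()
            },
        }


def generate_truth(config: SimulationConfig) -> TruthAssignment:
    """Assign classes and effect vectors; deterministic for a fixed seed.

    Effect magnitudes are drawn N(effect_log2, effect_jitter_log2)
    truncated below at 0.05 log2; NULL genes carry all-zero vectors;
    resistant genes keep equal-sign effects pre- and post-dialysis;
    mimicked genes carry the same-sign effect in the IS-spiked condition;
    probenecid-reversible genes have zero effect in both probenecid
    conditions.
    """
    rng = np.random.default_rng([config.seed, 11])
    gene_ids, labels = [], []
    for cls in GeneClass:
        n = config.class_counts.get(cls, 0)
        start = len(gene_ids)
        gene_ids += [f"G{start + i + 1:05d}" for i in range(n)]
        labels += [cls.value] * n
    classes = pd.Series(labels, index=gene_ids, name="gene_class")

    cond_keys = [c.value for c in CONDITION_ORDER]
    effects = pd.DataFrame(0.0, index=gene_ids, columns=cond_keys)
    for cls in GeneClass:
        if cls is GeneClass.NULL:
            continue
        genes = classes.index[classes == cls.value]
        if len(genes) == 0:
            continue
        mags = config.effect_log2 + config.effect_jitter_log2 * rng.standard_normal(
            len(genes)
        )
        mags = np.maximum(mags, 0.05)
        eff = cls.direction * mags
        for cond in cls.affected_conditions():
            effects.loc[genes, cond.value] = eff
        if not config.probenecid_reversible:
            effects.loc[genes, Condition.PRE_PROB.value] = eff
            if cls.resistant:
                effects.loc[genes, Condition.POST_PROB.value] = eff
    return TruthAssignment(classes=classes, effects=effects)


def generate_expression(
    truth: TruthAssignment, config: SimulationConfig
) -> ExpressionMatrix:
    """Matrix of baseline + planted effect + replicate noise, with sheet.

    Samples are named ``<CONDITION>_<k>``; PRE/POST samples carry patient
    ids (paired across the two conditions) with the first half of patients
    flagged as retaining residual renal function.
    """
    reps = config.replicates_per_condition
    for cond, n in reps.items():
        if n < 1:
            raise ConfigurationError(f"{cond.value} needs >= 1 replicate")
    rng = np.random.default_rng([config.seed, 13])
    genes = list(truth.classes.index)
    baseline = config.baseline_mean_log2 + config.baseline_sd_log2 * rng.standard_normal(
        len(genes)
    )

    n_patients = max(reps.get(Condition.PRE, 0), reps.get(Condition.POST, 0))
    n_rrf = n_patients // 2 + n_patients % 2

    columns, rows = {}, []
    for cond in CONDITION_ORDER:
        if cond not in reps:
            continue
        eff = truth.effects[cond.value].to_numpy()
        for k in range(reps[cond]):
            name = f"{cond.value}_{k + 1:02d}"
            noise = config.replicate_sd_log2 * rng.standard_normal(len(genes))
            columns[name] = baseline + eff + noise
            if cond in (Condition.PRE, Condition.POST):
                patient, rrf = f"P{k + 1:02d}", k < n_rrf
            else:
                patient, rrf = "", pd.NA
            rows.append(
                {"sample_id": name, "condition": cond.value, "patient_id": patient,
                 "rrf": rrf}
            )
    values = pd.DataFrame(columns, index=genes)
    sheet = SampleSheet(pd.DataFrame(rows))
    return ExpressionMatrix(values=values, sheet=sheet)


def generate_nanostring(
    matrix: ExpressionMatrix,
    truth: TruthAssignment | None,
    gene_subset,
    noise_sd_log2: float,
    seed: int,
) -> pd.DataFrame:
    """Two-platform ratio table for a verification panel.

    Platform 1 (microarray) ratios are the matrix's condition-mean log2
    ratios; platform 2 (NanoString-like) re-measures them under
    multiplicative log-normal noise (additive N(0, noise_sd_log2) in
    log2).  Output uses the signed-ratio convention with pre/control and
    post/control columns per platform.  At zero noise the two platforms
    coincide exactly.
    """
    if noise_sd_log2 < 0:
        raise ConfigurationError("noise_sd_log2 must be nonnegative")
    gene_subset = list(gene_subset)
    unknown = [g for g in gene_subset if g not in matrix.values.index]
    if unknown:
        raise LookupError(f"unknown gene id(s): {unknown[:5]}")
    cols = list(RATIO_COLUMNS)
    if not gene_subset:
        return pd.DataFrame(columns=cols)

    from .profiles import condition_means, fold_changes

    fc = fold_changes(condition_means(matrix))
    pre = fc.column(Condition.PRE).loc[gene_subset].to_numpy()
    post = fc.column(Condition.POST).loc[gene_subset].to_numpy()
    rng = np.random.default_rng([seed, 17])
    ns_pre = pre + noise_sd_log2 * rng.standard_normal(len(gene_subset))
    ns_post = post + noise_sd_log2 * rng.standard_normal(len(gene_subset))
    return pd.DataFrame(
        {
            "microarray_pre": signed_from_log2(pre),
            "microarray_post": signed_from_log2(post),
            "nanostring_pre": signed_from_log2(ns_pre),
            "nanostring_post": signed_from_log2(ns_post),
        },
        index=pd.Index(gene_subset, name="gene_id"),
    )[cols]


@dataclass(frozen=True)
class SoluteSimConfig:
    """Per-patient plasma IS concentrations with RRF group structure.

    Pre-dialysis concentrations are log-normal around the stratum mean
    (36.4 ug/ml with residual renal function, 57.5 anuric -- the anuric
    mean recomputed from the cohort's per-patient values); one dialysis
    removes a fraction drawn around reduction_mean (0.41 ~ 1 - 27.7/47.0),
    so post = pre * (1 - reduction) < pre by construction.
    """

    n_rrf: int = 5
    n_anuric: int = 5
    pre_mean_rrf: float = 36.4
    pre_mean_anuric: float = 57.5
    pre_cv: float = 0.5
    reduction_mean: float = 0.41
    reduction_sd: float = 0.10
    control_mean: float = 0.89
    n_controls: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rrf < 1 or self.n_anuric < 1:
            raise ConfigurationError("need >= 1 patient per stratum")
        if not 0 < self.reduction_mean < 1:
            raise ConfigurationError("reduction_mean must be in (0, 1)")
        if self.pre_cv < 0 or self.reduction_sd < 0:
            raise ConfigurationError("dispersions must be nonnegative")
        for m in (self.pre_mean_rrf, self.pre_mean_anuric, self.control_mean):
            if m <= 0:
                raise ConfigurationError("means must be positive")


def _lognormal_around(rng, mean: float, cv: float, n: int) -> np.ndarray:
    """Log-normal draws with exact arithmetic mean ``mean`` and CV ``cv``."""
    if cv == 0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2
    return np.exp(mu + np.sqrt(sigma2) * rng.standard_normal(n))


def generate_solutes(config: SoluteSimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Patient solute table plus control-subject concentrations.

    Returns (patients, controls): patients with columns ``patient_id``,
    ``rrf``, ``pre_is``, ``post_is``; controls a Series of control-plasma
    IS concentrations drawn around control_mean with the same CV.
    """
    rng = np.random.default_rng([config.seed, 19])
    pre_rrf = _lognormal_around(rng, config.pre_mean_rrf, config.pre_cv, config.n_rrf)
    pre_anuric = _lognormal_around(
        rng, config.pre_mean_anuric, config.pre_cv, config.n_anuric
    )
    pre = np.concatenate([pre_rrf, pre_anuric])
    n = pre.size
    reduction = np.clip(
        config.reduction_mean + config.reduction_sd * rng.standard_normal(n),
        0.01,
        0.99,
    )
    post = pre * (1.0 - reduction)
    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:02d}" for i in range(n)],
            "rrf": [True] * config.n_rrf + [False] * config.n_anuric,
            "pre_is": pre,
            "post_is": post,
        }
    )
    controls = pd.Series(
        _lognormal_around(rng, config.control_mean, config.pre_cv, config.n_controls),
        index=[f"C{i + 1:02d}" for i in range(config.n_controls)],
        name="control_is",
    )
    return patients, controls


def generate_group_contrast(
    n_genes: int,
    active_genes,
    n_a: int = 5,
    n_b: int = 5,
    effect_log2: float = 1.0,
    replicate_sd_log2: float = 0.25,
    baseline_mean_log2: float = 8.0,
    baseline_sd_log2: float = 2.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Two-group patient matrix for the RRF enrichment contrast.

    Group A (anuric-like, rrf=False) gets ``effect_log2`` added to the
    ``active_genes``; group B (RRF, rrf=True) stays at baseline.  Samples
    are labeled as PRE-condition patient profiles so the sheet round-trips
    through the standard readers.
    """
    rng = np.random.default_rng([seed, 23])
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    active = set(active_genes)
    unknown = active - set(genes)
    if unknown:
        raise LookupError(f"active genes outside universe: {sorted(unknown)[:5]}")
    baseline = baseline_mean_log2 + baseline_sd_log2 * rng.standard_normal(n_genes)
    eff = np.array([effect_log2 if g in active else 0.0 for g in genes])
    columns, rows = {}, []
    for k in range(n_a + n_b):
        in_a = k < n_a
        name = f"PAT{k + 1:02d}"
        noise = replicate_sd_log2 * rng.standard_normal(n_genes)
        columns[name] = baseline + (eff if in_a else 0.0) + noise
        rows.append(
            {"sample_id": name, "condition": Condition.PRE.value,
             "patient_id": name, "rrf": not in_a}
        )
    return ExpressionMatrix(
        values=pd.DataFrame(columns, index=genes), sheet=SampleSheet(pd.DataFrame(rows))
    )


def paper_like_config(
    n_genes: int = 5000,
    replicate_sd_log2: float = 0.15,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Preset mirroring the study's headline proportions.

    Plants 1912 responsive genes: 282 up + 255 down dialyzable (537
    returned), 843 up + 532 down dialysis-resistant (1375 remained) with
    687/843 and 428/532 of them IS-mimicked (81.5% / 80.5%); the rest of
    the universe is NULL.
    """
    counts = {
        GeneClass.DIALYZABLE_UP: 282,
        GeneClass.DIALYZABLE_DOWN: 255,
        GeneClass.RESISTANT_MIM_UP: 687,
        GeneClass.RESISTANT_NONMIM_UP: 156,
        GeneClass.RESISTANT_MIM_DOWN: 428,
        GeneClass.RESISTANT_NONMIM_DOWN: 104,
    }
    if n_genes < sum(counts.values()):
        raise ConfigurationError("n_genes too small for the preset classes")
    return SimulationConfig(
        n_genes=n_genes,
        class_counts=counts,
        replicate_sd_log2=replicate_sd_log2,
        seed=seed,
        **overrides,
    )
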