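"""Core in-memory containers shared across the pipeline.

Expression values are held in log2 space throughout; the signed-ratio
convention (±fold, |v| >= 1) appears only at reporting boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "SampleSheet",
    "ExpressionMatrix",
    "ConfigurationError",
    "FormatError",
]


class ConfigurationError(ValueError):
    """Invalid analysis or simulation configuration."""


class FormatError(ValueError):
    """Malformed input file."""


class Condition(str, Enum):
    """The six plasma exposure conditions of the reporter-cell design.

    CONTROL      -- normal control plasma
    CONTROL_IS   -- control plasma spiked with indoxyl sulfate (60 ug/ml)
    PRE          -- pre-dialysis uremic plasma
    POST         -- post-dialysis uremic plasma
    PRE_PROB     -- pre-dialysis uremic plasma + 1 mM probenecid
    POST_PROB    -- post-dialysis uremic plasma + 1 mM probenecid
    """

    CONTROL = "CONTROL"
    CONTROL_IS = "CONTROL_IS"
    PRE = "PRE"
    POST = "POST"
    PRE_PROB = "PRE_PROB"
    POST_PROB = "POST_PROB"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: canonical condition ordering used for profiles and templates
CONDITION_ORDER: tuple[Condition, ...] = tuple(Condition)


@dataclass
class SampleSheet:
    """Maps sample ids to exposure conditions and (optionally) patients.

    Parameters
    ----------
    frame : pandas.DataFrame
        Columns ``sample_id``, ``condition`` and optionally ``patient_id``
        (empty string when the sample is not patient-derived) and ``rrf``
        (residual renal function flag; pandas nullable boolean).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        required = {"sample_id", "condition"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id in sheet: {dup!r}")
        try:
            df["condition"] = df["condition"].map(lambda c: Condition(c).value)
        except ValueError as exc:
            raise FormatError(f"unknown condition in sample sheet: {exc}") from None
        if "patient_id" not in df.columns:
            df["patient_id"] = ""
        df["patient_id"] = df["patient_id"].fillna("").astype(str)
        if "rrf" not in df.columns:
            df["rrf"] = pd.array([pd.NA] * len(df), dtype="boolean")
        else:
            df["rrf"] = df["rrf"].astype("boolean")
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def conditions(self) -> list[Condition]:
        """Conditions present, in canonical order."""
        present = set(self.frame["condition"])
        return [c for c in CONDITION_ORDER if c.value in present]

    def samples_for(self, condition: Condition | str) -> list[str]:
        cond = Condition(condition).value
        sel = self.frame["condition"] == cond
        return list(self.frame.loc[sel, "sample_id"])

    def replicate_counts(self) -> dict[Condition, int]:
        return {c: len(self.samples_for(c)) for c in self.conditions()}

    def samples_by_rrf(self, condition: Condition | str) -> tuple[list[str], list[str]]:
        """(rrf, anuric) sample ids within one condition; NA flags excluded."""
        cond = Condition(condition).value
        sub = self.frame[self.frame["condition"] == cond]
        with_rrf = list(sub.loc[sub["rrf"] == True, "sample_id"])  # noqa: E712
        anuric = list(sub.loc[sub["rrf"] == False, "sample_id"])  # noqa: E712
        return with_rrf, anuric


@dataclass
class ExpressionMatrix:
    """Normalized log2 expression, genes x samples, plus its sample sheet.

    ``values`` is a DataFrame indexed by gene id with one column per sample;
    no missing values are allowed after ingestion.
    """

    values: pd.DataFrame
    sheet: SampleSheet = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if self.values.isna().any().any():
            raise FormatError("expression matrix contains missing values")
        sheet_ids = set(self.sheet.sample_ids)
        matrix_ids = set(self.values.columns)
        unknown = matrix_ids - sheet_ids
        if unknown:
            raise ConfigurationError(
                f"samples absent from sheet: {sorted(unknown)[:5]}"
            )
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise LookupError(f"unknown gene id(s): {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.sheet)
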