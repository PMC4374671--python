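"""Readers and writers for the pipeline's plain-text formats.

Tab-delimited expression matrices (gene id column + one column per
sample), sample sheets, Broad-dialect GMT gene sets, two-platform ratio
tables, patient solute tables, JSON reports, plus a thin adapter for
GEO series-matrix text.  Every reader is total on its corresponding
writer's output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, FormatError, SampleSheet
from .validation import RATIO_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "read_expression",
    "write_expression",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gmt",
    "write_gmt",
    "read_ratio_table",
    "write_ratio_table",
    "read_solute_table",
    "write_solute_table",
    "write_partition_report",
    "write_truth",
    "read_series_matrix",
]


@dataclass
class GeneSet:
    """A named gene set (GMT line): name, description, unique members."""

    name: str
    description: str
    members: list[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.name!r} has no members")
        seen, unique = set(), []
        for m in self.members:
            if m not in seen:
                seen.add(m)
                unique.append(m)
        if len(unique) != len(self.members):
            logger.warning(
                "gene set %r: %d duplicate member(s) removed",
                self.name,
                len(self.members) - len(unique),
            )
        self.members = unique

    def __len__(self) -> int:
        return len(self.members)


def read_expression(path, sheet: SampleSheet | None = None) -> ExpressionMatrix:
    """Read a tab-delimited log2 expression matrix.

    First column gene ids, header row sample ids.  Duplicate gene ids and
    non-numeric cells are rejected with their location.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"duplicate gene id {dup!r} in {path}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.any().any():
        gene = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[gene]][0]
        raise FormatError(
            f"non-numeric value {raw.loc[gene, col]!r} at gene {gene!r}, "
            f"sample {col!r} in {path}"
        )
    if numeric.isna().any().any():
        gene = numeric.index[numeric.isna().any(axis=1)][0]
        raise FormatError(f"missing value at gene {gene!r} in {path}")
    if sheet is None:
        sheet = _sheet_from_columns(numeric.columns)
    return ExpressionMatrix(values=numeric, sheet=sheet)


def _sheet_from_columns(columns) -> SampleSheet:
    """Infer a sheet from ``<CONDITION>_<k>`` sample names (writer's own)."""
    rows = []
    for name in columns:
        cond = name.rsplit("_", 1)[0]
        rows.append({"sample_id": name, "condition": cond})
    try:
        return SampleSheet(pd.DataFrame(rows))
    except FormatError as exc:
        raise FormatError(
            f"cannot infer conditions from sample names; provide a sheet ({exc})"
        ) from None


def write_expression(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    if "rrf" in df.columns:
        df["rrf"] = df["rrf"].map(
            {"True": True, "False": False, True: True, False: False}
        )
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> list[GeneSet]:
    """Read Broad-dialect GMT: name<TAB>description<TAB>member...; one set
    per line, member order preserved, duplicates dropped with a warning."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            sets.append(
                GeneSet(
                    name=fields[0],
                    description=fields[1],
                    members=[f for f in fields[2:] if f],
                )
            )
    return sets


def write_gmt(gene_sets, path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def read_ratio_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    missing = [c for c in RATIO_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"ratio table missing columns {missing} in {path}")
    return df


def write_ratio_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_solute_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    for col in ("pre_is", "post_is"):
        if col not in df.columns:
            raise FormatError(f"solute table missing column {col!r} in {path}")
    if "rrf" in df.columns:
        df["rrf"] = df["rrf"].map(
            {"True": True, "False": False, True: True, False: False}
        ).astype(bool)
    return df


def write_solute_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_partition_report(partition, path, extra: dict | None = None) -> None:
    """JSON counts report plus a sidecar TSV of per-set gene ids.

    The sidecar ``<path stem>.genes.tsv`` lists (set, gene_id) pairs for
    the four partition sets and the post-only sets.
    """
    path = Path(path)
    counts = partition.counts()
    assert (
        counts["n_returned"] + counts["n_remained"] == counts["n_dysregulated"]
    ), "partition counts inconsistent"
    payload = {"counts": counts}
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    sidecar = path.with_suffix(".genes.tsv")
    with open(sidecar, "w") as fh:
        fh.write("set\tgene_id\n")
        for name in (
            "returned_up",
            "returned_down",
            "remained_up",
            "remained_down",
            "post_only_up",
            "post_only_down",
        ):
            for gene in sorted(getattr(partition, name)):
                fh.write(f"{name}\t{gene}\n")


def write_truth(truth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_json_dict(), indent=1, sort_keys=True))


def read_series_matrix(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Thin GEO series-matrix adapter.

    Extracts only the sample table (one row per sample: geo accession,
    title, characteristics lines) and the expression matrix block between
    ``!series_matrix_table_begin`` / ``!series_matrix_table_end``; all
    other metadata is ignored.  Returns (matrix, sample_table); mapping
    samples to exposure conditions is left to the caller's sheet.
    """
    meta: dict[str, list[str]] = {}
    matrix_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                matrix_lines.append(line)
            elif line.startswith("!Sample_"):
                key, *vals = line.split("\t")
                key = key[len("!Sample_"):]
                vals = [v.strip('"') for v in vals]
                k, i = key, 1
                while k in meta:
                    i += 1
                    k = f"{key}_{i}"
                meta[k] = vals
    if not matrix_lines:
        raise FormatError(f"no series_matrix table block in {path}")
    from io import StringIO

    matrix = pd.read_csv(StringIO("\n".join(matrix_lines)), sep="\t", index_col=0)
    matrix.columns = [c.strip('"') for c in matrix.columns]
    matrix.index = [str(i).strip('"') for i in matrix.index]
    sample_table = pd.DataFrame(meta)
    return matrix, sample_table
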