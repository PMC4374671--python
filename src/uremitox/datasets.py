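"""Bundled study tables: the dialysis cohort and the verification panel.

Two small tables from the uremic-plasma reporter-cell study ship with the
package so the solute statistics and the cross-platform concordance can be
recomputed without any download:

* :func:`patient_characteristics` -- the ten hemodialysis patients (five
  with residual renal function, five anuric) with plasma markers drawn
  immediately pre- and post-dialysis;
* :func:`platform_ratio_table` -- the 22-gene verification panel with
  pre/control and post/control fold changes estimated independently by
  microarray and by NanoString tag counting (signed-ratio convention).

The full expression series is public under GEO accession GSE45709; these
tables cover only the printed patient and panel data.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

__all__ = ["patient_characteristics", "platform_ratio_table"]

_PATIENTS_TSV = """\
patient_id	rrf	sex	age	etiology	months_on_dialysis	urine_output_oz	pre_creatinine_mg_ml	pre_bun_mg_dl	post_bun_mg_dl	pre_is	post_is
1	True	M	47	DM	36	12-18	9.38	63	20	70.21	44.14
2	True	M	70	DM	108	18-24	6.1	55	14	42.67	26.7
3	True	F	64	DM	3	18	4.45	42	7	12.32	5.71
4	True	M	59	DM	60	12	4.27	38	11	28.55	18.63
5	True	M	42	DM	7	9	7.25	63	21	28.33	19.41
6	False	M	28	Transplant Rejection	36	0	13.28	47	12	79.56	40.2
7	False	M	39	FSGS	36	1	16.86	71	19	46.49	34.15
8	False	M	53	DM	84	1	7.98	63	15	65.09	44.29
9	False	F	32	DM	48	0	7.6	45	10	68.56	30.23
10	False	M	50	HTN	180	0	8.58	73	18	27.89	13.07
"""

_RATIOS_TSV = """\
gene_id	microarray_pre	microarray_post	nanostring_pre	nanostring_post
MKI67	2.03	2.26	1.62	1.8
KIF11	1.69	1.8	1.37	1.48
PLAT	1.55	1.78	1.31	1.5
SERPINE1	1.44	1.68	1.67	2.3
TNFSF13B	1.29	1.43	1.37	1.67
BRCA2	1.28	1.48	1.3	1.58
IL8	1.27	1.31	1.37	1.46
CCL2	1.25	1.3	1.75	1.57
THBS1	1.23	1.27	1.32	1.35
FOSL1	1.2	1.35	1.37	1.69
CA9	1.19	1.02	1.35	1.37
B4GALNT2	1.15	1.27	1.23	1.32
ARHGDIB	1.14	1.17	1.12	-1.06
FGF1	1.14	1.26	1.24	1.31
TPM1	1.11	1.14	1.1	1.22
RHOQ	-1.12	-1.16	-1.2	-1.23
PPARGC1A	-1.14	-1.19	-1.33	-1.45
ME1	-1.14	-1.13	-1.23	-1.24
ACOX2	-1.19	-1.29	-1.42	-1.36
GCLC	-1.24	-1.26	-1.48	-1.6
GHR	-1.33	-1.36	-1.45	-1.33
GPD1	-1.37	-1.64	-1.47	-1.88
"""


def patient_characteristics() -> pd.DataFrame:
    """Per-patient markers for the ten-patient dialysis cohort.

    Columns include ``rrf`` (residual renal function), ``pre_is`` and
    ``post_is`` (total plasma indoxyl sulfate, ug/ml) plus BUN and
    creatinine.  Suitable input for :func:`uremitox.validation.solute_summary`.
    """
    df = pd.read_csv(StringIO(_PATIENTS_TSV), sep="\t")
    df["rrf"] = df["rrf"].astype(bool)
    return df


def platform_ratio_table() -> pd.DataFrame:
    """The 22-gene microarray/NanoString verification panel (signed ratios)."""
    return pd.read_csv(StringIO(_RATIOS_TSV), sep="\t", index_col="gene_id")
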