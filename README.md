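# uremitox

Analysis toolkit for a functional-genomic read-out of uremia: normal human
renal cortical cells are used as a *reporter system*, incubated with plasma
drawn from hemodialysis patients immediately before and after one dialysis
session, and their transcriptional response is compared against cells
incubated with control plasma. The package classifies the plasma-induced
gene dysregulation into a **dialyzable** component (cleared by one session)
and a **dialysis-resistant** component, quantifies how much of the
resistant component is mimicked by the protein-bound solute **indoxyl
sulfate (IS)** and abolished by the organic-anion-transport inhibitor
**probenecid**, and validates the read-out with cross-platform concordance,
gene-set enrichment, and plasma solute statistics.

It is written for nephrology / transcriptomics researchers who want the
full classification chain as a tested, scriptable library with a synthetic
cohort generator for planted-truth validation.

## The classification at its core

All expression is handled in log2 space. For each gene *g* and exposure
condition *c* the condition mean is
x̄<sub>g,c</sub> = mean over replicates, and the fold change against
control is λ<sub>g,c</sub> = x̄<sub>g,c</sub> − x̄<sub>g,CONTROL</sub>.
With dysregulation boundary θ (default 0.10, i.e. a 10% deviation,
applied log-symmetrically):

- **dysregulated up**: λ<sub>g,PRE</sub> ≥ log2(1+θ); **down**:
  λ<sub>g,PRE</sub> ≤ −log2(1+θ) (ties count, "at least" a θ difference);
- **returned to baseline**: a dysregulated gene whose
  λ<sub>g,POST</sub> lies strictly inside (−log2(1+θ), log2(1+θ));
  otherwise it **remained** dysregulated;
- **IS-mimicked**: a remained gene whose IS-spiked-control ratio crosses
  the same boundary in the same direction;
- **probenecid-reversed**: a dysregulated gene whose matching
  probenecid-condition ratio falls back inside the boundary.

Supporting machinery: Pavlidis-style template matching (Pearson r of a
gene's condition profile against a template, p from
t = r·√((n−2)/(1−r²))), weighted Kolmogorov–Smirnov gene-set enrichment
with leading-edge ("core-enriched") extraction and phenotype-permutation
p-values, Pearson concordance between microarray and NanoString
fold-change estimates, and paired/Welch t-tests on plasma IS
concentrations stratified by residual renal function (RRF).

## Worked example

```python
import uremitox as ux

cfg = ux.paper_like_config(replicate_sd_log2=0.0, effect_jitter_log2=0.0, seed=1)
truth = ux.generate_truth(cfg)
matrix = ux.generate_expression(truth, cfg)     # 5000 genes x 40 samples
res = ux.DialyzabilityModel(matrix).fit()
print(res.summary())
```

```
Dialyzability classification
============================================================
genes analyzed:          5000
boundary theta:          0.10 (log_symmetric)
dysregulated (pre):      1912
  returned post-dialysis:   537  (up 282, down 255)
  remained dysregulated:   1375  (up 843, down 532)
  dysregulated post-only:     0
Indoxyl-sulfate mimicry of dialysis-resistant genes
  up-regulated:   81.5%
  down-regulated: 80.5%
Probenecid reversal of dysregulation
  pre-dialysis:   100.0%
  post-dialysis:  100.0%
```

Read: of 1912 genes dysregulated by pre-dialysis plasma, 537 normalized
after one dialysis while 1375 did not; about 81% of the dialysis-resistant
response is reproduced by simply spiking control plasma with IS, and all
of it disappears under probenecid — the planted ground truth of this
noise-free synthetic cohort, recovered exactly by the classifier chain.

The bundled study tables work the same way:

```python
from uremitox import datasets, validation
s = validation.solute_summary(datasets.patient_characteristics())
print(round(s.pre_mean, 1), round(s.post_mean, 1))   # 47.0 27.7 ug/ml
r = validation.concordance(datasets.platform_ratio_table())
print(round(r.r_pre, 2), round(r.r_post, 2))         # 0.99 0.93
```

A `uremitox` console script exposes `simulate`, `classify`, `sweep`,
`gsea`, `concord`, `solutes` and `run-all` subcommands; see
`uremitox --help`.

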