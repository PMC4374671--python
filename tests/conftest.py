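import numpy as np
import pandas as pd
import pytest

import uremitox as ux
from uremitox.simulate import GeneClass

# the 2000-gene default-noise cohort used for recovery checks:
# 100 dialyzable, 275 resistant (210 of them IS-mimicked), 1625 null
RECOVERY_COUNTS = {
    GeneClass.DIALYZABLE_UP: 50,
    GeneClass.DIALYZABLE_DOWN: 50,
    GeneClass.RESISTANT_MIM_UP: 110,
    GeneClass.RESISTANT_NONMIM_UP: 30,
    GeneClass.RESISTANT_MIM_DOWN: 100,
    GeneClass.RESISTANT_NONMIM_DOWN: 35,
}


def make_cohort(replicate_sd=0.15, effect_jitter=0.1, seed=0, n_genes=2000,
                counts=None):
    if counts is None:
        total = sum(RECOVERY_COUNTS.values())
        if n_genes >= total:
            counts = RECOVERY_COUNTS
        else:  # shrink the planted classes proportionally for tiny cohorts
            f = n_genes / 2000
            counts = {k: max(1, int(v * f)) for k, v in RECOVERY_COUNTS.items()}
    cfg = ux.SimulationConfig(
        n_genes=n_genes,
        class_counts=counts,
        replicate_sd_log2=replicate_sd,
        effect_jitter_log2=effect_jitter,
        seed=seed,
    )
    truth = ux.generate_truth(cfg)
    matrix = ux.generate_expression(truth, cfg)
    return cfg, truth, matrix


@pytest.fixture(scope="session")
def noise_free_cohort():
    return make_cohort(replicate_sd=0.0, effect_jitter=0.0, seed=3)


@pytest.fixture(scope="session")
def noisy_cohort():
    return make_cohort(seed=5)


def fc_from_signed(pre, post, extra=None):
    """Build a FoldChangeTable from signed pre/post ratios (test helper)."""
    genes = [f"g{i + 1}" for i in range(len(pre))]
    cols = {
        "CONTROL": np.zeros(len(pre)),
        "PRE": [ux.log2_from_signed(v) for v in pre],
        "POST": [ux.log2_from_signed(v) for v in post],
    }
    if extra:
        for key, vals in extra.items():
            cols[key] = [ux.log2_from_signed(v) for v in vals]
    return ux.FoldChangeTable(pd.DataFrame(cols, index=genes))
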