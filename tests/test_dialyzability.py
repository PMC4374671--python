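"""Boundary classification, mimicry, reversal and the theta sweep."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import uremitox as ux
from uremitox.containers import ConfigurationError
from uremitox.dialyzability import AnalysisConfig, BoundaryRule

from conftest import fc_from_signed, make_cohort


def brute_force_classify(fc, theta):
    """Independent re-evaluation of the boundary rule as direct comparisons."""
    up_cut = np.log2(1 + theta)
    out = {"returned_up": set(), "remained_up": set(),
           "returned_down": set(), "remained_down": set()}
    for gene in fc.log2_ratios.index:
        pre = fc.log2_ratios.loc[gene, "PRE"]
        post = fc.log2_ratios.loc[gene, "POST"]
        if pre >= up_cut:
            direction = "up"
        elif pre <= -up_cut:
            direction = "down"
        else:
            continue
        fate = "returned" if (-up_cut < post < up_cut) else "remained"
        out[f"{fate}_{direction}"].add(gene)
    return out


class TestClassify:
    def test_all_unit_ratios_empty_partition(self):
        fc = fc_from_signed([1.0] * 4, [1.0] * 4)
        part = ux.classify(fc)
        assert part.n_dysregulated == 0
        assert part.counts()["n_returned"] == 0

    def test_six_gene_hand_example(self):
        fc = fc_from_signed(
            pre=[1.30, 1.30, -1.20, -1.20, 1.05, 1.0],
            post=[1.05, 1.25, 1.02, -1.30, 1.50, 1.0],
        )
        part = ux.classify(fc, AnalysisConfig(theta=0.10))
        assert part.returned_up == {"g1"}
        assert part.remained_up == {"g2"}
        assert part.returned_down == {"g3"}
        assert part.remained_down == {"g4"}
        assert part.post_only_up == {"g5"}  # pre below boundary, post above
        assert part.n_dysregulated == 4

    def test_boundary_tie_counts_as_dysregulated(self):
        fc = fc_from_signed([1.10], [1.0])
        part = ux.classify(fc, AnalysisConfig(theta=0.10))
        assert part.returned_up == {"g1"}

    def test_linear_down_rule_option(self):
        # ratio 0.905 (signed -1.105): down under linear (<= 0.90? no, 0.905>0.9)
        # use 0.895: down under both; 0.905: down under log-symmetric only
        fc = fc_from_signed([-(1 / 0.905)], [1.0])
        log_part = ux.classify(fc, AnalysisConfig(theta=0.10))
        lin_part = ux.classify(
            fc, AnalysisConfig(theta=0.10, boundary_rule=BoundaryRule.LINEAR)
        )
        assert log_part.returned_down == {"g1"}
        assert lin_part.n_dysregulated == 0

    def test_zero_noise_recovery_exact(self):
        _, truth, matrix = make_cohort(replicate_sd=0.0, effect_jitter=0.0,
                                       seed=41, n_genes=500)
        part = ux.DialyzabilityModel(matrix).fit().partition
        assert part.n_returned == 100
        assert part.n_remained == 275

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_agrees_with_brute_force_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 50)
        genes = [f"g{i}" for i in range(n)]
        fc = ux.FoldChangeTable(pd.DataFrame(
            {"CONTROL": 0.0,
             "PRE": rng.normal(0, 0.3, n),
             "POST": rng.normal(0, 0.3, n)},
            index=genes,
        ))
        theta = float(rng.uniform(0.05, 0.4))
        part = ux.classify(fc, AnalysisConfig(theta=theta))
        ref = brute_force_classify(fc, theta)
        assert part.returned_up == ref["returned_up"]
        assert part.remained_up == ref["remained_up"]
        assert part.returned_down == ref["returned_down"]
        assert part.remained_down == ref["remained_down"]
        # partition additivity
        assert part.n_returned + part.n_remained == part.n_dysregulated

    def test_missing_condition_error(self):
        fc = ux.FoldChangeTable(pd.DataFrame({"CONTROL": [0.0], "PRE": [0.5]},
                                             index=["g1"]))
        with pytest.raises(ConfigurationError):
            ux.classify(fc)


class TestMimicry:
    def test_null_is_column_gives_zero_fractions(self):
        fc = fc_from_signed([1.3, -1.3], [1.3, -1.3],
                            extra={"CONTROL_IS": [1.0, 1.0]})
        part = ux.classify(fc)
        mim = ux.mimicry(part, fc)
        assert mim.frac_up_mimicked == 0.0
        assert mim.frac_down_mimicked == 0.0

    def test_is_column_equal_to_pre_gives_full_mimicry(self):
        fc = fc_from_signed([1.3, -1.3], [1.3, -1.3],
                            extra={"CONTROL_IS": [1.3, -1.3]})
        mim = ux.mimicry(ux.classify(fc), fc)
        assert mim.frac_up_mimicked == 1.0
        assert mim.frac_down_mimicked == 1.0

    def test_empty_remained_set_reports_none(self):
        fc = fc_from_signed([1.3], [1.0], extra={"CONTROL_IS": [1.3]})
        mim = ux.mimicry(ux.classify(fc), fc)  # gene returned; nothing remained
        assert mim.frac_up_mimicked is None
        assert mim.frac_down_mimicked is None

    def test_planted_fraction_recovered_exactly_at_zero_noise(self):
        from uremitox.simulate import GeneClass

        counts = {
            GeneClass.RESISTANT_MIM_UP: 163,
            GeneClass.RESISTANT_NONMIM_UP: 37,  # 163/200 = 0.815 exactly
        }
        _, truth, matrix = make_cohort(replicate_sd=0.0, effect_jitter=0.0,
                                       seed=42, n_genes=400, counts=counts)
        res = ux.DialyzabilityModel(matrix).fit()
        assert res.mimicry.frac_up_mimicked == pytest.approx(0.815, abs=0)
        assert res.mimicry.mimicked_up <= res.partition.remained_up

    def test_missing_is_condition_error(self):
        fc = fc_from_signed([1.3], [1.3])
        with pytest.raises(ConfigurationError):
            ux.mimicry(ux.classify(fc), fc)


class TestReversal:
    def test_unit_probenecid_ratios_full_reversal(self):
        fc = fc_from_signed([1.3, -1.4], [1.3, -1.4],
                            extra={"PRE_PROB": [1.0, 1.0], "POST_PROB": [1.0, 1.0]})
        rev = ux.reversal(fc)
        assert rev.frac_reversed == {"PRE": 1.0, "POST": 1.0}

    def test_probenecid_equal_to_plain_no_reversal(self):
        fc = fc_from_signed([1.3, -1.4], [1.3, -1.4],
                            extra={"PRE_PROB": [1.3, -1.4],
                                   "POST_PROB": [1.3, -1.4]})
        rev = ux.reversal(fc)
        assert rev.frac_reversed == {"PRE": 0.0, "POST": 0.0}

    def test_planted_reversibility_recovered_at_zero_noise(self):
        _, _, matrix = make_cohort(replicate_sd=0.0, effect_jitter=0.0,
                                   seed=43, n_genes=300)
        res = ux.DialyzabilityModel(matrix).fit()
        assert res.reversal.frac_reversed == {"PRE": 1.0, "POST": 1.0}

    def test_reversed_sets_subset_of_dysregulated(self):
        _, _, matrix = make_cohort(seed=44, n_genes=300)
        res = ux.DialyzabilityModel(matrix).fit()
        pre = res.fold_change.column("PRE")
        cut = AnalysisConfig().up_cut
        dys_pre = set(pre.index[(pre >= cut) | (pre <= -cut)])
        assert res.reversal.reversed_genes["PRE"] <= dys_pre

    def test_missing_probenecid_condition_error(self):
        fc = fc_from_signed([1.3], [1.3])
        with pytest.raises(ConfigurationError):
            ux.reversal(fc)


class TestBoundarySweep:
    def test_counts_identical_when_effects_clear_both_boundaries(self):
        _, _, matrix = make_cohort(replicate_sd=0.0, effect_jitter=0.0,
                                   seed=45, n_genes=300)
        fc = ux.DialyzabilityModel(matrix).fit().fold_change
        table = ux.boundary_sweep(fc, [0.10, 0.20])
        assert table.loc[0.10].equals(table.loc[0.20])

    def test_total_dysregulated_monotone_in_theta(self):
        _, _, matrix = make_cohort(seed=46, n_genes=400)
        fc = ux.DialyzabilityModel(matrix).fit().fold_change
        table = ux.boundary_sweep(fc, [0.05, 0.10, 0.20, 0.50, 0.90])
        assert (np.diff(table["n_dysregulated"]) <= 0).all()
        assert table.loc[0.90, "n_dysregulated"] == 0  # all effects < 1-fold

    def test_empty_theta_list_rejected(self):
        fc = fc_from_signed([1.3], [1.3])
        with pytest.raises(ConfigurationError):
            ux.boundary_sweep(fc, [])


class TestModelFrontEnd:
    def test_summary_and_report(self):
        _, _, matrix = make_cohort(seed=47, n_genes=200)
        res = ux.DialyzabilityModel(matrix).fit()
        text = res.summary()
        assert "Dialyzability classification" in text
        assert "mimicry" in text.lower()
        rep = res.to_report()
        assert rep["counts"]["n_dysregulated"] == res.partition.n_dysregulated

    def test_from_files_round_trip(self, tmp_path):
        from uremitox import io

        _, truth, matrix = make_cohort(replicate_sd=0.0, effect_jitter=0.0,
                                       seed=48, n_genes=150)
        io.write_expression(matrix, tmp_path / "m.tsv")
        io.write_sample_sheet(matrix.sheet, tmp_path / "s.tsv")
        model = ux.DialyzabilityModel.from_files(tmp_path / "m.tsv",
                                                 tmp_path / "s.tsv")
        planted = truth.n_dialyzable + truth.n_resistant
        assert model.fit().partition.n_dysregulated == planted

    def test_ptm_prefilter_restricts_universe(self):
        from uremitox.profiles import Template

        _, _, matrix = make_cohort(seed=49, n_genes=300)
        templates = [
            Template("resistant_up", {"CONTROL": 0, "CONTROL_IS": 1, "PRE": 1,
                                      "POST": 1, "PRE_PROB": 0, "POST_PROB": 0}),
        ]
        plain = ux.DialyzabilityModel(matrix).fit()
        filtered = ux.DialyzabilityModel(matrix, ptm_templates=templates,
                                         ptm_min_r=0.9).fit()
        assert len(filtered.fold_change.gene_ids) < len(plain.fold_change.gene_ids)
        assert filtered.partition.n_dysregulated <= plain.partition.n_dysregulated
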