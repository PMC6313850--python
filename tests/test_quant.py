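import math

import numpy as np
import pandas as pd
import pytest

from xenoquant.core import Condition, PeptideQuantTable, StudyDesign
from xenoquant.quant import cv, max_fold_change, normalize, rollup
from xenoquant.species import SpeciesClass
from xenoquant.synth import scaled_replicate_table

from .conftest import make_table


class TestNormalize:
    def test_identical_samples_unit_factors(self):
        table = make_table(["AAAK", "CCCR"], values=[[1.0, 1.0], [5.0, 5.0]])
        norm = normalize(table)
        assert all(f == pytest.approx(1.0) for f in norm.scale_factor_by_sample.values())

    def test_global_doubling_removed(self):
        table = make_table(
            ["AAAK", "CCCR", "DDDK"],
            values=[[1.0, 2.0], [5.0, 10.0], [3.0, 6.0]],
        )
        norm = normalize(table)
        # after normalization both samples carry the same values
        assert np.allclose(norm.abundance["s1"], norm.abundance["s2"])
        ref = norm.reference_sample
        other = [s for s in norm.samples if s != ref][0]
        expected = 0.5 if ref == "s1" else 2.0
        assert norm.scale_factor_by_sample[other] == pytest.approx(expected)

    def test_planted_factors_recovered_exactly(self):
        table, factors = scaled_replicate_table(
            100, factors=[1.0, 2.0, 4.0], seed=11, noise_cv=0.0
        )
        norm = normalize(table)
        # the middle sample is the closest to the median profile
        assert norm.reference_sample == "S2"
        assert norm.scale_factor_by_sample["S2"] == 1.0
        got = np.array(
            [norm.scale_factor_by_sample[s] for s in ("S1", "S2", "S3")]
        )
        # relative factors recover the planted {1, 2, 4} scaling exactly
        assert np.allclose(got / got[0], [1.0, 0.5, 0.25], atol=1e-9)
        # all samples coincide after normalization (noise-free case)
        logs = np.log(norm.abundance.to_numpy())
        assert np.allclose(logs - logs[:, [0]], 0.0, atol=1e-9)

    def test_all_zero_sample_named_in_error(self):
        table = make_table(["AAAK"], values=[[1.0, 0.0]])
        with pytest.raises(ValueError, match="s2"):
            normalize(table)


class TestRollup:
    def test_sum_of_unique_peptides(self, toy_index):
        table = make_table(
            ["AAADK", "CCCER"], values=[[3.0, 1.0], [7.0, 2.0]]
        )
        out = rollup(table, toy_index, SpeciesClass.HUMAN_SPECIFIC)
        assert len(out) == 1
        res = out[0]
        assert res.accession == "HUM1"
        assert res.unique_peptides == 2
        assert res.abundance_by_sample == {"s1": 10.0, "s2": 3.0}

    def test_same_species_shared_peptide_contributes_to_neither(self, toy_index):
        out = rollup(
            make_table(["SSSVR"]), toy_index, SpeciesClass.HUMAN_SPECIFIC
        )
        assert out == []

    def test_hand_computed_multi_protein(self, toy_index):
        table = make_table(
            ["AAADK", "CCCER", "GGGFK", "DDDWR"],
            values=[[1.0, 0.0], [2.0, 5.0], [4.0, 6.0], [8.0, 7.0]],
        )
        out = rollup(table, toy_index, SpeciesClass.HUMAN_SPECIFIC)
        by_acc = {r.accession: r for r in out}
        # DDDWR is shared between HUM3 and MUS3 -> indistinguishable, dropped
        assert set(by_acc) == {"HUM1", "HUM3"}
        assert by_acc["HUM1"].abundance_by_sample == {"s1": 3.0, "s2": 5.0}
        assert by_acc["HUM3"].abundance_by_sample == {"s1": 4.0, "s2": 6.0}

    def test_rollup_conserves_retained_abundance(self, toy_index):
        from xenoquant.species import filter_species_specific

        table = make_table(
            ["AAADK", "CCCER", "GGGFK", "PEPTWDEK", "SSSVR"],
            values=np.arange(10, dtype=float).reshape(5, 2) + 1,
        )
        filt = filter_species_specific(
            table, toy_index, SpeciesClass.HUMAN_SPECIFIC
        )
        out = rollup(filt.retained, toy_index, SpeciesClass.HUMAN_SPECIFIC)
        for j, s in enumerate(table.samples):
            total_rolled = sum(r.abundance_by_sample[s] for r in out)
            assert total_rolled == pytest.approx(
                filt.retained.abundance[s].sum()
            )

    def test_condition_summaries_filled_with_design(self, toy_index):
        design = StudyDesign(
            pd.DataFrame(
                {
                    "sample_id": ["s1", "s2"],
                    "condition": ["tumour", "pdx_f1"],
                }
            )
        )
        table = make_table(["AAADK", "CCCER"], values=[[3.0, 1.0], [1.0, 1.0]])
        out = rollup(
            table, toy_index, SpeciesClass.HUMAN_SPECIFIC, design=design
        )
        res = out[0]
        assert res.mean_by_condition[Condition.TUMOUR] == pytest.approx(4.0)
        assert res.mean_by_condition[Condition.PDX_F1] == pytest.approx(2.0)
        assert res.max_fold_change == pytest.approx(2.0)
        assert res.higher_condition is Condition.TUMOUR


class TestMaxFoldChange:
    def test_simple_pair(self):
        fold, higher = max_fold_change(
            {Condition.TUMOUR: 10.0, Condition.PDX_F1: 20.0}
        )
        assert (fold, higher) == (2.0, Condition.PDX_F1)

    def test_pairwise_enumeration(self):
        fold, higher = max_fold_change(
            {
                Condition.ADJ_NORMAL: 8.0,
                Condition.TUMOUR: 2.0,
                Condition.PDX_F1: 4.0,
            }
        )
        assert (fold, higher) == (4.0, Condition.ADJ_NORMAL)

    def test_all_equal_ties_to_first(self):
        fold, higher = max_fold_change(
            {Condition.PDX_F1: 5.0, Condition.TUMOUR: 5.0}
        )
        assert (fold, higher) == (1.0, Condition.PDX_F1)

    def test_zero_mean_flagged_infinite(self):
        with pytest.warns(UserWarning, match="adjacent_normal"):
            fold, higher = max_fold_change(
                {Condition.ADJ_NORMAL: 0.0, Condition.TUMOUR: 3.0}
            )
        assert math.isinf(fold)
        assert higher is Condition.TUMOUR

    def test_scale_and_relabel_invariance(self):
        rng = np.random.default_rng(5)
        conds = list(Condition)
        for _ in range(20):
            means = {c: float(rng.uniform(0.1, 100)) for c in conds}
            fold, _ = max_fold_change(means)
            assert fold >= 1.0
            scaled, _ = max_fold_change({c: 7.3 * v for c, v in means.items()})
            assert scaled == pytest.approx(fold)
            perm = dict(reversed(list(means.items())))
            fold_perm, _ = max_fold_change(perm)
            assert fold_perm == pytest.approx(fold)


class TestCV:
    def test_constant_values(self):
        assert cv([10.0, 10.0, 10.0]) == 0.0

    def test_closed_form(self):
        # sd = 2*sqrt(2), mean = 10
        assert cv([8.0, 12.0]) == pytest.approx(2 * math.sqrt(2) / 10)

    def test_scale_invariance(self):
        vals = [3.0, 5.0, 9.0, 4.0]
        assert cv([7.0 * v for v in vals]) == pytest.approx(cv(vals))

    def test_undefined_cases_missing(self):
        assert math.isnan(cv([5.0]))
        assert math.isnan(cv([-1.0, 1.0]))
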