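import math

import numpy as np
import pytest
from scipy import stats

from xenoquant.core import Condition
from xenoquant.diffexp import (
    P_FLOOR,
    DECriteria,
    DifferentialResult,
    anova_oneway,
    anova_repeated,
    anova_repeated_full,
    apply_de_filters,
    stability_report,
)
from xenoquant.io import load_fixture


class TestOneWayAnova:
    def test_identical_groups_p_one(self):
        assert anova_oneway(
            {Condition.TUMOUR: [1.0, 2.0, 3.0], Condition.PDX_F1: [1.0, 2.0, 3.0]}
        ) == pytest.approx(1.0)

    def test_constant_equal_groups_p_one(self):
        assert anova_oneway(
            {Condition.TUMOUR: [2.0, 2.0], Condition.PDX_F1: [2.0, 2.0]}
        ) == 1.0

    def test_constant_different_groups_p_zero(self):
        assert anova_oneway(
            {Condition.TUMOUR: [1.0, 1.0], Condition.PDX_F1: [2.0, 2.0]}
        ) == 0.0

    def test_worked_example_closed_form(self):
        # between SS = 1.5 (1 df), within SS = 4 (4 df) -> F = 1.5
        p = anova_oneway(
            {Condition.TUMOUR: [1.0, 2.0, 3.0], Condition.PDX_F1: [2.0, 3.0, 4.0]}
        )
        assert p == pytest.approx(stats.f.sf(1.5, 1, 4))
        assert p == pytest.approx(0.2879, abs=1e-4)

    def test_too_few_groups_or_values(self):
        with pytest.raises(ValueError):
            anova_oneway({Condition.TUMOUR: [1.0, 2.0]})
        with pytest.raises(ValueError):
            anova_oneway({Condition.TUMOUR: [1.0], Condition.PDX_F1: [1.0, 2.0]})


class TestRepeatedMeasuresAnova:
    def test_constant_shift_floors_p(self):
        p = anova_repeated({"a": (1.0, 2.0), "b": (2.0, 3.0), "c": (3.0, 4.0)})
        assert p == P_FLOOR

    def test_worked_example_paired_t_oracle(self):
        full = anova_repeated_full(
            {"a": (1.0, 2.0), "b": (2.0, 4.0), "c": (3.0, 3.0)}
        )
        assert full.f_statistic == pytest.approx(3.0)
        assert full.p_value == pytest.approx(0.2254, abs=1e-4)

    def test_no_difference_p_one(self):
        assert anova_repeated({"a": (1.0, 1.0), "b": (5.0, 5.0)}) == 1.0

    def test_incomplete_subjects_dropped_and_counted(self):
        full = anova_repeated_full(
            {"a": (1.0, 2.0), "b": (2.0, 4.0), "c": (3.0, None), "d": (1.0, 3.0)}
        )
        assert full.n_subjects == 3
        assert full.n_dropped == 1

    def test_fewer_than_two_pairs_is_error(self):
        with pytest.raises(ValueError):
            anova_repeated({"a": (1.0, 2.0), "b": (2.0, None)})

    def test_f_equals_squared_paired_t(self):
        # the two-condition repeated-measures F must equal t^2 of the
        # paired t-test, with identical p-values
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(3, 12)
            a = rng.normal(size=n)
            b = a + rng.normal(0.3, 1.0, size=n)
            full = anova_repeated_full(
                {f"s{i}": (a[i], b[i]) for i in range(n)}
            )
            t = stats.ttest_rel(b, a)
            assert full.f_statistic == pytest.approx(t.statistic**2)
            assert full.p_value == pytest.approx(t.pvalue)

    def test_three_conditions_matches_statsmodels(self):
        import pandas as pd
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(9)
        n, k = 8, 3
        data = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
        full = anova_repeated_full(
            {f"s{i}": tuple(data[i]) for i in range(n)}
        )
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "cond": np.tile(np.arange(k), n),
                "y": data.ravel(),
            }
        )
        sm = AnovaRM(long, "y", "subject", within=["cond"]).fit()
        assert full.f_statistic == pytest.approx(
            float(sm.anova_table["F Value"].iloc[0])
        )
        assert full.p_value == pytest.approx(
            float(sm.anova_table["Pr > F"].iloc[0])
        )


def _result(p=0.01, peptides=2, fold=2.0, direction=Condition.TUMOUR, acc="P1"):
    return DifferentialResult(
        accession=acc,
        unique_peptides=peptides,
        p_value=p,
        fold_change=fold,
        direction=direction,
    )


class TestApplyDEFilters:
    def test_table1_fixture_all_pass(self):
        fx = load_fixture("table1")
        rows = [DifferentialResult.from_fixture_row(r) for r in fx.rows]
        passing, summary = apply_de_filters(
            rows, DECriteria(), baseline=Condition.ADJ_NORMAL
        )
        assert len(passing) == 25
        assert summary == {"up": 25, "down": 0}
        # sorted by descending fold change
        folds = [r.fold_change for r in passing]
        assert folds == sorted(folds, reverse=True)
        assert passing[0].accession == "P18564"

    def test_single_criterion_violation_fails(self):
        passing, _ = apply_de_filters(
            [_result(p=0.001, peptides=1, fold=10.0)], DECriteria()
        )
        assert passing == []

    def test_boundary_values_inclusive(self):
        passing, _ = apply_de_filters(
            [_result(p=0.05, peptides=2, fold=1.5)], DECriteria()
        )
        assert len(passing) == 1

    def test_tightening_is_monotone(self):
        rng = np.random.default_rng(1)
        rows = [
            _result(
                p=float(rng.uniform(0, 0.2)),
                peptides=int(rng.integers(1, 5)),
                fold=float(rng.uniform(1.0, 4.0)),
                acc=f"P{i}",
            )
            for i in range(50)
        ]
        base, _ = apply_de_filters(rows, DECriteria())
        base_set = {r.accession for r in base}
        for tighter in (
            DECriteria(p_threshold=0.01),
            DECriteria(min_unique_peptides=3),
            DECriteria(min_fold_change=2.5),
        ):
            sub, _ = apply_de_filters(rows, tighter)
            assert {r.accession for r in sub} <= base_set

    def test_fdr_adjustment_never_grows_passing_set(self):
        rows = [
            _result(p=p, acc=f"P{i}")
            for i, p in enumerate([0.001, 0.02, 0.04, 0.049, 0.3])
        ]
        raw, _ = apply_de_filters(rows, DECriteria())
        adj, _ = apply_de_filters(rows, DECriteria(fdr_adjust=True))
        assert {r.accession for r in adj} <= {r.accession for r in raw}


class TestStabilityReport:
    def test_table3_fixture_directions(self):
        fx = load_fixture("table3")
        rows = [DifferentialResult.from_fixture_row(r) for r in fx.rows]
        passing, _ = apply_de_filters(rows, DECriteria())
        assert len(passing) == 8
        report = stability_report(passing)
        assert report.n_higher_f2 == 5
        assert report.n_higher_f1 == 3

    def test_table3_f2_subset_stays_under_twofold(self):
        fx = load_fixture("table3")
        rows = [DifferentialResult.from_fixture_row(r) for r in fx.rows]
        passing, _ = apply_de_filters(rows, DECriteria())
        report = stability_report(passing)
        assert report.max_fold_f2_higher == pytest.approx(1.87)
        assert report.over_twofold_f2 == []
        assert report.stable
        # the F1-higher subset does exceed 2-fold (serum albumin at 5.15)
        assert report.max_fold_f1_higher == pytest.approx(5.15)
        assert "P02768" in report.over_twofold

    def test_empty_list_is_stable(self):
        report = stability_report([])
        assert report.n_higher_f2 == report.n_higher_f1 == 0
        assert report.stable
        assert math.isnan(report.max_fold_f2_higher)
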