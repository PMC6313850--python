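import dataclasses

import numpy as np
import pandas as pd
import pytest

from xenoquant.core import Condition, merge_proteomes
from xenoquant.diffexp import DECriteria
from xenoquant.digest import build_index
from xenoquant.model import XenograftComparison
from xenoquant.ordination import pca_coordinates, pearson_cluster
from xenoquant.species import SpeciesClass
from xenoquant.synth import SimConfig, simulate_study


class TestPCA:
    def test_single_protein_difference_on_pc1(self):
        mat = pd.DataFrame(
            {"s1": [1.0, 5.0], "s2": [1.0, 9.0]}, index=["pA", "pB"]
        )
        with pytest.warns(UserWarning, match="reducing"):
            coords = pca_coordinates(mat, n_components=2)
        assert coords.shape[1] == 1  # rank 1: PC2 carries no variance
        assert coords.loc["s1", "PC1"] != pytest.approx(
            coords.loc["s2", "PC1"]
        )

    def test_duplicated_sample_identical_coordinates(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(6, 3))
        mat = pd.DataFrame(base, columns=["s1", "s2", "s3"])
        mat["s4"] = mat["s2"]
        coords = pca_coordinates(mat, n_components=2)
        assert np.allclose(coords.loc["s2"], coords.loc["s4"])

    def test_matches_eigendecomposition_oracle(self):
        # 2 proteins x 4 samples: scores recoverable from the 2x2
        # covariance eigendecomposition
        mat = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [1.0, 1.0, 2.0, 0.0]],
            index=["pA", "pB"],
            columns=["s1", "s2", "s3", "s4"],
        )
        coords = pca_coordinates(mat, n_components=2)
        X = mat.to_numpy().T
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1]
        evecs = evecs[:, order]
        expected = Xc @ evecs
        for k in range(2):
            got = coords.iloc[:, k].to_numpy()
            ref = expected[:, k]
            assert np.allclose(np.abs(got), np.abs(ref), atol=1e-10)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.normal(size=(10, 5)))
        a = pca_coordinates(mat, 2)
        b = pca_coordinates(mat, 2)
        assert np.allclose(a, b)


class TestPearsonCluster:
    def test_perfectly_correlated_merge_at_zero(self):
        mat = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0], "s2": [2.0, 4.0, 6.0]}
        )
        dendro = pearson_cluster(mat)
        assert dendro.merge_heights()[0] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_merge_at_two(self):
        mat = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0], "s2": [3.0, 2.0, 1.0]}
        )
        dendro = pearson_cluster(mat)
        assert dendro.merge_heights()[0] == pytest.approx(2.0)

    def test_planted_blocks_merge_first(self):
        rng = np.random.default_rng(4)
        u, v = rng.normal(size=50), rng.normal(size=50)
        mat = pd.DataFrame(
            {
                "a1": u + rng.normal(0, 0.05, 50),
                "a2": u + rng.normal(0, 0.05, 50),
                "b1": v + rng.normal(0, 0.05, 50),
                "b2": v + rng.normal(0, 0.05, 50),
            }
        )
        dendro = pearson_cluster(mat)
        clusters = dendro.cut(2)
        assert clusters["a1"] == clusters["a2"]
        assert clusters["b1"] == clusters["b2"]
        assert clusters["a1"] != clusters["b1"]

    def test_zero_variance_sample_named(self):
        mat = pd.DataFrame({"s1": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            pearson_cluster(mat)


CFG = SimConfig(
    n_proteins=60,
    n_subjects=4,
    n_de_human=6,
    de_fold_range=(3.0, 3.0),
    n_peptides_per_protein=5,
    seed=21,
)


@pytest.fixture(scope="module")
def fitted():
    human, mouse, table, design, truth = simulate_study(CFG)
    index = build_index(merge_proteomes(human, mouse), CFG.digest_params)
    model = XenograftComparison(
        table,
        design,
        index,
        conditions=(Condition.TUMOUR, Condition.PDX_F1),
        keep=SpeciesClass.HUMAN_SPECIFIC,
    )
    return model.fit(), truth


class TestXenograftComparison:
    def test_planted_effects_dominate_passing_list(self, fitted):
        res, truth = fitted
        planted = set(truth.de_proteins)
        passing = {r.accession for r in res.passing}
        assert passing
        assert passing <= set(r.accession for r in res.results)
        assert len(passing & planted) >= len(passing) - 1

    def test_results_only_human_proteins(self, fitted):
        res, _ = fitted
        assert all(r.accession.startswith("HP") for r in res.results)

    def test_summary_mentions_counts(self, fitted):
        res, _ = fitted
        text = str(res.summary())
        assert "tumour" in text and "pdx_f1" in text
        assert f"{len(res.passing)}/{len(res.results)}" in text

    def test_frame_and_views_consistent(self, fitted):
        res, _ = fitted
        df = res.to_frame()
        assert int(df["passes"].sum()) == len(res.passing)
        mat = res.abundance_matrix()
        assert mat.shape == (len(res.passing), len(res.model.design.sample_ids))
        coords = res.pca()
        assert list(coords.index) == res.model.design.sample_ids
        cvs = res.cv_table()
        assert set(cvs.index) == {r.accession for r in res.passing}

    def test_paired_analysis_runs(self):
        human, mouse, table, design, _ = simulate_study(CFG)
        index = build_index(merge_proteomes(human, mouse), CFG.digest_params)
        res = XenograftComparison(
            table,
            design,
            index,
            conditions=(Condition.TUMOUR, Condition.PDX_F1),
            criteria=DECriteria(paired=True),
        ).fit()
        assert res.results
        assert all(0 <= r.p_value <= 1 for r in res.results if r.p_value == r.p_value)

    def test_absent_condition_rejected_before_fit(self):
        human, mouse, table, design, _ = simulate_study(
            dataclasses.replace(CFG, n_proteins=10, n_de_human=0)
        )
        sub = design.subset([Condition.TUMOUR, Condition.PDX_F1])
        index = build_index(merge_proteomes(human, mouse), CFG.digest_params)
        with pytest.raises(ValueError, match="adjacent_normal"):
            XenograftComparison(
                table.subset_samples(sub.sample_ids),
                sub,
                index,
                conditions=(Condition.ADJ_NORMAL, Condition.TUMOUR),
            )
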