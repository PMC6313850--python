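"""Model/Results interface for a two-condition xenograft comparison.

:class:`XenograftComparison` bundles the full deconvolution analysis of
one comparison — species filtering against the merged-database index,
reference-run normalization, protein roll-up, per-protein ANOVA and the
three differential-expression criteria — behind a ``fit()`` that returns
a :class:`ComparisonResults` carrying the per-protein estimates, the
passing list, removal accounting, and descriptive views (PCA, Pearson
clustering, CV tables).

Typical use::

    model = XenograftComparison(
        table, design, index,
        conditions=(Condition.TUMOUR, Condition.PDX_F1),
        keep=SpeciesClass.HUMAN_SPECIFIC,
    )
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from .core import Condition, PeptideQuantTable, Species, StudyDesign
from .diffexp import (
    DECriteria,
    DifferentialResult,
    StabilityReport,
    anova_oneway,
    anova_repeated_full,
    apply_de_filters,
    stability_report,
)
from .digest import PeptideIndex
from .ordination import Dendrogram, pca_coordinates, pearson_cluster
from .quant import NormalizedQuantTable, ProteinQuantResult, normalize, rollup
from .species import (
    FilteredQuantTable,
    PartitionReport,
    SpeciesClass,
    filter_species_specific,
    species_partition_report,
)


def _safe_log(values: np.ndarray) -> np.ndarray:
    """Natural log with zeros imputed at half the smallest positive value.

    Zero protein abundance in an aligned label-free table means below
    detection, not missing at random; the half-minimum substitution
    keeps such samples in the test at a floor value.
    """
    values = np.asarray(values, dtype=float)
    positive = values[values > 0]
    if positive.size == 0:
        return np.full_like(values, np.nan)
    floor = positive.min() / 2.0
    return np.log(np.where(values > 0, values, floor))


class XenograftComparison:
    """A species-resolved differential comparison between two conditions.

    Parameters
    ----------
    table, design, index
        The peptide quant table, the study design, and the peptide index
        built over the merged two-species database.
    conditions
        The two (or more) conditions compared; the first is the baseline
        for up/down accounting.
    keep
        Species class analysed: ``HUMAN_SPECIFIC`` for tumour-cell-derived
        evidence in xenografts, ``MOUSE_SPECIFIC`` for stroma, or
        ``INDISTINGUISHABLE`` for the shared-orthology cohort.
    criteria
        Differential-expression thresholds; ``criteria.paired`` selects
        repeated-measures ANOVA over subject-matched samples.
    expect_species
        Declare single-species input material (e.g. ``Species.HUMAN`` for
        an adjacent-normal vs tumour comparison) so that impossible
        other-species hits are flagged as false positives.
    """

    def __init__(
        self,
        table: PeptideQuantTable,
        design: StudyDesign,
        index: PeptideIndex,
        conditions: Sequence[Condition] = (
            Condition.TUMOUR,
            Condition.PDX_F1,
        ),
        keep: SpeciesClass = SpeciesClass.HUMAN_SPECIFIC,
        criteria: DECriteria = DECriteria(),
        expect_species: Optional[Species] = None,
    ):
        table.check_against_design(design)
        self.conditions = [
            c if isinstance(c, Condition) else Condition(c) for c in conditions
        ]
        missing = [
            c for c in self.conditions if not design.samples_for(c)
        ]
        if missing:
            raise ValueError(
                f"condition(s) absent from design: "
                f"{[str(c) for c in missing]}"
            )
        self.design = design.subset(self.conditions)
        self.design.require_replication(self.conditions)
        samples = self.design.sample_ids
        sub = table.subset_samples(samples)
        detected = (sub.abundance.to_numpy() > 0).any(axis=1)
        self.table = sub.subset_rows(detected)
        self.index = index
        self.keep = keep
        self.criteria = criteria
        self.expect_species = expect_species

    def fit(self) -> "ComparisonResults":
        partition = species_partition_report(
            self.table, self.index, self.expect_species
        )
        normalized = normalize(self.table, self.design)
        filtered = filter_species_specific(
            normalized.table, self.index, self.keep
        )
        proteins = rollup(
            filtered.retained,
            self.index,
            self.keep,
            self.design,
            self.conditions,
        )
        results = [self._test_protein(p) for p in proteins]
        passing, summary = apply_de_filters(
            results, self.criteria, baseline=self.conditions[0]
        )
        return ComparisonResults(
            model=self,
            proteins=proteins,
            results=results,
            passing=passing,
            up_down=summary,
            partition=partition,
            filtered=filtered,
            normalized=normalized,
        )

    # ------------------------------------------------------------------
    def _test_protein(self, protein: ProteinQuantResult) -> DifferentialResult:
        if self.criteria.paired:
            p_value = self._paired_p(protein)
        else:
            p_value = self._unpaired_p(protein)
        return DifferentialResult(
            accession=protein.accession,
            unique_peptides=protein.unique_peptides,
            p_value=p_value,
            fold_change=protein.max_fold_change,
            direction=protein.higher_condition,
            protein=protein,
        )

    def _unpaired_p(self, protein: ProteinQuantResult) -> float:
        groups = {}
        for cond in self.conditions:
            vals = [
                protein.abundance_by_sample[s]
                for s in self.design.samples_for(cond)
            ]
            groups[cond] = _safe_log(np.asarray(vals))
        if any(np.isnan(g).any() for g in groups.values()):
            return float("nan")
        return anova_oneway(groups)

    def _paired_p(self, protein: ProteinQuantResult) -> float:
        if len(self.conditions) != 2:
            raise ValueError("paired analysis is defined for 2 conditions")
        pairs, _ = self.design.pairs(*self.conditions)
        if len(pairs) < 2:
            raise ValueError(
                "paired analysis needs >= 2 complete subject pairs"
            )
        by_subject = {}
        for subj, (sa, sb) in pairs.items():
            vals = _safe_log(
                np.asarray(
                    [
                        protein.abundance_by_sample[sa],
                        protein.abundance_by_sample[sb],
                    ]
                )
            )
            by_subject[subj] = vals
        if any(np.isnan(v).any() for v in by_subject.values()):
            return float("nan")
        return anova_repeated_full(by_subject).p_value


@dataclass
class ComparisonResults:
    """Fitted comparison: per-protein tests, passing list, diagnostics."""

    model: XenograftComparison
    proteins: list[ProteinQuantResult]
    results: list[DifferentialResult]
    passing: list[DifferentialResult]
    up_down: dict[str, int]
    partition: PartitionReport
    filtered: FilteredQuantTable
    normalized: NormalizedQuantTable

    # -- tabular views -------------------------------------------------
    def to_frame(self, passing_only: bool = False) -> pd.DataFrame:
        rows = self.passing if passing_only else self.results
        records = []
        for r in rows:
            rec = {
                "accession": r.accession,
                "unique_peptides": r.unique_peptides,
                "p_value": r.p_value,
                "fold_change": r.fold_change,
                "direction": str(r.direction) if r.direction else "",
                "passes": r.passes,
            }
            if r.protein is not None:
                for cond, m in r.protein.mean_by_condition.items():
                    rec[f"mean_{cond.value}"] = m
                for cond, c in r.protein.cv_by_condition.items():
                    rec[f"cv_{cond.value}"] = c
            records.append(rec)
        df = pd.DataFrame(records)
        if not df.empty:
            df = df.sort_values(
                ["passes", "fold_change"], ascending=[False, False]
            ).reset_index(drop=True)
        return df

    def abundance_matrix(
        self, passing_only: bool = True, log: bool = True
    ) -> pd.DataFrame:
        """Protein × sample matrix of (log) rolled-up abundances."""
        rows = self.passing if passing_only else self.results
        samples = self.model.design.sample_ids
        data = {
            r.accession: [r.protein.abundance_by_sample[s] for s in samples]
            for r in rows
            if r.protein is not None
        }
        mat = pd.DataFrame(data, index=samples).T
        if log:
            mat = pd.DataFrame(
                np.vstack([_safe_log(mat.loc[a].to_numpy()) for a in mat.index])
                if len(mat)
                else mat.to_numpy(),
                index=mat.index,
                columns=mat.columns,
            )
        return mat

    def cv_table(self) -> pd.DataFrame:
        """Per-protein CV per condition over the passing proteins — the
        data behind the published violin plots."""
        records = {}
        for r in self.passing:
            if r.protein is not None:
                records[r.accession] = {
                    cond.value: c
                    for cond, c in r.protein.cv_by_condition.items()
                }
        return pd.DataFrame.from_dict(records, orient="index")

    # -- descriptive views --------------------------------------------
    def pca(self, n_components: int = 2) -> pd.DataFrame:
        return pca_coordinates(self.abundance_matrix(), n_components)

    def cluster(self) -> Dendrogram:
        return pearson_cluster(self.abundance_matrix())

    def stability(self) -> StabilityReport:
        later = (
            Condition.PDX_F2
            if Condition.PDX_F2 in self.model.conditions
            else self.model.conditions[-1]
        )
        return stability_report(self.passing, later_generation=later)

    # -- summary -------------------------------------------------------
    def summary(self, top: int = 10) -> SimpleTable:
        m = self.model
        a, b = m.conditions[0], m.conditions[-1]
        headers = ["accession", "peptides", "p-value", "fold", "highest in"]
        cells = [
            [
                r.accession,
                str(r.unique_peptides),
                f"{r.p_value:.3g}",
                f"{r.fold_change:.2f}",
                str(r.direction),
            ]
            for r in self.passing[:top]
        ]
        title = (
            f"{m.keep.value} comparison {a} vs {b}: "
            f"{len(self.passing)}/{len(self.results)} proteins pass "
            f"(up {self.up_down.get('up', 0)} / "
            f"down {self.up_down.get('down', 0)}); "
            f"{self.filtered.removed_count}/{len(m.table)} peptide rows "
            f"removed by the species filter "
            f"({self.filtered.removal_fraction:.0%})"
        )
        if not cells:
            cells = [["(none)"] + [""] * (len(headers) - 1)]
        return SimpleTable(cells, headers=headers, title=title)
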