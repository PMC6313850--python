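"""Normalization, protein roll-up, fold changes and coefficients of variation.

Normalization emulates the reference-run behaviour of label-free
alignment software: one sample is chosen as the reference (the one whose
log-abundance profile sits closest to the per-peptide median profile)
and every other sample is rescaled so its median log-ratio to the
reference, over peptides detected in both, is zero. Median-based scaling
is robust to a minority of genuinely differential peptides.

Protein abundance per sample is the sum of the abundances of the
protein's unique peptides (peptides mapping to that protein alone within
the kept species); the unique-peptide count per protein feeds the
"at least two unique peptides" identification criterion downstream.

The maximum fold change of a protein places its condition means in a
condition-vs-condition matrix and reports the largest larger/smaller
ratio over all pairs, together with the condition holding the larger
mean in that pair.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import Condition, PeptideQuantTable, StudyDesign
from .digest import PeptideIndex
from .species import SpeciesClass, _SPECIES_OF


@dataclass
class NormalizedQuantTable:
    """A quant table after reference-run median-ratio normalization."""

    table: PeptideQuantTable
    reference_sample: str
    scale_factor_by_sample: dict[str, float]

    # convenience passthroughs
    @property
    def peptides(self):
        return self.table.peptides

    @property
    def proteins(self):
        return self.table.proteins

    @property
    def abundance(self) -> pd.DataFrame:
        return self.table.abundance

    @property
    def samples(self):
        return self.table.samples

    def __len__(self) -> int:
        return len(self.table)


def _choose_reference(log_abund: pd.DataFrame) -> str:
    """Sample whose log profile has minimal summed |deviation| from the
    per-peptide median profile (zeros excluded as below-detection)."""
    median_profile = log_abund.median(axis=1, skipna=True)
    deviations = (log_abund.sub(median_profile, axis=0)).abs().sum(
        axis=0, skipna=True
    )
    return deviations.idxmin()


def normalize(
    table: PeptideQuantTable, design: Optional[StudyDesign] = None
) -> NormalizedQuantTable:
    """Median log-ratio normalization against an auto-chosen reference run.

    Zero abundances are treated as below detection limit: they are
    excluded from ratio estimation but preserved (as zero) in the
    rescaled table. A sample with no nonzero measurement is an error.
    """
    if design is not None:
        table.check_against_design(design)
    a = table.abundance
    if a.shape[1] < 2:
        raise ValueError("normalization needs at least 2 samples")
    zero_samples = [s for s in a.columns if not (a[s] > 0).any()]
    if zero_samples:
        raise ValueError(
            f"sample(s) with all-zero abundances: {zero_samples}"
        )
    log_abund = np.log(a.where(a > 0))
    reference = _choose_reference(log_abund)
    factors: dict[str, float] = {}
    for s in a.columns:
        if s == reference:
            factors[s] = 1.0
            continue
        ratios = log_abund[s] - log_abund[reference]
        ratios = ratios.dropna()
        if ratios.empty:
            warnings.warn(
                f"sample {s!r} shares no detected peptides with the "
                f"reference {reference!r}; left unscaled",
                stacklevel=2,
            )
            factors[s] = 1.0
            continue
        factors[s] = float(np.exp(-ratios.median()))
    scaled = a.mul(pd.Series(factors), axis=1)
    return NormalizedQuantTable(
        table=PeptideQuantTable(table.peptides, table.proteins, scaled),
        reference_sample=reference,
        scale_factor_by_sample=factors,
    )


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation: sample SD (n-1) over the mean.

    Returns NaN (reported missing) for fewer than two values or a
    non-positive mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        return float("nan")
    mean = arr.mean()
    if mean <= 0:
        return float("nan")
    return float(arr.std(ddof=1) / mean)


def max_fold_change(
    mean_by_condition: Mapping[Condition, float],
) -> tuple[float, Condition]:
    """Maximum pairwise ratio of condition means and its higher condition.

    All-equal means give (1.0, first condition in input order). A zero or
    negative mean makes the fold change infinite; the offending condition
    is named in a warning rather than silently dropped.
    """
    conds = list(mean_by_condition)
    if len(conds) < 2:
        raise ValueError("max fold change needs at least 2 conditions")
    bad = [c for c in conds if mean_by_condition[c] <= 0]
    if bad:
        warnings.warn(
            "non-positive condition mean(s) "
            f"{[str(c) for c in bad]}: fold change is infinite",
            stacklevel=2,
        )
        positive = [c for c in conds if mean_by_condition[c] > 0]
        higher = (
            max(positive, key=lambda c: mean_by_condition[c])
            if positive
            else conds[0]
        )
        return (math.inf, higher)
    best = (1.0, conds[0])
    for i, a in enumerate(conds):
        for b in conds[i + 1 :]:
            ma, mb = mean_by_condition[a], mean_by_condition[b]
            fold = max(ma, mb) / min(ma, mb)
            if fold > best[0]:
                best = (fold, a if ma >= mb else b)
    return best


@dataclass
class ProteinQuantResult:
    """Per-protein quantitation summary after roll-up."""

    accession: str
    species_class: SpeciesClass
    unique_peptides: int
    abundance_by_sample: dict[str, float]
    mean_by_condition: dict[Condition, float] = field(default_factory=dict)
    max_fold_change: float = float("nan")
    higher_condition: Optional[Condition] = None
    cv_by_condition: dict[Condition, float] = field(default_factory=dict)


def summarize_conditions(
    result: ProteinQuantResult,
    design: StudyDesign,
    conditions: Optional[Sequence[Condition]] = None,
) -> ProteinQuantResult:
    """Fill condition means, max fold change and per-condition CV in place."""
    conds = list(conditions) if conditions is not None else design.conditions
    means: dict[Condition, float] = {}
    cvs: dict[Condition, float] = {}
    for cond in conds:
        samples = [
            s for s in design.samples_for(cond)
            if s in result.abundance_by_sample
        ]
        vals = [result.abundance_by_sample[s] for s in samples]
        if vals:
            means[cond] = float(np.mean(vals))
            cvs[cond] = cv(vals)
    result.mean_by_condition = means
    result.cv_by_condition = cvs
    if len(means) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result.max_fold_change, result.higher_condition = max_fold_change(
                means
            )
    return result


def rollup(
    table: NormalizedQuantTable | PeptideQuantTable,
    index: PeptideIndex,
    keep: SpeciesClass,
    design: Optional[StudyDesign] = None,
    conditions: Optional[Sequence[Condition]] = None,
) -> list[ProteinQuantResult]:
    """Roll peptide abundances up to proteins.

    The table is assumed already filtered to the ``keep`` class. For
    species-specific classes each peptide contributes to the single
    protein it maps to within that species. For the indistinguishable
    class a peptide contributes to the orthologous protein *group*,
    keyed by the sorted accession tuple, only when the group is the same
    unambiguous set for the peptide (peptides touching two distinct
    groups are non-unique and contribute to neither).

    When a design is given, condition means, max fold change and CVs are
    filled for each protein; otherwise only per-sample abundances and
    unique-peptide counts are populated.
    """
    samples = table.samples
    abund = table.abundance
    per_protein_rows: dict[str, list[int]] = {}
    per_protein_peps: dict[str, set[str]] = {}
    for i, pep in enumerate(table.peptides):
        matches = index.lookup(pep)
        if not matches:
            continue
        species_seen = {sp for _, sp in matches}
        if keep in _SPECIES_OF:
            # enforce the species clause even on unfiltered input
            if species_seen != {_SPECIES_OF[keep]}:
                continue
            species = _SPECIES_OF[keep]
            accs = sorted(a for a, sp in matches if sp is species)
            if len(accs) != 1:
                continue  # non-unique within species: contributes to neither
            key = accs[0]
        else:
            if len(species_seen) < 2:
                continue
            key = ";".join(sorted(a for a, _ in matches))
        per_protein_rows.setdefault(key, []).append(i)
        per_protein_peps.setdefault(key, set()).add(
            index.params.canonicalize(pep)
        )
    results = []
    for acc in sorted(per_protein_rows):
        rows = per_protein_rows[acc]
        sums = abund.iloc[rows].sum(axis=0)
        res = ProteinQuantResult(
            accession=acc,
            species_class=keep,
            unique_peptides=len(per_protein_peps[acc]),
            abundance_by_sample={s: float(sums[s]) for s in samples},
        )
        if design is not None:
            summarize_conditions(res, design, conditions)
        results.append(res)
    return results
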