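"""Species classification of peptides and the unambiguity filter.

A merged human/mouse database lets every peptide be classified by the
species of the proteins that could produce it:

* ``HUMAN_SPECIFIC`` / ``MOUSE_SPECIFIC`` — all index matches in one
  species; such peptides resolve the tumour (human) vs stroma (mouse)
  origin of xenograft material.
* ``INDISTINGUISHABLE`` — matches span both species (typically the human
  and mouse versions of an orthologous protein); these cannot resolve
  origin and are analysed as a separate cohort.
* ``UNMAPPED`` — not derivable from the database under the current
  digestion model (e.g. a semi-tryptic artefact); excluded downstream.

The unambiguity rule applied before protein-level quantitation has two
clauses: the peptide must be species-unambiguous, and within that species
it must map to exactly one protein accession. Peptides shared by two
same-species paralogues survive the species clause but fail the
single-protein clause; they are counted separately, not silently dropped.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

from .core import PeptideQuantTable, Species
from .digest import PeptideIndex


class SpeciesClass(enum.Enum):
    HUMAN_SPECIFIC = "human_specific"
    MOUSE_SPECIFIC = "mouse_specific"
    INDISTINGUISHABLE = "indistinguishable"
    UNMAPPED = "unmapped"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_SPECIFIC_OF = {
    Species.HUMAN: SpeciesClass.HUMAN_SPECIFIC,
    Species.MOUSE: SpeciesClass.MOUSE_SPECIFIC,
}
_SPECIES_OF = {
    SpeciesClass.HUMAN_SPECIFIC: Species.HUMAN,
    SpeciesClass.MOUSE_SPECIFIC: Species.MOUSE,
}


def classify_peptide(peptide: str, index: PeptideIndex) -> SpeciesClass:
    """Three-way species class of a peptide under the merged index."""
    matches = index.lookup(peptide)
    if not matches:
        return SpeciesClass.UNMAPPED
    species = {sp for _, sp in matches}
    if len(species) > 1:
        return SpeciesClass.INDISTINGUISHABLE
    return _SPECIFIC_OF[next(iter(species))]


@dataclass
class FilteredQuantTable:
    """Outcome of the species/unambiguity filter on a quant table."""

    retained: PeptideQuantTable
    kept_class: SpeciesClass
    removed_count: int
    removal_fraction: float
    ambiguous_within_species_count: int = 0

    @property
    def retained_count(self) -> int:
        return len(self.retained) if self.retained is not None else 0


def filter_species_specific(
    table: PeptideQuantTable, index: PeptideIndex, keep: SpeciesClass
) -> FilteredQuantTable:
    """Retain rows of one species class, applying the unambiguity rule.

    For the species-specific classes a retained peptide must additionally
    map to exactly one protein accession within the kept species; rows
    failing only that clause are counted in
    ``ambiguous_within_species_count``. For ``INDISTINGUISHABLE`` the
    single-protein clause does not apply (origin is unresolvable anyway).
    """
    if keep is SpeciesClass.UNMAPPED:
        raise ValueError("cannot keep the UNMAPPED class")
    mask = []
    n_ambiguous = 0
    for pep in table.peptides:
        cls = classify_peptide(pep, index)
        if cls is not keep:
            mask.append(False)
            continue
        if keep in _SPECIES_OF:
            species = _SPECIES_OF[keep]
            accs = {a for a, sp in index.lookup(pep) if sp is species}
            if len(accs) != 1:
                n_ambiguous += 1
                mask.append(False)
                continue
        mask.append(True)
    retained = table.subset_rows(mask)
    total = len(table)
    removed = total - len(retained)
    if total and not len(retained):
        warnings.warn(
            f"species filter retained no rows for class {keep}", stacklevel=2
        )
    return FilteredQuantTable(
        retained=retained,
        kept_class=keep,
        removed_count=removed,
        removal_fraction=(removed / total) if total else 0.0,
        ambiguous_within_species_count=n_ambiguous,
    )


@dataclass
class PartitionReport:
    """Row counts per species class, with integrity flags.

    When the material is declared single-species (``expect_species``),
    any rows specific to the other species are physically impossible and
    are flagged as false-positive identifications.
    """

    counts: dict[SpeciesClass, int]
    total: int
    expect_species: Species | None = None
    flags: list[str] = field(default_factory=list)

    def __getitem__(self, cls: SpeciesClass) -> int:
        return self.counts[cls]

    @property
    def indistinguishable_fraction(self) -> float:
        if not self.total:
            return 0.0
        return self.counts[SpeciesClass.INDISTINGUISHABLE] / self.total


def species_partition_report(
    table: PeptideQuantTable,
    index: PeptideIndex,
    expect_species: Species | None = None,
) -> PartitionReport:
    """Partition every row of a quant table by species class.

    The four classes are exhaustive and exclusive, so the counts sum to
    the row count.
    """
    counts = {cls: 0 for cls in SpeciesClass}
    for pep in table.peptides:
        counts[classify_peptide(pep, index)] += 1
    flags: list[str] = []
    if expect_species is not None:
        impossible = (
            SpeciesClass.MOUSE_SPECIFIC
            if expect_species is Species.HUMAN
            else SpeciesClass.HUMAN_SPECIFIC
        )
        if counts[impossible] > 0:
            flags.append(
                f"{counts[impossible]} {impossible.value} row(s) in material "
                f"declared {expect_species.value}-only: false-positive "
                "identifications"
            )
    return PartitionReport(
        counts=counts,
        total=len(table),
        expect_species=expect_species,
        flags=flags,
    )
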