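"""Core data containers for species-resolved xenograft proteomics.

The analysis operates on four containers: species-tagged protein
collections (the merged two-species search space), a peptide-level
abundance table in wide format (one row per peptide ion, one column per
sample), a study design mapping samples to experimental conditions and
subjects, and transcriptions of published result tables used as fixtures.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

# 20 canonical residues; X marks an undetermined residue and is tolerated
# in input sequences but never supports a species assignment.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


class Species(enum.Enum):
    """Species of origin of a protein sequence in the merged database."""

    HUMAN = "human"
    MOUSE = "mouse"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Condition(str, enum.Enum):
    """Experimental groups of the four-arm xenograft study design.

    ``ADJ_NORMAL``
        adjacent-normal pancreas resected with the tumour;
    ``TUMOUR``
        primary patient tumour;
    ``PDX_F1`` / ``PDX_F2``
        first- and second-generation patient-derived xenografts grown in
        immunodeficient mice (F2 engrafted with an F1 fragment).
    """

    ADJ_NORMAL = "adjacent_normal"
    TUMOUR = "tumour"
    PDX_F1 = "pdx_f1"
    PDX_F2 = "pdx_f2"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def validate_sequence(sequence: str, accession: str = "?") -> str:
    """Uppercase and validate an amino-acid sequence.

    Raises ``ValueError`` on an empty sequence or characters outside the
    20-letter alphabet plus X.
    """
    seq = re.sub(r"\s+", "", sequence).upper()
    if not seq:
        raise ValueError(f"empty sequence for protein {accession!r}")
    bad = set(seq) - _VALID_RESIDUES
    if bad:
        raise ValueError(
            f"protein {accession!r} contains non-amino-acid characters: "
            f"{sorted(bad)}"
        )
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence with an explicit species tag."""

    accession: str
    species: Species
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", validate_sequence(self.sequence, self.accession)
        )


class SpeciesProteome:
    """An ordered collection of :class:`ProteinRecord` with unique accessions.

    May hold one species (a source database) or two (the merged search
    space used to decide species specificity).
    """

    def __init__(self, records: Iterable[ProteinRecord]):
        self.records: list[ProteinRecord] = list(records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.accession in seen:
                raise ValueError(f"duplicate accession {rec.accession!r}")
            seen.add(rec.accession)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def species_counts(self) -> dict[Species, int]:
        counts = {sp: 0 for sp in Species}
        for rec in self.records:
            counts[rec.species] += 1
        return {sp: n for sp, n in counts.items() if n}

    @property
    def accessions(self) -> list[str]:
        return [rec.accession for rec in self.records]

    def single_species(self) -> Optional[Species]:
        counts = self.species_counts
        if len(counts) == 1:
            return next(iter(counts))
        return None


def merge_proteomes(
    human: SpeciesProteome, mouse: SpeciesProteome
) -> SpeciesProteome:
    """Merge two single-species collections into one dual-species database.

    Species tags are retained, the record count is conserved, and an
    accession shared across the two inputs is an error — the source
    databases are distinct and must not collide.
    """
    for proteome, expected in ((human, Species.HUMAN), (mouse, Species.MOUSE)):
        present = set(proteome.species_counts)
        if present - {expected}:
            raise ValueError(
                f"expected a single-species proteome tagged {expected}, "
                f"found {sorted(s.value for s in present)}"
            )
    shared = set(human.accessions) & set(mouse.accessions)
    if shared:
        raise ValueError(
            f"accession collision across species: {sorted(shared)[:5]}"
        )
    return SpeciesProteome(list(human.records) + list(mouse.records))


class PeptideQuantTable:
    """Peptide-level abundance matrix across samples, wide format.

    One row per peptide ion carrying the peptide sequence, the set of
    protein accessions the upstream identification engine matched it to,
    and one non-negative abundance per sample.
    """

    def __init__(
        self,
        peptides: Sequence[str],
        proteins: Sequence[Iterable[str]],
        abundance: pd.DataFrame,
    ):
        if not (len(peptides) == len(proteins) == len(abundance)):
            raise ValueError("peptides, proteins and abundance row counts differ")
        self.peptides = [str(p).upper() for p in peptides]
        self.proteins = [frozenset(p) for p in proteins]
        for i, accs in enumerate(self.proteins):
            if not accs:
                raise ValueError(
                    f"row {i} ({self.peptides[i]}) has no matched accessions"
                )
        abundance = abundance.reset_index(drop=True).astype(float)
        if (abundance.to_numpy() < 0).any():
            raise ValueError("negative abundances are not allowed")
        self.abundance = abundance

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)

    def subset_rows(self, mask: Sequence[bool]) -> "PeptideQuantTable":
        mask = np.asarray(mask, dtype=bool)
        idx = np.flatnonzero(mask)
        return PeptideQuantTable(
            [self.peptides[i] for i in idx],
            [self.proteins[i] for i in idx],
            self.abundance.iloc[idx],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "PeptideQuantTable":
        missing = [s for s in sample_ids if s not in self.abundance.columns]
        if missing:
            raise KeyError(f"samples absent from table: {missing}")
        return PeptideQuantTable(
            self.peptides, self.proteins, self.abundance[list(sample_ids)]
        )

    def check_against_design(self, design: "StudyDesign") -> None:
        unknown = set(self.samples) - set(design.sample_ids)
        if unknown:
            raise ValueError(
                f"quant table references samples absent from design: "
                f"{sorted(unknown)}"
            )


class StudyDesign:
    """Sample → condition / subject mapping.

    A ``subject_id`` shared by samples in two conditions defines a matched
    pair for repeated-measures analysis; samples without a subject are
    unpaired.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"sample_id", "condition"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"study design missing columns: {sorted(missing)}")
        table = table.copy().reset_index(drop=True)
        if "subject_id" not in table.columns:
            table["subject_id"] = pd.NA
        table["condition"] = table["condition"].map(
            lambda c: c if isinstance(c, Condition) else Condition(str(c))
        )
        if table["sample_id"].duplicated().any():
            dups = table.loc[table["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")
        self.table = table

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def conditions(self) -> list[Condition]:
        seen: list[Condition] = []
        for c in self.table["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def samples_for(self, condition: Condition) -> list[str]:
        rows = self.table[self.table["condition"] == condition]
        return list(rows["sample_id"])

    def condition_of(self, sample_id: str) -> Condition:
        rows = self.table[self.table["sample_id"] == sample_id]
        if rows.empty:
            raise KeyError(f"sample {sample_id!r} absent from design")
        return rows["condition"].iloc[0]

    def subset(self, conditions: Sequence[Condition]) -> "StudyDesign":
        mask = self.table["condition"].isin(list(conditions))
        return StudyDesign(self.table[mask])

    def pairs(
        self, cond_a: Condition, cond_b: Condition
    ) -> tuple[dict[str, tuple[str, str]], int]:
        """Complete subject pairs across two conditions.

        Returns ``(pairs, n_dropped)`` where ``pairs`` maps subject id to
        the (sample in ``cond_a``, sample in ``cond_b``) pair, and
        ``n_dropped`` counts subjects present in only one of the two
        conditions (these are excluded from paired testing).
        """
        by_cond: dict[Condition, dict[str, str]] = {cond_a: {}, cond_b: {}}
        for _, row in self.table.iterrows():
            cond, subj = row["condition"], row["subject_id"]
            if cond in by_cond and pd.notna(subj):
                by_cond[cond][str(subj)] = row["sample_id"]
        subjects_a, subjects_b = by_cond[cond_a], by_cond[cond_b]
        shared = sorted(set(subjects_a) & set(subjects_b))
        dropped = len(set(subjects_a) ^ set(subjects_b))
        return {s: (subjects_a[s], subjects_b[s]) for s in shared}, dropped

    def require_replication(self, conditions: Sequence[Condition]) -> None:
        for cond in conditions:
            n = len(self.samples_for(cond))
            if n < 2:
                raise ValueError(
                    f"condition {cond} has {n} sample(s); differential "
                    "comparison needs at least 2 per condition"
                )


@dataclass(frozen=True)
class FixtureRow:
    """One row of a transcribed published result table."""

    accession: str
    protein_name: str
    gene: str
    peptides: int
    p_value: float
    fold_change: float
    highest_in: Optional[str] = None


@dataclass(frozen=True)
class PrintedTableFixture:
    """A transcribed published result table shipped with the package."""

    name: str
    rows: tuple[FixtureRow, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.rows)
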