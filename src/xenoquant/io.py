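"""Readers and writers for FASTA proteomes, quant/design tables and fixtures.

File formats
------------
* Protein collections: standard FASTA. UniProt ``sp|ACC|NAME`` headers and
  bare-accession headers are both accepted; the accession is the first
  header token (middle field for the UniProt dialect).
* Peptide quant table: tab-separated, columns ``peptide``, ``proteins``
  (semicolon-separated accessions), then one abundance column per sample.
* Study design: tab-separated, columns ``sample_id``, ``condition``
  (one of ``adjacent_normal``/``tumour``/``pdx_f1``/``pdx_f2``) and an
  optional ``subject_id``.
* Fixtures: published result tables transcribed as tab-separated resources
  shipped inside the package and verified by checksum on load.
"""

from __future__ import annotations

import hashlib
import io
from importlib import resources
from pathlib import Path
from typing import Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    Condition,
    FixtureRow,
    PeptideQuantTable,
    PrintedTableFixture,
    ProteinRecord,
    Species,
    SpeciesProteome,
    StudyDesign,
)

PathLike = Union[str, Path]

_FIXTURE_CHECKSUMS = {
    "table1": "2d98d5dd6468ae8fe1bf5acc6a556058707612362de22cd4bfa4906dcdc98bb6",
    "table2": "ac9b174cb2f2ae211c280fe065985bd75d996d6fd7fb30187a45d8ab559f4668",
    "table3": "276250a20c038e87f38e9549cc370aa2990f1847676af7260ec1e7b8ebd95810",
}
_FIXTURE_ROW_COUNTS = {"table1": 25, "table2": 32, "table3": 8}
# Tables 1 and 2 list only proteins higher in one arm; the direction is
# stated in the table captions rather than a column.
_FIXTURE_DIRECTION = {
    "table1": Condition.TUMOUR,
    "table2": Condition.PDX_F1,
    "table3": None,
}


def parse_fasta_accession(header: str) -> str:
    """Accession from a FASTA header: first token, UniProt dialect aware."""
    token = header.split()[0]
    if token.count("|") >= 2:  # sp|ACC|NAME or tr|ACC|NAME
        return token.split("|")[1]
    return token


def read_fasta(path: PathLike, species: Species) -> SpeciesProteome:
    """Read a single-species FASTA file into a tagged proteome.

    Raises on an empty file, a duplicate accession (named in the error)
    or residues outside the amino-acid alphabet (X tolerated).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = parse_fasta_accession(rec.description or rec.id)
        records.append(ProteinRecord(accession, species, str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return SpeciesProteome(records)


def write_fasta(proteome: SpeciesProteome, path: PathLike) -> None:
    seq_records = [
        SeqRecord(
            Seq(rec.sequence),
            id=rec.accession,
            description=f"species={rec.species.value}",
        )
        for rec in proteome
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_quant_table(
    path: PathLike, design: StudyDesign | None = None
) -> PeptideQuantTable:
    """Read a tab-separated peptide quant table.

    When a design is supplied, every sample column must appear in it.
    """
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "proteins": str})
    for col in ("peptide", "proteins"):
        if col not in df.columns:
            raise ValueError(f"quant table missing required column {col!r}")
    sample_cols = [c for c in df.columns if c not in ("peptide", "proteins")]
    if not sample_cols:
        raise ValueError("quant table has no sample columns")
    proteins = [
        frozenset(filter(None, str(cell).split(";"))) for cell in df["proteins"]
    ]
    table = PeptideQuantTable(
        list(df["peptide"]), proteins, df[sample_cols].fillna(0.0)
    )
    if design is not None:
        table.check_against_design(design)
    return table


def write_quant_table(table: PeptideQuantTable, path: PathLike) -> None:
    df = table.abundance.copy()
    df.insert(0, "proteins", [";".join(sorted(p)) for p in table.proteins])
    df.insert(0, "peptide", table.peptides)
    df.to_csv(path, sep="\t", index=False)


def read_design(path: PathLike) -> StudyDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "condition" not in df.columns:
        raise ValueError(
            "study design requires 'sample_id' and 'condition' columns"
        )
    return StudyDesign(df)


def write_design(design: StudyDesign, path: PathLike) -> None:
    df = design.table.copy()
    df["condition"] = [c.value for c in df["condition"]]
    df.to_csv(path, sep="\t", index=False)


def load_fixture(name: str) -> PrintedTableFixture:
    """Load a packaged transcription of a published result table.

    ``name`` is one of ``table1`` (top 25 proteins higher in primary
    tumour vs adjacent-normal), ``table2`` (32 human-specific proteins
    higher in PDX F1 vs primary tumour) or ``table3`` (8 human-specific
    proteins differential between PDX F1 and F2). The file checksum and
    row count are verified so a corrupted transcription fails loudly.
    """
    if name not in _FIXTURE_CHECKSUMS:
        raise KeyError(
            f"unknown fixture {name!r}; available: "
            f"{sorted(_FIXTURE_CHECKSUMS)}"
        )
    data = (
        resources.files("xenoquant").joinpath(f"data/{name}.tsv").read_bytes()
    )
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_CHECKSUMS[name]:
        raise ValueError(f"fixture {name!r} checksum mismatch: {digest}")
    df = pd.read_csv(io.BytesIO(data), sep="\t", dtype={"accession": str})
    default_dir = _FIXTURE_DIRECTION[name]
    rows = []
    for _, r in df.iterrows():
        highest = (
            Condition(r["highest_in"])
            if "highest_in" in df.columns
            else default_dir
        )
        rows.append(
            FixtureRow(
                accession=r["accession"],
                protein_name=r["protein_name"],
                gene=r["gene"],
                peptides=int(r["peptides"]),
                p_value=float(r["p_value"]),
                fold_change=float(r["fold_change"]),
                highest_in=highest,
            )
        )
    if len(rows) != _FIXTURE_ROW_COUNTS[name]:
        raise ValueError(
            f"fixture {name!r} has {len(rows)} rows, expected "
            f"{_FIXTURE_ROW_COUNTS[name]}"
        )
    return PrintedTableFixture(name=name, rows=tuple(rows))
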