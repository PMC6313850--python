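"""In-silico tryptic digestion and the peptide → (protein, species) index.

The index answers the question at the heart of xenograft deconvolution:
given a peptide sequence, which proteins of which species could have
produced it? A peptide derivable only from human proteins is
human-specific evidence; one derivable from both species is
species-indistinguishable and cannot resolve tumour (human) from stroma
(mouse) origin.

Digestion is fully specific trypsin: cleavage after K or R except when
the next residue is proline, with a configurable number of missed
cleavages. Isoleucine and leucine are isobaric and indistinguishable by
the MS/MS workflow, so by default peptide sequences are canonicalized
with I/L folded together — a peptide whose orthologs differ only by an
I↔L substitution is treated as matching both, which is the conservative
reading of an "omitted if it matches both species" rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .core import AMINO_ACIDS, Species, SpeciesProteome, validate_sequence

_RESIDUES = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class DigestParams:
    """Parameters of the in-silico digestion.

    max_missed_cleavages : allowed uncut internal K/R sites (default 2).
    min_length, max_length : retained peptide length window; 6–50 is the
        usual detectable tryptic range.
    il_equivalent : fold I and L together when indexing and querying.
    """

    enzyme: str = "trypsin"
    max_missed_cleavages: int = 2
    min_length: int = 6
    max_length: int = 50
    il_equivalent: bool = True

    def __post_init__(self) -> None:
        if self.enzyme != "trypsin":
            raise ValueError(f"unsupported enzyme {self.enzyme!r}")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.min_length < 1 or self.min_length > self.max_length:
            raise ValueError("require 1 <= min_length <= max_length")

    def canonicalize(self, peptide: str) -> str:
        pep = peptide.upper()
        if self.il_equivalent:
            pep = pep.replace("I", "L")
        return pep


def cleavage_sites(sequence: str) -> list[int]:
    """0-based positions i such that trypsin cuts between i and i+1.

    K or R not followed by P; the protein C-terminus is not a site.
    """
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(sequence: str, params: DigestParams = DigestParams()) -> list[str]:
    """Fully-specific tryptic peptides of one protein.

    Peptides carry 0..``max_missed_cleavages`` internal missed sites and
    are filtered to the configured length window. Output order is
    N-terminal to C-terminal start position, then by missed-cleavage
    count; a peptide occurring at two positions is emitted once per
    position. Sequences are validated against the amino-acid alphabet.
    """
    seq = validate_sequence(sequence)
    bounds = [0] + [i + 1 for i in cleavage_sites(seq)] + [len(seq)]
    n_frag = len(bounds) - 1
    peptides: list[str] = []
    for start in range(n_frag):
        for missed in range(min(params.max_missed_cleavages, n_frag - start - 1) + 1):
            pep = seq[bounds[start] : bounds[start + missed + 1]]
            if params.min_length <= len(pep) <= params.max_length:
                peptides.append(pep)
    return peptides


@dataclass
class PeptideIndex:
    """Map canonical peptide → set of (accession, species) source proteins."""

    entries: dict[str, set[tuple[str, Species]]] = field(default_factory=dict)
    params: DigestParams = field(default_factory=DigestParams)

    def lookup(self, peptide: str) -> set[tuple[str, Species]]:
        """Exact-match source set under the index's canonicalization.

        Case-insensitive; peptides containing X never match (an undefined
        residue cannot support a species call). Unknown peptides return
        the empty set.
        """
        pep = self.params.canonicalize(peptide)
        if "X" in pep:
            return set()
        return set(self.entries.get(pep, ()))

    def __len__(self) -> int:
        return len(self.entries)


def build_index(
    proteome: SpeciesProteome, params: DigestParams = DigestParams()
) -> PeptideIndex:
    """Digest every protein and record every (peptide, protein) pair.

    Peptides containing X are excluded from the index entirely.
    """
    entries: dict[str, set[tuple[str, Species]]] = {}
    for rec in proteome:
        for pep in digest(rec.sequence, params):
            if "X" in pep:
                continue
            canon = params.canonicalize(pep)
            entries.setdefault(canon, set()).add((rec.accession, rec.species))
    return PeptideIndex(entries=entries, params=params)


def lookup(index: PeptideIndex, peptide: str) -> set[tuple[str, Species]]:
    """Functional alias for :meth:`PeptideIndex.lookup`."""
    return index.lookup(peptide)


def theoretical_peptide_count(n_internal_sites: int, max_missed: int) -> int:
    """Number of length-unfiltered peptides for ``c`` internal sites.

    With c internal cleavage sites and m >= missed allowance, digestion
    yields sum_{k=0..min(c, m)} (c + 1 - k) peptides.
    """
    c = n_internal_sites
    return sum(c + 1 - k for k in range(min(c, max_missed) + 1))
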