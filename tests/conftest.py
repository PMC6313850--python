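"""Shared fixtures: hand-built toy proteomes and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from xenoquant.core import (
    PeptideQuantTable,
    ProteinRecord,
    Species,
    SpeciesProteome,
    merge_proteomes,
)
from xenoquant.digest import DigestParams, build_index, cleavage_sites


@pytest.fixture
def toy_params() -> DigestParams:
    # short toy sequences: disable the length filter
    return DigestParams(min_length=1, max_length=100)


@pytest.fixture
def toy_index(toy_params):
    """Merged index over a hand-designed human/mouse pair.

    HUM1 "AAADKCCCER"  : peptides AAADK, CCCER (+ missed forms) human-only
    HUM2 / MUS2 share "PEPTWDEK" exactly        : indistinguishable
    HUM3 "GGGFK..." vs MUS3 "GGGYK..."          : species-specific forms
    HUM4 and HUM5 share peptide "SSSVR"         : same-species paralogues
    """
    human = SpeciesProteome(
        [
            ProteinRecord("HUM1", Species.HUMAN, "AAADKCCCER"),
            ProteinRecord("HUM2", Species.HUMAN, "PEPTWDEK"),
            ProteinRecord("HUM3", Species.HUMAN, "GGGFKDDDWR"),
            ProteinRecord("HUM4", Species.HUMAN, "SSSVRMMMEK"),
            ProteinRecord("HUM5", Species.HUMAN, "SSSVRQQQTK"),
        ]
    )
    mouse = SpeciesProteome(
        [
            ProteinRecord("MUS2", Species.MOUSE, "PEPTWDEK"),
            ProteinRecord("MUS3", Species.MOUSE, "GGGYKDDDWR"),
        ]
    )
    return build_index(merge_proteomes(human, mouse), toy_params)


def make_table(peptides, samples=("s1", "s2"), values=None, proteins=None):
    n = len(peptides)
    if values is None:
        values = np.ones((n, len(samples)))
    if proteins is None:
        proteins = [{"ANY"}] * n
    return PeptideQuantTable(
        peptides, proteins, pd.DataFrame(values, columns=list(samples))
    )


def brute_force_digest(sequence: str, params: DigestParams) -> list[str]:
    """Independent digestion oracle: enumerate every substring, keep those
    bounded by termini or cleavage sites with at most ``max_missed``
    internal cleavage sites, then length-filter."""
    sites = set(cleavage_sites(sequence))
    bounds = {-1, len(sequence) - 1} | sites
    out = []
    for start in range(len(sequence)):
        for end in range(start, len(sequence)):
            if (start - 1) not in bounds or end not in bounds:
                continue
            internal = sum(1 for i in sites if start <= i < end)
            if internal > params.max_missed_cleavages:
                continue
            if params.min_length <= end - start + 1 <= params.max_length:
                out.append(sequence[start : end + 1])
    return out


def brute_force_classify(peptide: str, proteome, params: DigestParams):
    """Classification oracle: digest every protein directly and test
    membership of the canonicalized peptide."""
    canon = params.canonicalize
    target = canon(peptide)
    if "X" in target:
        return set()
    hits = set()
    for rec in proteome:
        peps = {
            canon(p)
            for p in brute_force_digest(rec.sequence, params)
            if "X" not in p
        }
        if target in peps:
            hits.add((rec.accession, rec.species))
    return hits


def random_proteome_pair(rng, n_proteins=5, length=40, identity=0.85):
    from xenoquant.synth import make_ortholog, random_protein

    human, mouse = [], []
    for i in range(n_proteins):
        seq = random_protein(length, rng)
        human.append(ProteinRecord(f"H{i}", Species.HUMAN, seq))
        mouse.append(
            ProteinRecord(
                f"M{i}", Species.MOUSE, make_ortholog(seq, identity, rng)
            )
        )
    return SpeciesProteome(human), SpeciesProteome(mouse)
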