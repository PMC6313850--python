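"""Synthetic xenograft studies with known ground truth.

The generator emulates the statistical structure the deconvolution
analysis assumes, without pretending to be a mass spectrometer:

* a human proteome of random sequences and a mouse proteome of
  per-protein orthologs, with per-residue identity drawn from a mixture
  spanning 0.60–0.99 (mean ~0.85) — orthology is heterogeneous, and the
  species-indistinguishable peptide fraction depends on the mixture's
  shape, not just its mean;
* four sample groups: adjacent-normal, primary tumour, and two PDX
  generations, with 9 of 10 subjects patient-matched by default;
* binary tissue compartments: each protein belongs to a cancer
  (epithelial) or stromal compartment. Patient samples express both
  compartments from human sequences; in PDX samples the human stroma is
  replaced by the mouse orthologs of the stromal proteins, so
  human-specific peptides in a PDX can only come from tumour cells;
* log-normal protein abundances with condition-specific CVs (tumour CV
  below adjacent-normal CV), planted multiplicative fold changes on
  cancer-compartment proteins, per-peptide ionization efficiencies,
  multiplicative measurement noise, and planted per-sample scale
  factors for the normalization stage to recover.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    AMINO_ACIDS,
    Condition,
    PeptideQuantTable,
    ProteinRecord,
    Species,
    SpeciesProteome,
    StudyDesign,
)
from .digest import DigestParams, build_index, digest

# Approximate vertebrate amino-acid background frequencies.
_AA_FREQ = {
    "A": 8.3, "R": 5.5, "N": 4.0, "D": 5.4, "C": 1.4, "Q": 3.9, "E": 6.8,
    "G": 7.1, "H": 2.3, "I": 6.0, "L": 9.7, "K": 5.8, "M": 2.4, "F": 3.9,
    "P": 4.7, "S": 6.6, "T": 5.3, "W": 1.1, "Y": 2.9, "V": 6.9,
}
_AA = np.array(list(_AA_FREQ))
_AA_P = np.array(list(_AA_FREQ.values()))
_AA_P = _AA_P / _AA_P.sum()

#: Default ortholog identity mixture: heterogeneous, mean ~0.85.
DEFAULT_IDENTITY_MIXTURE: tuple[tuple[float, float], ...] = (
    (0.60, 0.10),
    (0.78, 0.20),
    (0.85, 0.30),
    (0.93, 0.25),
    (0.99, 0.15),
)


@dataclass(frozen=True)
class SimConfig:
    """Study-generator configuration.

    The defaults encode the study conditions the analysis targets:
    10 subjects with 9 matched adjacent-normal specimens, four arms,
    heterogeneous human/mouse orthology, tumour group less variable than
    adjacent-normal, and planted fold changes at or above the 1.5-fold
    reporting threshold.
    """

    n_proteins: int = 200
    ortholog_identity_distribution: tuple[tuple[float, float], ...] = (
        DEFAULT_IDENTITY_MIXTURE
    )
    n_subjects: int = 10
    matched_fraction: float = 0.9
    stromal_fraction_tumour: float = 0.5
    stromal_fraction_pdx: float = 0.4
    n_de_human: int = 20
    de_fold_range: tuple[float, float] = (1.5, 4.0)
    de_conditions: tuple[Condition, Condition] = (
        Condition.TUMOUR,
        Condition.PDX_F1,
    )
    abundance_mu_sigma: tuple[float, float] = (13.8, 1.2)
    cv_by_condition: dict[Condition, float] = field(
        default_factory=lambda: {
            Condition.ADJ_NORMAL: 0.45,
            Condition.TUMOUR: 0.30,
            Condition.PDX_F1: 0.25,
            Condition.PDX_F2: 0.25,
        }
    )
    seed: int = 0
    # mechanics of peptide emission
    protein_length_mean: float = 160.0
    protein_length_sd: float = 40.0
    n_peptides_per_protein: int = 10
    peptide_noise_cv: float = 0.1
    sample_scale_sigma: float = 0.25
    digest_params: DigestParams = field(default_factory=DigestParams)

    def __post_init__(self) -> None:
        for name in (
            "matched_fraction",
            "stromal_fraction_tumour",
            "stromal_fraction_pdx",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_proteins < 1 or self.n_subjects < 2:
            raise ValueError("need n_proteins >= 1 and n_subjects >= 2")
        lo, hi = self.de_fold_range
        if not 1.0 <= lo <= hi:
            raise ValueError("de_fold_range must satisfy 1 <= lo <= hi")
        weights = [w for _, w in self.ortholog_identity_distribution]
        if not weights or min(weights) < 0 or sum(weights) <= 0:
            raise ValueError("identity mixture weights must be non-negative")
        for ident, _ in self.ortholog_identity_distribution:
            if not 0.0 <= ident <= 1.0:
                raise ValueError("identities must be in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery testing."""

    #: accession -> (condition pair, noise-free mean ratio, higher condition)
    de_proteins: dict[str, tuple[tuple[Condition, Condition], float, Condition]]
    #: planted multiplicative effect per DE accession (before compartment
    #: weights); equals the noise-free ratio whenever the compared
    #: conditions weight the cancer compartment equally
    planted_fold: dict[str, float]
    #: species of origin of each emitted row (a set: a peptide conserved
    #: between an expressed human protein and an expressed mouse ortholog
    #: is one row fed by both)
    row_origin: list[set[Species]]
    #: source protein accessions per row
    row_sources: list[set[str]]
    scale_factor_by_sample: dict[str, float]
    compartment_by_accession: dict[str, str]


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_AA, size=length, p=_AA_P))


def make_ortholog(
    human_sequence: str,
    identity: float,
    seed: int | np.random.Generator,
) -> str:
    """Mutate a sequence to a target per-residue identity.

    Each residue is independently substituted with probability
    ``1 - identity`` to a uniformly random different residue. Length is
    preserved and K/R/P positions are as mutable as any other, so the
    tryptic cleavage pattern of the ortholog may change — as it does
    between real orthologs.
    """
    if not 0.0 <= identity <= 1.0:
        raise ValueError("identity must be in [0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    seq = np.array(list(human_sequence))
    hit = rng.random(seq.size) < (1.0 - identity)
    if hit.any():
        alphabet = np.array(list(AMINO_ACIDS))
        for i in np.flatnonzero(hit):
            choices = alphabet[alphabet != seq[i]]
            seq[i] = rng.choice(choices)
    return "".join(seq)


def _make_design(config: SimConfig) -> StudyDesign:
    n = config.n_subjects
    n_matched = int(round(config.matched_fraction * n))
    subjects = [f"P{i + 1:02d}" for i in range(n)]
    extra = [f"X{i + 1:02d}" for i in range(n - n_matched)]
    rows = []
    for subj in subjects[:n_matched]:
        rows.append((f"{subj}_N", Condition.ADJ_NORMAL, subj))
    for subj in subjects:
        rows.append((f"{subj}_T", Condition.TUMOUR, subj))
    pdx_subjects = subjects[:n_matched] + extra
    for gen, cond in (("F1", Condition.PDX_F1), ("F2", Condition.PDX_F2)):
        for subj in pdx_subjects:
            rows.append((f"{subj}_{gen}", cond, subj))
    return StudyDesign(
        pd.DataFrame(rows, columns=["sample_id", "condition", "subject_id"])
    )


def _lognormal_noise(
    rng: np.random.Generator, cv: float, size
) -> np.ndarray:
    """Multiplicative mean-1 log-normal noise with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size=size)


def simulate_study(
    config: SimConfig,
) -> tuple[
    SpeciesProteome, SpeciesProteome, PeptideQuantTable, StudyDesign, GroundTruth
]:
    """Generate a full four-arm study with known ground truth.

    Returns the human proteome, the mouse ortholog proteome, the wide
    peptide quant table, the study design, and the planted truth.
    """
    rng = np.random.default_rng(config.seed)

    # --- proteomes -------------------------------------------------------
    lengths = np.maximum(
        rng.normal(
            config.protein_length_mean,
            config.protein_length_sd,
            size=config.n_proteins,
        ).astype(int),
        40,
    )
    identities, weights = zip(*config.ortholog_identity_distribution)
    w = np.asarray(weights, dtype=float)
    ident_per_protein = rng.choice(
        identities, size=config.n_proteins, p=w / w.sum()
    )
    human_records, mouse_records = [], []
    for i in range(config.n_proteins):
        seq = random_protein(int(lengths[i]), rng)
        acc_h, acc_m = f"HP{i + 1:05d}", f"MP{i + 1:05d}"
        human_records.append(ProteinRecord(acc_h, Species.HUMAN, seq))
        mouse_records.append(
            ProteinRecord(
                acc_m,
                Species.MOUSE,
                make_ortholog(seq, float(ident_per_protein[i]), rng),
            )
        )
    human = SpeciesProteome(human_records)
    mouse = SpeciesProteome(mouse_records)

    # --- compartments and planted effects --------------------------------
    n_stroma = int(round(config.stromal_fraction_pdx * config.n_proteins))
    order = rng.permutation(config.n_proteins)
    stroma_idx = set(order[:n_stroma].tolist())
    compartment = {
        human_records[i].accession: ("stroma" if i in stroma_idx else "cancer")
        for i in range(config.n_proteins)
    }
    cancer_idx = [i for i in range(config.n_proteins) if i not in stroma_idx]
    if config.n_de_human > len(cancer_idx):
        raise ValueError(
            "n_de_human exceeds the number of cancer-compartment proteins"
        )
    de_idx = rng.choice(
        np.array(cancer_idx, dtype=int),
        size=config.n_de_human,
        replace=False,
    )
    lo, hi = config.de_fold_range
    planted_fold: dict[str, float] = {}
    de_effect: dict[int, float] = {}
    cond_a, cond_b = config.de_conditions
    for i in de_idx:
        fold = float(rng.uniform(lo, hi))
        up = bool(rng.random() < 0.5)
        acc = human_records[int(i)].accession
        planted_fold[acc] = fold
        de_effect[int(i)] = fold if up else 1.0 / fold

    # --- design, composition weights, sample factors ---------------------
    design = _make_design(config)
    samples = design.sample_ids
    cond_of = {s: design.condition_of(s) for s in samples}
    scale = {
        s: float(rng.lognormal(0.0, config.sample_scale_sigma))
        if config.sample_scale_sigma > 0
        else 1.0
        for s in samples
    }
    sft, sfp = config.stromal_fraction_tumour, config.stromal_fraction_pdx
    # compartment weight per (condition, compartment, species expressed)
    weight = {
        Condition.ADJ_NORMAL: {"cancer": 1.0 - sft, "stroma_human": sft,
                               "stroma_mouse": 0.0},
        Condition.TUMOUR: {"cancer": 1.0 - sft, "stroma_human": sft,
                           "stroma_mouse": 0.0},
        Condition.PDX_F1: {"cancer": 1.0 - sfp, "stroma_human": 0.0,
                           "stroma_mouse": sfp},
        Condition.PDX_F2: {"cancer": 1.0 - sfp, "stroma_human": 0.0,
                           "stroma_mouse": sfp},
    }

    # --- noise-free protein condition means (for ground-truth folds) -----
    base = rng.lognormal(
        config.abundance_mu_sigma[0],
        config.abundance_mu_sigma[1],
        size=config.n_proteins,
    )

    def _noisefree_mean(i: int, cond: Condition, expressed_as: str) -> float:
        w_ = weight[cond][expressed_as]
        eff = (
            de_effect.get(i, 1.0)
            if cond == cond_b and i in de_effect
            else 1.0
        )
        return base[i] * w_ * eff

    # --- per-sample protein abundances -----------------------------------
    # entity = (protein index, expressed species); human everywhere except
    # PDX stroma, where the mouse ortholog is expressed instead.
    prot_abund: dict[tuple[int, Species], dict[str, float]] = {}
    for i in range(config.n_proteins):
        comp = compartment[human_records[i].accession]
        for sp in (Species.HUMAN, Species.MOUSE):
            per_sample: dict[str, float] = {}
            for s in samples:
                cond = cond_of[s]
                key = comp if comp == "cancer" else (
                    "stroma_human" if sp is Species.HUMAN else "stroma_mouse"
                )
                if comp == "cancer" and sp is Species.MOUSE:
                    continue  # cancer compartment is always human
                w_ = weight[cond][key] if comp == "stroma" else weight[cond][
                    "cancer"
                ]
                if w_ <= 0:
                    continue
                eff = de_effect.get(i, 1.0) if cond == cond_b else 1.0
                cv_c = config.cv_by_condition.get(cond, 0.3)
                noise = float(_lognormal_noise(rng, cv_c, None))
                per_sample[s] = base[i] * w_ * eff * noise
            if per_sample:
                prot_abund[(i, sp)] = per_sample

    # --- peptide emission -------------------------------------------------
    merged_records = list(human.records) + list(mouse.records)
    index = build_index(
        SpeciesProteome(merged_records), config.digest_params
    )
    rows: dict[str, dict] = {}  # canonical peptide -> row accumulator
    canon = config.digest_params.canonicalize
    for (i, sp), per_sample in sorted(
        prot_abund.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        rec = human_records[i] if sp is Species.HUMAN else mouse_records[i]
        peps = sorted(set(digest(rec.sequence, config.digest_params)))
        if not peps:
            continue
        k = min(config.n_peptides_per_protein, len(peps))
        chosen = rng.choice(np.array(peps, dtype=object), size=k, replace=False)
        for pep in sorted(chosen):
            ion = float(rng.lognormal(0.0, 0.5))
            key = canon(pep)
            row = rows.setdefault(
                key,
                {
                    "peptide": pep,
                    "origin": set(),
                    "sources": set(),
                    "abund": {s: 0.0 for s in samples},
                },
            )
            row["origin"].add(sp)
            row["sources"].add(rec.accession)
            for s, a in per_sample.items():
                noise = float(
                    _lognormal_noise(rng, config.peptide_noise_cv, None)
                )
                row["abund"][s] += a * ion * noise

    peptides, origins, sources, data = [], [], [], []
    for key in sorted(rows):
        row = rows[key]
        peptides.append(row["peptide"])
        origins.append(row["origin"])
        sources.append(row["sources"])
        data.append([row["abund"][s] * scale[s] for s in samples])
    matched = []
    for pep, srcs in zip(peptides, sources):
        hits = {acc for acc, _ in index.lookup(pep)}
        matched.append(hits or set(srcs))
    table = PeptideQuantTable(
        peptides, matched, pd.DataFrame(data, columns=samples)
    )

    # --- ground truth -----------------------------------------------------
    de_proteins: dict[
        str, tuple[tuple[Condition, Condition], float, Condition]
    ] = {}
    for i in de_idx:
        i = int(i)
        acc = human_records[i].accession
        mean_a = _noisefree_mean(i, cond_a, "cancer")
        mean_b = _noisefree_mean(i, cond_b, "cancer")
        ratio = max(mean_a, mean_b) / min(mean_a, mean_b)
        higher = cond_a if mean_a >= mean_b else cond_b
        de_proteins[acc] = ((cond_a, cond_b), float(ratio), higher)
    truth = GroundTruth(
        de_proteins=de_proteins,
        planted_fold=planted_fold,
        row_origin=origins,
        row_sources=sources,
        scale_factor_by_sample=scale,
        compartment_by_accession=compartment,
    )
    return human, mouse, table, design, truth


def scaled_replicate_table(
    n_peptides: int,
    factors: Sequence[float],
    seed: int = 0,
    noise_cv: float = 0.0,
) -> tuple[PeptideQuantTable, list[float]]:
    """One abundance profile replicated across samples with planted scale
    factors — the minimal fixture for normalization recovery.

    Returns the table and the planted factors (sample ids ``S1``, ``S2``,
    ...). With ``noise_cv = 0`` normalization must recover the factors to
    numerical precision.
    """
    rng = np.random.default_rng(seed)
    profile = rng.lognormal(10.0, 1.0, size=n_peptides)
    cols = {}
    for j, f in enumerate(factors):
        noise = _lognormal_noise(rng, noise_cv, n_peptides)
        cols[f"S{j + 1}"] = profile * f * noise
    peptides = [f"PEPTIDE{i:04d}K" for i in range(n_peptides)]
    proteins = [{f"HP{i:05d}"} for i in range(n_peptides)]
    return (
        PeptideQuantTable(peptides, proteins, pd.DataFrame(cols)),
        list(map(float, factors)),
    )
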