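"""Run configuration and end-to-end pipeline orchestration.

A run is described by a YAML config (see :class:`RunConfig`) naming the
input files (or a synthetic-study block), the digestion parameters, the
differential-expression criteria and the comparison to perform. The
pipeline writes a reproducible report bundle: the differential table,
species-partition report, CV tables, PCA coordinates, clustering, and a
manifest capturing every parameter and the seed, from which the run can
be regenerated byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import yaml

from . import __version__
from .core import Condition, PeptideQuantTable, Species, StudyDesign
from .diffexp import DECriteria
from .digest import DigestParams, PeptideIndex, build_index
from .io import (
    read_design,
    read_fasta,
    read_quant_table,
    write_design,
    write_fasta,
    write_quant_table,
)
from .model import ComparisonResults, XenograftComparison
from .species import SpeciesClass
from .synth import SimConfig, simulate_study

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    output_dir: Path
    human_fasta: Optional[Path] = None
    mouse_fasta: Optional[Path] = None
    quant_table: Optional[Path] = None
    design: Optional[Path] = None
    simulate: Optional[SimConfig] = None
    digest: DigestParams = dataclasses.field(default_factory=DigestParams)
    criteria: DECriteria = dataclasses.field(default_factory=DECriteria)
    conditions: tuple[Condition, ...] = (Condition.TUMOUR, Condition.PDX_F1)
    keep: SpeciesClass = SpeciesClass.HUMAN_SPECIFIC
    expect_species: Optional[Species] = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict[str, Any], base: Path = Path(".")) -> "RunConfig":
        def _path(key):
            return (base / raw[key]) if raw.get(key) else None

        sim = None
        if "simulate" in raw and raw["simulate"] is not None:
            sim_kwargs = dict(raw["simulate"])
            if "cv_by_condition" in sim_kwargs:
                sim_kwargs["cv_by_condition"] = {
                    Condition(k): float(v)
                    for k, v in sim_kwargs["cv_by_condition"].items()
                }
            if "de_conditions" in sim_kwargs:
                sim_kwargs["de_conditions"] = tuple(
                    Condition(c) for c in sim_kwargs["de_conditions"]
                )
            if "ortholog_identity_distribution" in sim_kwargs:
                sim_kwargs["ortholog_identity_distribution"] = tuple(
                    (float(a), float(b))
                    for a, b in sim_kwargs["ortholog_identity_distribution"]
                )
            if "de_fold_range" in sim_kwargs:
                sim_kwargs["de_fold_range"] = tuple(
                    float(x) for x in sim_kwargs["de_fold_range"]
                )
            sim_kwargs.setdefault("seed", raw.get("seed", 0))
            sim = SimConfig(**sim_kwargs)
        comparison = raw.get("comparison", {})
        conditions = tuple(
            Condition(c)
            for c in comparison.get("conditions", ["tumour", "pdx_f1"])
        )
        expect = comparison.get("expect_species")
        return cls(
            output_dir=base / raw.get("output_dir", "xenoquant_out"),
            human_fasta=_path("human_fasta"),
            mouse_fasta=_path("mouse_fasta"),
            quant_table=_path("quant_table"),
            design=_path("design"),
            simulate=sim,
            digest=DigestParams(**raw.get("digest", {})),
            criteria=DECriteria(**raw.get("criteria", {})),
            conditions=conditions,
            keep=SpeciesClass(comparison.get("keep", "human_specific")),
            expect_species=Species(expect) if expect else None,
            seed=int(raw.get("seed", 0)),
        )

    def validate(self) -> None:
        if self.simulate is None:
            missing = [
                k
                for k in ("human_fasta", "mouse_fasta", "quant_table", "design")
                if getattr(self, k) is None
            ]
            if missing:
                raise ValueError(
                    "config needs either a 'simulate' block or input paths; "
                    f"missing: {missing}"
                )

    def manifest(self) -> dict[str, Any]:
        def _enc(obj):
            if isinstance(obj, (Condition, Species, SpeciesClass)):
                return obj.value
            if isinstance(obj, Path):
                return str(obj)
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: _enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, dict):
                return {_enc(k): _enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_enc(v) for v in obj]
            return obj

        data = _enc(self)
        data["xenoquant_version"] = __version__
        return data


@dataclass
class ReportBundle:
    """Outputs of one pipeline run."""

    config: RunConfig
    results: ComparisonResults
    paths: dict[str, Path]


def _load_inputs(
    config: RunConfig,
) -> tuple[PeptideQuantTable, StudyDesign, PeptideIndex]:
    if config.simulate is not None:
        human, mouse, table, design, _ = simulate_study(config.simulate)
        from .core import merge_proteomes

        index = build_index(merge_proteomes(human, mouse), config.digest)
        return table, design, index
    human = read_fasta(config.human_fasta, Species.HUMAN)
    mouse = read_fasta(config.mouse_fasta, Species.MOUSE)
    from .core import merge_proteomes

    index = build_index(merge_proteomes(human, mouse), config.digest)
    design = read_design(config.design)
    table = read_quant_table(config.quant_table, design)
    return table, design, index


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the configured comparison and write the report bundle."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, design, index = _load_inputs(config)
    model = XenograftComparison(
        table,
        design,
        index,
        conditions=config.conditions,
        keep=config.keep,
        criteria=config.criteria,
        expect_species=config.expect_species,
    )
    res = model.fit()
    paths: dict[str, Path] = {}

    de = res.to_frame()
    paths["de_table"] = out / "de_table.tsv"
    de.to_csv(paths["de_table"], sep="\t", index=False, float_format=_FLOAT_FMT)

    paths["partition"] = out / "partition.json"
    partition = {
        "counts": {
            cls.value: n for cls, n in res.partition.counts.items()
        },
        "total": res.partition.total,
        "indistinguishable_fraction": res.partition.indistinguishable_fraction,
        "flags": res.partition.flags,
        "species_filter": {
            "kept_class": res.filtered.kept_class.value,
            "retained": res.filtered.retained_count,
            "removed": res.filtered.removed_count,
            "removal_fraction": res.filtered.removal_fraction,
            "ambiguous_within_species": (
                res.filtered.ambiguous_within_species_count
            ),
        },
    }
    paths["partition"].write_text(json.dumps(partition, indent=2, sort_keys=True))

    paths["cv_table"] = out / "cv_table.tsv"
    res.cv_table().to_csv(paths["cv_table"], sep="\t", float_format=_FLOAT_FMT)

    if len(res.passing) >= 1:
        try:
            paths["pca"] = out / "pca.tsv"
            res.pca().to_csv(paths["pca"], sep="\t", float_format=_FLOAT_FMT)
            dendro = res.cluster()
            paths["cluster"] = out / "cluster.json"
            paths["cluster"].write_text(
                json.dumps(
                    {
                        "labels": dendro.labels,
                        "linkage": [
                            [float(x) for x in row] for row in dendro.linkage
                        ],
                        "leaves_order": dendro.leaves_order(),
                    },
                    indent=2,
                )
            )
        except ValueError:
            pass  # e.g. a single passing protein: views are undefined

    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(
        json.dumps(config.manifest(), indent=2, sort_keys=True)
    )
    paths["summary"] = out / "summary.txt"
    paths["summary"].write_text(str(res.summary()) + "\n")
    return ReportBundle(config=config, results=res, paths=paths)


def write_simulated_inputs(sim: SimConfig, out_dir) -> dict[str, Path]:
    """Materialise a synthetic study as pipeline input files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    human, mouse, table, design, truth = simulate_study(sim)
    paths = {
        "human_fasta": out / "human.fasta",
        "mouse_fasta": out / "mouse.fasta",
        "quant_table": out / "quant.tsv",
        "design": out / "design.tsv",
        "truth": out / "truth.json",
    }
    write_fasta(human, paths["human_fasta"])
    write_fasta(mouse, paths["mouse_fasta"])
    write_quant_table(table, paths["quant_table"])
    write_design(design, paths["design"])
    paths["truth"].write_text(
        json.dumps(
            {
                "de_proteins": {
                    acc: {
                        "conditions": [c.value for c in pair],
                        "true_fold": fold,
                        "higher": higher.value,
                    }
                    for acc, (pair, fold, higher) in truth.de_proteins.items()
                },
                "planted_fold": truth.planted_fold,
                "scale_factor_by_sample": truth.scale_factor_by_sample,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return paths
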