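"""Run configuration and end-to-end pipeline orchestration.

A :class:`RunConfig` names the input files, the d_max mode, the frequency
weight table, clustering parameters and a master seed; :func:`run_pipeline`
executes the requested stages (load -> distance matrices -> maps -> overlap),
reusing cached artifacts when the inputs that produced them are unchanged
(content hashes) and stamping every output with config + seed provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import yaml

from .annotations import (
    DEFAULT_FREQUENCY_WEIGHTS,
    assemble_knowledge_base,
    load_disease_genes,
    load_disease_phenotypes,
    load_gene_annotations,
)
from .disease_map import build_map, cluster_overlap
from .distances import DistanceMatrix, build_distance_matrix
from .errors import InputError, ValidationError
from .ontology import compute_d_max, load_obo

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_knowledge_base", "PUBLISHED_CENSUS"]

STAGES = ("load", "phen_matrix", "gene_matrix", "phen_map", "gene_map", "overlap")

#: Disease counts of the originally published maps (2019 Orphanet snapshot),
#: reported next to a build's own census for manual comparison.
PUBLISHED_CENSUS = {"phenotype_diseases": 3287, "gene_diseases": 3789, "overlap": 1718}


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    phenotype_obo: str
    go_cc_obo: str
    go_mf_obo: str
    go_bp_obo: str
    disease_phenotypes: str
    disease_genes: str
    gene_go: str
    out_dir: str = "rdmap_out"
    dialect: str = "tsv"
    gene_go_dialect: str = "tsv"
    d_max_mode: str = "depth_bound"
    frequency_weights: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FREQUENCY_WEIGHTS)
    )
    search_method: str = "similarity"
    use_weights: bool = True
    k_range: Sequence[int] = (2, 8)  # inclusive bounds
    bootstrap_B: int = 20
    stability_threshold: float = 0.85
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.d_max_mode not in ("exact", "depth_bound"):
            raise ValidationError(f"unknown d_max mode {self.d_max_mode!r}")
        lo, hi = self.k_range
        if lo < 2 or hi < lo:
            raise ValidationError(f"invalid k range {self.k_range!r}")
        for label, w in self.frequency_weights.items():
            if not 0.0 <= float(w) <= 1.0:
                raise ValidationError(f"frequency weight {label!r}={w} outside [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            with open(path, "r", encoding="utf-8") as fh:
                data = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise InputError(f"cannot read config {path!r}: {exc}") from exc
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def input_hash(self) -> str:
        """Content hash over every input file plus the scoring-relevant settings."""
        h = hashlib.sha256()
        for p in (
            self.phenotype_obo, self.go_cc_obo, self.go_mf_obo, self.go_bp_obo,
            self.disease_phenotypes, self.disease_genes, self.gene_go,
        ):
            with open(p, "rb") as fh:
                h.update(hashlib.sha256(fh.read()).digest())
        h.update(json.dumps(
            {
                "d_max_mode": self.d_max_mode,
                "weights": self.frequency_weights,
                "dialect": self.dialect,
            },
            sort_keys=True,
        ).encode())
        return h.hexdigest()


def load_knowledge_base(config: RunConfig):
    """Load and cross-validate all inputs named by the config."""
    dags = {
        name: load_obo(path, name=name)
        for name, path in (
            ("phenotype", config.phenotype_obo),
            ("go-cc", config.go_cc_obo),
            ("go-mf", config.go_mf_obo),
            ("go-bp", config.go_bp_obo),
        )
    }
    for dag in dags.values():
        compute_d_max(dag, mode=config.d_max_mode)
    kb = assemble_knowledge_base(
        load_disease_phenotypes(
            config.disease_phenotypes, dialect=config.dialect,
            weight_table={k.lower(): v for k, v in config.frequency_weights.items()},
        ),
        load_disease_genes(config.disease_genes, dialect=config.dialect),
        load_gene_annotations(config.gene_go, dialect=config.gene_go_dialect),
        phenotype_dag=dags["phenotype"],
        go_cc_dag=dags["go-cc"],
        go_mf_dag=dags["go-mf"],
        go_bp_dag=dags["go-bp"],
    )
    return kb


def _file_sha(path) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


def _matrix_cached(prefix: str, input_hash: str) -> Optional[DistanceMatrix]:
    meta_path = f"{prefix}.json"
    if not all(os.path.exists(f"{prefix}{ext}") for ext in (".tsv", ".ids", ".json")):
        return None
    try:
        with open(meta_path, "r", encoding="utf-8") as fh:
            meta = json.load(fh)
        if meta.get("input_hash") != input_hash:
            return None
        if meta.get("matrix_sha") != _file_sha(f"{prefix}.tsv"):
            logger.warning("cache %s corrupted (hash mismatch); recomputing", prefix)
            return None
        return DistanceMatrix.load(prefix)
    except Exception as exc:  # any cache defect -> recompute
        logger.warning("cache %s unreadable (%s); recomputing", prefix, exc)
        return None


def run_pipeline(config: RunConfig, stages: Sequence[str] = STAGES) -> Dict[str, str]:
    """Execute the requested stages and return the artifact paths.

    Stage dependencies are implicit: a map stage loads its matrix from cache
    and raises an actionable error if the matrix stage has not run.  Cached
    matrices are keyed by a content hash over all inputs, so a rerun with
    unchanged inputs is a cache hit and a corrupted cache file is detected
    and recomputed.
    """
    for s in stages:
        if s not in STAGES:
            raise ValidationError(f"unknown stage {s!r}; valid: {STAGES}")
    os.makedirs(config.out_dir, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    config.to_yaml(os.path.join(config.out_dir, "config.yaml"))
    input_hash = config.input_hash()
    rng = np.random.default_rng(config.seed)
    stage_seeds = {s: int(rng.integers(0, 2**31 - 1)) for s in STAGES}
    artifacts: Dict[str, str] = {"config": os.path.join(config.out_dir, "config.yaml")}
    kb = None

    def need_kb():
        nonlocal kb
        if kb is None:
            kb = load_knowledge_base(config)
        return kb

    if "load" in stages:
        kb = need_kb()
        report = {
            "census": kb.census,
            "published_reference_census": PUBLISHED_CENSUS,
            "dropped_terms": kb.dropped_terms,
            "d_max_mode": config.d_max_mode,
            "input_hash": input_hash,
            "seed": config.seed,
        }
        path = os.path.join(config.out_dir, "build_report.json")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        artifacts["build_report"] = path

    matrices: Dict[str, DistanceMatrix] = {}
    for stage, kind in (("phen_matrix", "phenotype"), ("gene_matrix", "gene")):
        prefix = os.path.join(config.out_dir, f"{kind}_distances")
        if stage in stages:
            dm = _matrix_cached(prefix, input_hash)
            if dm is None:
                dm = build_distance_matrix(need_kb(), kind)
                dm.metadata.update(input_hash=input_hash, seed=config.seed)
                dm.save(prefix)
                dm.metadata["matrix_sha"] = _file_sha(f"{prefix}.tsv")
                with open(f"{prefix}.json", "w", encoding="utf-8") as fh:
                    json.dump({"kind": dm.kind, **dm.metadata}, fh, indent=2, sort_keys=True)
            else:
                logger.info("%s: cache hit", prefix)
            matrices[kind] = dm
            artifacts[f"{kind}_matrix"] = f"{prefix}.tsv"

    maps = {}
    lo, hi = config.k_range
    for stage, kind in (("phen_map", "phenotype"), ("gene_map", "gene")):
        if stage not in stages:
            continue
        prefix = os.path.join(config.out_dir, f"{kind}_distances")
        dm = matrices.get(kind) or _matrix_cached(prefix, input_hash)
        if dm is None:
            raise ValidationError(
                f"stage {stage!r} needs the {kind} distance matrix; run "
                f"'{'phen' if kind == 'phenotype' else 'gene'}_matrix' first"
            )
        emb = build_map(
            dm, k_range=range(lo, hi + 1), B=config.bootstrap_B,
            seed=stage_seeds[stage], threshold=config.stability_threshold,
        )
        path = os.path.join(config.out_dir, f"{kind}_map.json")
        emb.to_json(path, diseases=need_kb().diseases)
        maps[kind] = emb
        artifacts[f"{kind}_map"] = path

    if "overlap" in stages:
        if not ("phenotype" in maps and "gene" in maps):
            raise ValidationError(
                "stage 'overlap' needs both maps; run 'phen_map' and 'gene_map' first"
            )
        flows = cluster_overlap(maps["phenotype"], maps["gene"])
        path = os.path.join(config.out_dir, "cluster_overlap.json")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "flows": [
                        {"cluster_p": a, "cluster_g": b, "count": c}
                        for a, b, c in flows.flows
                    ],
                    "total_shared": flows.total,
                    "seed": config.seed,
                },
                fh, indent=2,
            )
        artifacts["cluster_overlap"] = path
    return artifacts
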