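"""Synthetic ontologies, knowledge bases and case sets with known ground truth.

Everything the loaders read — OBO ontologies, disease->phenotype and
disease->gene association files, gene->GO tables, case TSVs — can be
generated here deterministically from a seed, together with a manifest that
records the ground truth (term assignments, planted cluster memberships,
file paths).  The generated knowledge base is always produced by writing the
files and reading them back through the real loaders, so a fixture exercises
the same code paths as user data.

Generated DAGs grow as a single root with a handful of top-level branches
("sectors"); extra parents of a term stay within its sector, mimicking how
ontology cross-links concentrate within organ systems or processes.  When a
clustered knowledge base is requested, each planted cluster samples its
disease phenotypes (and its gene pool's GO terms) from one sector, so
within-cluster term distances are short while between-cluster routes must
climb to the root — a separation that distance-based embedding and
clustering should recover.  This planted structure is a testing device, not
a statistical model of real HPO/Orphanet data.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotations import (
    KnowledgeBase,
    PREVALENCE_CLASSES,
    assemble_knowledge_base,
    load_disease_genes,
    load_disease_phenotypes,
    load_gene_annotations,
)
from .errors import ValidationError
from .evaluation import make_characteristic_query, make_imprecise_query
from .ontology import OntologyDAG, Term, load_obo, write_obo

__all__ = [
    "FixtureManifest",
    "generate_dag",
    "generate_knowledge_base",
    "generate_cases",
]

# pretty labels as they appear in association files; parsed by frequency_weight
FREQUENCY_LABELS = {
    "obligate": "Obligate (100%)",
    "very frequent": "Very frequent (99-80%)",
    "frequent": "Frequent (79-30%)",
    "occasional": "Occasional (29-5%)",
    "very rare": "Very rare (<4-1%)",
    "excluded": "Excluded (0%)",
}

DEFAULT_WEIGHT_DISTRIBUTION = {
    "obligate": 0.15,
    "very frequent": 0.35,
    "frequent": 0.30,
    "occasional": 0.15,
    "very rare": 0.05,
}

# Planted clusters describe diseases through their characteristic (i.e.
# high-frequency) phenotypes: low weights deflate the weighted disease
# distance toward zero and would smear the planted geometry.
PLANTED_WEIGHT_DISTRIBUTION = {
    "obligate": 0.4,
    "very frequent": 0.4,
    "frequent": 0.2,
}


@dataclass
class FixtureManifest:
    """Ground truth of one generated fixture; fully determines the files."""

    seed: int
    files: Dict[str, str] = field(default_factory=dict)
    diseases: Dict[str, Dict] = field(default_factory=dict)
    genes: Dict[str, Dict[str, List[str]]] = field(default_factory=dict)
    cluster_of: Dict[str, int] = field(default_factory=dict)
    n_clusters: int = 1

    def save(self, path) -> None:
        payload = {
            "seed": self.seed,
            "files": self.files,
            "diseases": self.diseases,
            "genes": self.genes,
            "cluster_of": self.cluster_of,
            "n_clusters": self.n_clusters,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "FixtureManifest":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            seed=d["seed"], files=d["files"], diseases=d["diseases"],
            genes=d["genes"],
            cluster_of={k: int(v) for k, v in d["cluster_of"].items()},
            n_clusters=d["n_clusters"],
        )


# ---------------------------------------------------------------------------
# DAG generation
# ---------------------------------------------------------------------------

def generate_dag(
    n_terms: int,
    max_parents: int = 2,
    max_depth: int = 8,
    seed: int = 0,
    prefix: str = "ST",
    n_branches: int = 5,
    path=None,
) -> OntologyDAG:
    """Random rooted single-component DAG written (optionally) as OBO.

    The root's children define ``n_branches`` sectors; every later term picks
    a primary parent uniformly among existing terms below ``max_depth`` and
    any extra parents (up to ``max_parents``) within the same sector, so the
    graph stays acyclic by construction and sectors only meet at the root.
    """
    if n_terms < 1:
        raise ValidationError("n_terms must be >= 1")
    if max_parents < 1 or max_depth < 1:
        raise ValidationError("max_parents and max_depth must be >= 1")
    rng = np.random.default_rng(seed)

    def tid(i: int) -> str:
        return f"{prefix}:{i:07d}"

    parents: Dict[str, List[str]] = {tid(0): []}
    depth: Dict[str, int] = {tid(0): 0}
    sector: Dict[str, int] = {tid(0): -1}
    n_top = min(n_branches, max(n_terms - 1, 0))
    for b in range(n_top):
        t = tid(1 + b)
        parents[t] = [tid(0)]
        depth[t] = 1
        sector[t] = b
    for i in range(1 + n_top, n_terms):
        t = tid(i)
        eligible = [u for u in parents if depth[u] < max_depth and sector[u] >= 0]
        if not eligible:
            eligible = [tid(0)]
        primary = eligible[int(rng.integers(0, len(eligible)))]
        ps = [primary]
        sec = sector[primary]
        extra_pool = [
            u for u in parents
            if sector[u] == sec and depth[u] < max_depth and u not in ps
        ]
        n_extra = int(rng.integers(0, max_parents)) if extra_pool else 0
        for _ in range(min(n_extra, len(extra_pool))):
            choice = extra_pool[int(rng.integers(0, len(extra_pool)))]
            extra_pool.remove(choice)
            ps.append(choice)
        parents[t] = sorted(ps)
        depth[t] = min(depth[p] for p in ps) + 1
        sector[t] = sec if sec >= 0 else -1

    terms = {
        t: Term(id=t, name=f"synthetic term {t}", parent_ids=tuple(ps))
        for t, ps in parents.items()
    }
    dag = OntologyDAG(terms=terms, name=f"synthetic-{prefix.lower()}")
    dag._sector = dict(sector)  # ground truth for cluster planting
    if path is not None:
        write_obo(dag, path)
    return dag


def _anchor_pool(
    dag: OntologyDAG, sector_terms: List[str], size: int, rng
) -> List[str]:
    """Terms near a random anchor of the sector: the planted "seed subgraph".

    The pool is the ``size`` sector terms closest to the anchor in the
    common-ancestor-path metric itself (ties by term id), so every disease
    planted on this anchor draws from one tight ball of the ontology rather
    than a neighborhood that may straddle several sub-branches.
    """
    def ball(anchor: str) -> List[str]:
        ranked = sorted(
            sector_terms,
            key=lambda t: (dag.path_length(anchor, t) or 10**9, t),
        )
        return ranked[:size]

    def spread(pool: List[str]) -> float:
        return sum(
            dag.path_length(a, b) or 10**9
            for i, a in enumerate(pool) for b in pool[i + 1:]
        )

    # try a handful of anchors and keep the tightest ball: a ball that
    # straddles two sub-branches would plant two lumps, not one cluster
    n_cand = min(8, len(sector_terms))
    idx = rng.choice(len(sector_terms), size=n_cand, replace=False)
    candidates = [sector_terms[int(i)] for i in idx]
    best = min((ball(a) for a in candidates), key=spread)
    return sorted(best)


def _sector_terms(dag: OntologyDAG, min_depth: int = 2) -> Dict[int, List[str]]:
    depth = dag.depth
    sectors: Dict[int, List[str]] = {}
    for t, s in getattr(dag, "_sector", {}).items():
        if s >= 0 and depth[t] >= min_depth:
            sectors.setdefault(s, []).append(t)
    for s in sectors:
        sectors[s].sort()
    return sectors


# ---------------------------------------------------------------------------
# knowledge-base generation
# ---------------------------------------------------------------------------

def _sample_labels(rng, k: int, distribution: Dict[str, float]) -> List[str]:
    keys = sorted(distribution)
    probs = np.array([distribution[k_] for k_ in keys], dtype=float)
    probs /= probs.sum()
    picks = rng.choice(len(keys), size=k, p=probs)
    return [keys[int(i)] for i in picks]


def generate_knowledge_base(
    out_dir,
    n_diseases: int = 60,
    terms_per_disease: int = 8,
    n_clusters: int = 1,
    n_genes: int = 30,
    genes_per_disease: Tuple[int, int] = (1, 3),
    go_terms_per_aspect: Tuple[int, int] = (1, 3),
    weight_distribution: Optional[Dict[str, float]] = None,
    dag_terms: int = 200,
    go_dag_terms: int = 120,
    max_depth: int = 8,
    seed: int = 0,
    dialect: str = "tsv",
) -> Tuple[KnowledgeBase, FixtureManifest]:
    """Generate a full synthetic knowledge base on disk and load it back.

    With ``n_clusters > 1``, diseases (and the gene pools they draw from)
    are planted in distinct ontology sectors so true cluster memberships are
    known; with ``n_clusters == 1`` terms are sampled from the whole DAG and
    no structure is planted.  Frequency labels are drawn from
    ``weight_distribution`` (a label->probability map over the class ladder).
    Returns the knowledge base as read back through the loaders, plus the
    ground-truth manifest.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    if weight_distribution is not None:
        dist = weight_distribution
    else:
        dist = PLANTED_WEIGHT_DISTRIBUTION if n_clusters > 1 else DEFAULT_WEIGHT_DISTRIBUTION
    unknown = set(dist) - set(FREQUENCY_LABELS)
    if unknown:
        raise ValidationError(f"unknown frequency classes {sorted(unknown)}")
    n_branches = max(5, n_clusters)

    hp_path = os.path.join(out_dir, "phenotype.obo")
    hp_dag = generate_dag(
        dag_terms, max_depth=max_depth, seed=int(rng.integers(2**31 - 1)),
        prefix="HP", n_branches=n_branches, path=hp_path,
    )
    go_paths, go_dags = {}, {}
    for aspect in ("cc", "mf", "bp"):
        p = os.path.join(out_dir, f"go_{aspect}.obo")
        go_dags[aspect] = generate_dag(
            go_dag_terms, max_depth=max_depth, seed=int(rng.integers(2**31 - 1)),
            prefix=f"GO{aspect.upper()}", n_branches=n_branches, path=p,
        )
        go_paths[aspect] = p

    hp_sectors = _sector_terms(hp_dag)
    go_sectors = {a: _sector_terms(d) for a, d in go_dags.items()}
    sector_ids = sorted(hp_sectors)
    if n_clusters > 1:
        if n_clusters > len(sector_ids):
            raise ValidationError(
                f"cannot plant {n_clusters} clusters in {len(sector_ids)} sectors"
            )
        # plant in the best-populated sectors so small random branches
        # cannot starve a cluster of terms
        cluster_sectors = sorted(
            sorted(sector_ids, key=lambda s: -len(hp_sectors[s]))[:n_clusters]
        )
        for c in cluster_sectors:
            if len(hp_sectors[c]) < terms_per_disease:
                raise ValidationError(
                    f"sector {c} has {len(hp_sectors[c])} deep terms; "
                    f"need {terms_per_disease} per disease — grow the DAG"
                )
        # pool twice the per-disease draw: small enough to stay one tight
        # ball, large enough that two diseases rarely share a whole subset
        # (identical annotation lumps would read as extra stable clusters)
        anchor_pools = [
            _anchor_pool(hp_dag, hp_sectors[c], 2 * terms_per_disease, rng)
            for c in cluster_sectors
        ]
    all_terms = sorted(t for ts in hp_sectors.values() for t in ts)
    if not n_clusters > 1 and len(all_terms) < terms_per_disease:
        raise ValidationError("DAG too small for the requested disease size")

    manifest = FixtureManifest(seed=seed, n_clusters=n_clusters)

    # gene pools: each cluster gets its share of the gene list, annotated in
    # the matching GO sector per aspect
    gene_cluster: Dict[str, int] = {}
    for gi in range(n_genes):
        sym = f"SYNG{gi:03d}"
        cluster = gi % n_clusters if n_clusters > 1 else 0
        gene_cluster[sym] = cluster
        ann: Dict[str, List[str]] = {}
        for aspect in ("cc", "mf", "bp"):
            sectors = go_sectors[aspect]
            if n_clusters > 1:
                ranked = sorted(
                    sorted(sectors, key=lambda s: -len(sectors[s]))[:n_clusters]
                )
                pool = sectors[ranked[cluster]]
            else:
                pool = sorted(t for ts in sectors.values() for t in ts)
            k = int(rng.integers(go_terms_per_aspect[0], go_terms_per_aspect[1] + 1))
            k = min(k, len(pool))
            idx = rng.choice(len(pool), size=k, replace=False)
            ann[aspect] = sorted(pool[int(i)] for i in idx)
        manifest.genes[sym] = ann

    pheno_rows, gene_rows, go_rows = [], [], []
    for di in range(n_diseases):
        did = f"ORPHA:{90000 + di}"
        name = f"synthetic disease {di}"
        cluster = di % n_clusters if n_clusters > 1 else 0
        manifest.cluster_of[did] = cluster
        if n_clusters > 1:
            pool = anchor_pools[cluster]
        else:
            pool = all_terms
        idx = rng.choice(len(pool), size=terms_per_disease, replace=False)
        terms = sorted(pool[int(i)] for i in idx)
        labels = _sample_labels(rng, len(terms), dist)
        prevalence = PREVALENCE_CLASSES[int(rng.integers(len(PREVALENCE_CLASSES)))]
        omim = f"OMIM:{600000 + di}"
        cluster_genes = sorted(g for g, c in gene_cluster.items() if c == cluster)
        ng = int(rng.integers(genes_per_disease[0], genes_per_disease[1] + 1))
        ng = min(ng, len(cluster_genes))
        gidx = rng.choice(len(cluster_genes), size=ng, replace=False)
        genes = sorted(cluster_genes[int(i)] for i in gidx)
        manifest.diseases[did] = {
            "name": name, "terms": terms, "labels": labels,
            "genes": genes, "prevalence_class": prevalence, "omim": omim,
            "cluster": cluster,
        }
        for t, lab in zip(terms, labels):
            pheno_rows.append((did, name, t, FREQUENCY_LABELS[lab], prevalence, omim))
        for g in genes:
            gene_rows.append((did, g))
    for sym in sorted(manifest.genes):
        for aspect in ("cc", "mf", "bp"):
            for t in manifest.genes[sym][aspect]:
                go_rows.append((sym, aspect, t))

    if dialect == "tsv":
        pheno_path = os.path.join(out_dir, "disease_phenotypes.tsv")
        gene_path = os.path.join(out_dir, "disease_genes.tsv")
        with open(pheno_path, "w", encoding="utf-8") as fh:
            fh.write("disease_id\tdisease_name\thpo_id\tfrequency_label\tprevalence_class\tomim\n")
            for row in pheno_rows:
                fh.write("\t".join(row) + "\n")
        with open(gene_path, "w", encoding="utf-8") as fh:
            fh.write("disease_id\tgene_symbol\n")
            for row in gene_rows:
                fh.write("\t".join(row) + "\n")
    elif dialect == "orphanet_xml":
        pheno_path = os.path.join(out_dir, "disease_phenotypes.xml")
        gene_path = os.path.join(out_dir, "disease_genes.xml")
        _write_orphanet_xml(pheno_path, gene_path, manifest)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")

    go_path = os.path.join(out_dir, "gene_go.tsv")
    with open(go_path, "w", encoding="utf-8") as fh:
        fh.write("gene_symbol\taspect\tgo_id\n")
        for row in go_rows:
            fh.write("\t".join(row) + "\n")

    manifest.files = {
        "phenotype_obo": hp_path,
        **{f"go_{a}_obo": go_paths[a] for a in ("cc", "mf", "bp")},
        "disease_phenotypes": pheno_path,
        "disease_genes": gene_path,
        "gene_go": go_path,
    }
    manifest_path = os.path.join(out_dir, "manifest.json")
    manifest.save(manifest_path)
    manifest.files["manifest"] = manifest_path

    kb = assemble_knowledge_base(
        load_disease_phenotypes(pheno_path, dialect=dialect),
        load_disease_genes(gene_path, dialect=dialect),
        load_gene_annotations(go_path, dialect="tsv"),
        phenotype_dag=load_obo(hp_path, name="synthetic-hp"),
        go_cc_dag=load_obo(go_paths["cc"], name="synthetic-go-cc"),
        go_mf_dag=load_obo(go_paths["mf"], name="synthetic-go-mf"),
        go_bp_dag=load_obo(go_paths["bp"], name="synthetic-go-bp"),
    )
    return kb, manifest


def _xml_escape(s: str) -> str:
    return (
        s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    )


def _write_orphanet_xml(pheno_path, gene_path, manifest: FixtureManifest) -> None:
    """Emit the Orphanet-product-style XML dialect the loaders accept."""
    with open(pheno_path, "w", encoding="utf-8") as fh:
        fh.write('<?xml version="1.0" encoding="UTF-8"?>\n<JDBOR>\n<DisorderList>\n')
        for did in sorted(manifest.diseases):
            d = manifest.diseases[did]
            code = did.split(":")[1]
            fh.write(f"<Disorder>\n<OrphaCode>{code}</OrphaCode>\n")
            fh.write(f"<Name>{_xml_escape(d['name'])}</Name>\n")
            fh.write(f"<PrevalenceClass>{_xml_escape(d['prevalence_class'])}</PrevalenceClass>\n")
            fh.write("<ExternalReferenceList><ExternalReference>"
                     f"<Reference>{d['omim']}</Reference>"
                     "</ExternalReference></ExternalReferenceList>\n")
            fh.write("<HPODisorderAssociationList>\n")
            for t, lab in zip(d["terms"], d["labels"]):
                fh.write(
                    "<HPODisorderAssociation><HPO>"
                    f"<HPOId>{t}</HPOId><HPOTerm>{t}</HPOTerm></HPO>"
                    f"<HPOFrequency><Name>{_xml_escape(FREQUENCY_LABELS[lab])}</Name></HPOFrequency>"
                    "</HPODisorderAssociation>\n"
                )
            fh.write("</HPODisorderAssociationList>\n</Disorder>\n")
        fh.write("</DisorderList>\n</JDBOR>\n")
    with open(gene_path, "w", encoding="utf-8") as fh:
        fh.write('<?xml version="1.0" encoding="UTF-8"?>\n<JDBOR>\n<DisorderList>\n')
        for did in sorted(manifest.diseases):
            d = manifest.diseases[did]
            code = did.split(":")[1]
            fh.write(f"<Disorder>\n<OrphaCode>{code}</OrphaCode>\n")
            fh.write(f"<Name>{_xml_escape(d['name'])}</Name>\n<GeneList>\n")
            for g in d["genes"]:
                fh.write(f"<Gene><Symbol>{g}</Symbol></Gene>\n")
            fh.write("</GeneList>\n</Disorder>\n")
        fh.write("</DisorderList>\n</JDBOR>\n")


# ---------------------------------------------------------------------------
# case generation
# ---------------------------------------------------------------------------

def generate_cases(
    kb: KnowledgeBase,
    n_cases: int,
    terms_per_case: int = 4,
    n_imprecise: int = 0,
    seed: int = 0,
    path=None,
) -> List[Dict]:
    """Build evaluation cases from characteristic (optionally degraded) queries.

    Each case targets a sampled disease with >= ``terms_per_case``
    phenotypes; its query is the disease's top-weight terms with
    ``n_imprecise`` of them replaced by DAG-adjacent terms.  Written as the
    case TSV dialect when ``path`` is given.
    """
    rng = np.random.default_rng(seed)
    eligible = [
        d for d in kb.phenotype_disease_ids()
        if len(kb.diseases[d].phenotypes) >= terms_per_case
    ]
    if len(eligible) < n_cases:
        raise ValidationError(
            f"only {len(eligible)} diseases have >= {terms_per_case} phenotypes; "
            f"cannot build {n_cases} cases"
        )
    picks = rng.choice(len(eligible), size=n_cases, replace=False)
    cases = []
    for ci, pi in enumerate(sorted(int(i) for i in picks)):
        did = eligible[pi]
        base = make_characteristic_query(kb, did, terms_per_case)
        terms = make_imprecise_query(
            kb.phenotype_dag, base, n_imprecise, seed=int(rng.integers(2**31 - 1))
        )
        rec = kb.diseases[did]
        xref = rec.xrefs[0] if rec.xrefs else did
        cases.append({
            "case_id": f"syn{ci:03d}",
            "target_xref": xref,
            "target_name": rec.name,
            "hpo_terms": ",".join(terms),
            "target_disease_id": did,
        })
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("case_id\ttarget_xref\ttarget_name\thpo_terms\n")
            for c in cases:
                fh.write(
                    f"{c['case_id']}\t{c['target_xref']}\t{c['target_name']}\t{c['hpo_terms']}\n"
                )
    return cases
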