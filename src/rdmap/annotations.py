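"""Disease and gene annotations: loaders, frequency weights, knowledge base.

Diseases carry a weighted phenotype term set (HPO accessions plus an
Orphanet-style frequency class) and a pathogenic gene list; genes carry GO
term sets per aspect (cellular component, molecular function, biological
process).  Two input dialects are supported for each association file:

* ``orphanet_xml`` — Orphanet-product-style XML
  (``DisorderList/Disorder/HPODisorderAssociation`` with ``HPOId`` and
  ``HPOFrequency``; ``Disorder/.../Gene/Symbol`` for genes).  The reader
  tolerates unknown sibling elements.
* ``tsv`` — plain UTF-8 tab-separated files with a header row:
  ``disease_id  disease_name  hpo_id  frequency_label`` (phenotypes, with
  optional ``prevalence_class`` and ``omim`` columns) and
  ``disease_id  gene_symbol`` (genes).

Gene-to-GO annotations come from a GAF 2.x file or a three-column TSV
(``gene_symbol  aspect  go_id`` with aspect in {cc, mf, bp}).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from lxml import etree

from .errors import InputError, ValidationError
from .ontology import OntologyDAG

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedPhenotype",
    "DiseaseRecord",
    "GeneAnnotation",
    "KnowledgeBase",
    "DEFAULT_FREQUENCY_WEIGHTS",
    "frequency_weight",
    "load_disease_phenotypes",
    "load_disease_genes",
    "load_gene_annotations",
    "assemble_knowledge_base",
]

# Orphanet/HPO frequency vocabulary mapped to the midpoint of each printed
# band.  The map is an argument everywhere it is consumed, so users can probe
# score sensitivity to the weighting.
DEFAULT_FREQUENCY_WEIGHTS: Dict[str, float] = {
    "obligate": 1.0,        # Obligate (100%)
    "very frequent": 0.895,  # Very frequent (99-80%)
    "frequent": 0.545,       # Frequent (79-30%)
    "occasional": 0.17,      # Occasional (29-5%)
    "very rare": 0.02,       # Very rare (<4-1%)
    "excluded": 0.0,         # Excluded (0%)
}

PREVALENCE_CLASSES = (
    ">1 / 1000",
    "1-5 / 10 000",
    "1-9 / 100 000",
    "1-9 / 1 000 000",
    "<1 / 1 000 000",
    "unknown",
)


@dataclass(frozen=True)
class WeightedPhenotype:
    """A phenotype term with its numeric frequency weight in [0, 1]."""

    term_id: str
    weight: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValidationError(
                f"phenotype {self.term_id!r}: weight {self.weight} outside [0, 1]"
            )


@dataclass(frozen=True)
class DiseaseRecord:
    """One disease: weighted phenotypes, pathogenic genes, prevalence, xrefs."""

    disease_id: str
    name: str
    phenotypes: Tuple[WeightedPhenotype, ...] = ()
    genes: Tuple[str, ...] = ()
    prevalence_class: str = "unknown"
    xrefs: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen = [p.term_id for p in self.phenotypes]
        if len(seen) != len(set(seen)):
            raise ValidationError(
                f"disease {self.disease_id!r}: duplicate phenotype term ids"
            )

    @property
    def term_ids(self) -> Tuple[str, ...]:
        return tuple(p.term_id for p in self.phenotypes)

    @property
    def weights(self) -> Tuple[float, ...]:
        return tuple(p.weight for p in self.phenotypes)

    @property
    def all_excluded(self) -> bool:
        """True when every annotated phenotype has weight 0 (degenerate row)."""
        return bool(self.phenotypes) and all(p.weight == 0.0 for p in self.phenotypes)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene symbol with its GO term sets per aspect."""

    symbol: str
    cc_terms: frozenset = frozenset()
    mf_terms: frozenset = frozenset()
    bp_terms: frozenset = frozenset()

    def aspect(self, name: str) -> frozenset:
        return {"cc": self.cc_terms, "mf": self.mf_terms, "bp": self.bp_terms}[name]

    @property
    def empty(self) -> bool:
        return not (self.cc_terms or self.mf_terms or self.bp_terms)


def frequency_weight(
    label, table: Optional[Mapping[str, float]] = None
) -> float:
    """Map a frequency class label (or literal numeric fraction) to [0, 1].

    Labels match case-insensitively on the class name, ignoring the printed
    percentage band (``"Frequent (79-30%)"`` -> the ``frequent`` entry).
    """
    table = DEFAULT_FREQUENCY_WEIGHTS if table is None else table
    if isinstance(label, (int, float)) and not isinstance(label, bool):
        value = float(label)
        if not 0.0 <= value <= 1.0:
            raise ValidationError(f"numeric frequency {value} outside [0, 1]")
        return value
    key = str(label).split("(")[0].strip().lower()
    if key in table:
        return float(table[key])
    try:
        value = float(label)
    except (TypeError, ValueError):
        raise ValidationError(f"unknown frequency label {label!r}") from None
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"numeric frequency {value} outside [0, 1]")
    return value


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------

def _read_tsv(path) -> List[Dict[str, str]]:
    import csv

    try:
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None:
                raise InputError(f"{path}: empty TSV (no header row)")
            rows = list(reader)
    except OSError as exc:
        raise InputError(f"cannot read {path!r}: {exc}") from exc
    return rows


def _parse_xml(path) -> etree._ElementTree:
    try:
        return etree.parse(str(path))
    except OSError as exc:
        raise InputError(f"cannot read {path!r}: {exc}") from exc
    except etree.XMLSyntaxError as exc:
        raise InputError(f"malformed XML in {path!r}: {exc}") from exc


def _disorder_id(disorder: etree._Element, path) -> str:
    for tag in ("OrphaCode", "OrphaNumber"):
        el = disorder.find(tag)
        if el is not None and el.text:
            return f"ORPHA:{el.text.strip()}"
    raise InputError(
        f"{path}: Disorder element at line {disorder.sourceline} lacks "
        "OrphaCode/OrphaNumber"
    )


def _disorder_extras(disorder: etree._Element) -> Tuple[str, Tuple[str, ...]]:
    prev = disorder.findtext("PrevalenceClass")
    prevalence = prev.strip() if prev else "unknown"
    xrefs = []
    for ext in disorder.iterfind(".//ExternalReference"):
        ref = ext.findtext("Reference")
        if not ref:
            continue
        ref = ref.strip()
        source = (ext.findtext("Source") or "").strip()
        # Orphanet products carry Source/Reference pairs; the fixture dialect
        # writes already-qualified "OMIM:123456" references
        xrefs.append(ref if ":" in ref or not source else f"{source}:{ref}")
    return prevalence, tuple(xrefs)


def load_disease_phenotypes(
    path,
    dialect: str = "tsv",
    weight_table: Optional[Mapping[str, float]] = None,
) -> List[DiseaseRecord]:
    """Read disease->phenotype associations with frequency classes.

    Returns one :class:`DiseaseRecord` per disease with frequency labels
    already mapped to numeric weights.  Diseases with zero valid phenotype
    rows are retained (empty phenotype tuple) and flagged in the log.
    """
    records: Dict[str, DiseaseRecord] = {}
    phenos: Dict[str, List[WeightedPhenotype]] = {}

    if dialect == "tsv":
        for lineno, row in enumerate(_read_tsv(path), start=2):
            did = (row.get("disease_id") or "").strip()
            if not did:
                raise InputError(f"{path}: line {lineno}: missing disease_id")
            name = (row.get("disease_name") or did).strip()
            prevalence = (row.get("prevalence_class") or "unknown").strip()
            omim = (row.get("omim") or "").strip()
            xrefs = (omim,) if omim else ()
            if did not in records:
                records[did] = DiseaseRecord(
                    disease_id=did, name=name,
                    prevalence_class=prevalence, xrefs=xrefs,
                )
                phenos[did] = []
            term = (row.get("hpo_id") or "").strip()
            label = (row.get("frequency_label") or "").strip()
            if term:
                try:
                    w = frequency_weight(label, weight_table)
                except ValidationError as exc:
                    raise ValidationError(f"{path}: line {lineno}: {exc}") from None
                phenos[did].append(WeightedPhenotype(term, w))
    elif dialect == "orphanet_xml":
        tree = _parse_xml(path)
        for disorder in tree.iterfind(".//Disorder"):
            did = _disorder_id(disorder, path)
            if did in records:
                raise ValidationError(f"{path}: duplicate disease id {did!r}")
            name_el = disorder.find("Name")
            name = name_el.text.strip() if name_el is not None and name_el.text else did
            prevalence, xrefs = _disorder_extras(disorder)
            records[did] = DiseaseRecord(
                disease_id=did, name=name,
                prevalence_class=prevalence, xrefs=xrefs,
            )
            phenos[did] = []
            for assoc in disorder.iterfind(".//HPODisorderAssociation"):
                term = assoc.findtext(".//HPOId")
                label = assoc.findtext(".//HPOFrequency/Name")
                if not term:
                    raise InputError(
                        f"{path}: association at line {assoc.sourceline} lacks HPOId"
                    )
                w = frequency_weight(label if label is not None else "", weight_table)
                phenos[did].append(WeightedPhenotype(term.strip(), w))
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")

    out = []
    for did, rec in records.items():
        if not phenos[did]:
            logger.warning("disease %s has no valid phenotype rows", did)
        out.append(replace(rec, phenotypes=tuple(phenos[did])))
    return out


def load_disease_genes(path, dialect: str = "tsv") -> Dict[str, List[str]]:
    """Read disease->pathogenic-gene associations into ``{disease_id: [symbol]}``.

    Diseases with an empty gene list are omitted (with a logged warning).
    """
    genes: Dict[str, List[str]] = {}
    if dialect == "tsv":
        for lineno, row in enumerate(_read_tsv(path), start=2):
            did = (row.get("disease_id") or "").strip()
            if not did:
                raise InputError(f"{path}: line {lineno}: missing disease_id")
            sym = (row.get("gene_symbol") or "").strip()
            bucket = genes.setdefault(did, [])
            if sym and sym not in bucket:
                bucket.append(sym)
    elif dialect == "orphanet_xml":
        tree = _parse_xml(path)
        for disorder in tree.iterfind(".//Disorder"):
            did = _disorder_id(disorder, path)
            if did in genes:
                raise ValidationError(f"{path}: duplicate disease id {did!r}")
            bucket = genes.setdefault(did, [])
            for sym_el in disorder.iterfind(".//Gene/Symbol"):
                if sym_el.text:
                    sym = sym_el.text.strip()
                    if sym not in bucket:
                        bucket.append(sym)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")

    empty = [d for d, g in genes.items() if not g]
    for did in empty:
        logger.warning("disease %s has an empty gene list; omitted from gene map", did)
        del genes[did]
    return genes


_GAF_ASPECT = {"C": "cc", "F": "mf", "P": "bp"}


def load_gene_annotations(path, dialect: str = "tsv") -> Dict[str, GeneAnnotation]:
    """Read gene->GO annotations from a three-column TSV or a GAF 2.x file."""
    buckets: Dict[str, Dict[str, Set[str]]] = {}

    def add(symbol: str, aspect: str, go_id: str) -> None:
        buckets.setdefault(symbol, {"cc": set(), "mf": set(), "bp": set()})
        buckets[symbol][aspect].add(go_id)

    if dialect == "tsv":
        for lineno, row in enumerate(_read_tsv(path), start=2):
            sym = (row.get("gene_symbol") or "").strip()
            aspect = (row.get("aspect") or "").strip().lower()
            go_id = (row.get("go_id") or "").strip()
            if not (sym and go_id):
                raise InputError(f"{path}: line {lineno}: missing gene_symbol/go_id")
            if aspect not in ("cc", "mf", "bp"):
                raise ValidationError(
                    f"{path}: line {lineno}: unknown GO aspect {aspect!r}"
                )
            add(sym, aspect, go_id)
    elif dialect == "gaf":
        try:
            with open(path, "r", encoding="utf-8") as fh:
                for lineno, line in enumerate(fh, start=1):
                    if not line.strip() or line.startswith("!"):
                        continue
                    cols = line.rstrip("\n").split("\t")
                    if len(cols) < 9:
                        raise InputError(f"{path}: line {lineno}: short GAF row")
                    sym, go_id, aspect_code = cols[2], cols[4], cols[8]
                    aspect = _GAF_ASPECT.get(aspect_code)
                    if aspect is None:
                        raise ValidationError(
                            f"{path}: line {lineno}: unknown GAF aspect {aspect_code!r}"
                        )
                    add(sym, aspect, go_id)
        except OSError as exc:
            raise InputError(f"cannot read {path!r}: {exc}") from exc
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")

    return {
        sym: GeneAnnotation(
            symbol=sym,
            cc_terms=frozenset(sets["cc"]),
            mf_terms=frozenset(sets["mf"]),
            bp_terms=frozenset(sets["bp"]),
        )
        for sym, sets in buckets.items()
    }


# ---------------------------------------------------------------------------
# knowledge base
# ---------------------------------------------------------------------------

@dataclass
class KnowledgeBase:
    """Cross-validated view over diseases, genes and their ontologies."""

    diseases: Dict[str, DiseaseRecord]
    genes: Dict[str, GeneAnnotation]
    phenotype_dag: OntologyDAG
    go_cc_dag: OntologyDAG
    go_mf_dag: OntologyDAG
    go_bp_dag: OntologyDAG
    dropped_terms: int = 0

    @property
    def go_dags(self) -> Tuple[OntologyDAG, OntologyDAG, OntologyDAG]:
        return (self.go_cc_dag, self.go_mf_dag, self.go_bp_dag)

    def phenotype_disease_ids(self, include_all_excluded: bool = False) -> List[str]:
        """Diseases admissible to the phenotype map (sorted by id)."""
        return sorted(
            d for d, rec in self.diseases.items()
            if rec.phenotypes and (include_all_excluded or not rec.all_excluded)
        )

    def gene_disease_ids(self) -> List[str]:
        """Diseases admissible to the gene map: >=1 gene with GO annotation."""
        return sorted(
            d for d, rec in self.diseases.items()
            if any(g in self.genes and not self.genes[g].empty for g in rec.genes)
        )

    @property
    def census(self) -> Dict[str, int]:
        """Counts of phenotype-map diseases, gene-map diseases and overlap."""
        p = set(self.phenotype_disease_ids(include_all_excluded=True))
        g = set(self.gene_disease_ids())
        return {
            "phenotype_diseases": len(p),
            "gene_diseases": len(g),
            "overlap": len(p & g),
            "union": len(p | g),
        }

    def resolve_xref(self, xref: str) -> Optional[str]:
        """Find the disease id carrying an external reference (e.g. OMIM id)."""
        for did in sorted(self.diseases):
            if xref in self.diseases[did].xrefs:
                return did
        return None


def assemble_knowledge_base(
    phenotype_records: Sequence[DiseaseRecord],
    gene_map: Mapping[str, Sequence[str]],
    gene_annotations: Mapping[str, GeneAnnotation],
    phenotype_dag: OntologyDAG,
    go_cc_dag: OntologyDAG,
    go_mf_dag: OntologyDAG,
    go_bp_dag: OntologyDAG,
) -> KnowledgeBase:
    """Merge loaded annotations into a cross-validated :class:`KnowledgeBase`.

    Phenotype term ids are resolved against the phenotype ontology (aliases
    canonicalized); unresolvable terms are dropped with a logged count.  GO
    terms are resolved per aspect the same way.  Diseases appearing only in
    the gene map get a record with an empty phenotype set.
    """
    dropped = 0
    diseases: Dict[str, DiseaseRecord] = {}
    for rec in phenotype_records:
        if rec.disease_id in diseases:
            raise ValidationError(f"duplicate disease id {rec.disease_id!r}")
        kept = []
        seen: Set[str] = set()
        for p in rec.phenotypes:
            try:
                canon = phenotype_dag.resolve(p.term_id)
            except Exception:
                logger.warning(
                    "disease %s: phenotype %s does not resolve; dropped",
                    rec.disease_id, p.term_id,
                )
                dropped += 1
                continue
            if canon in seen:
                continue
            seen.add(canon)
            kept.append(WeightedPhenotype(canon, p.weight))
        diseases[rec.disease_id] = replace(rec, phenotypes=tuple(kept))

    for did, symbols in gene_map.items():
        rec = diseases.get(did)
        if rec is None:
            rec = DiseaseRecord(disease_id=did, name=did)
        diseases[did] = replace(rec, genes=tuple(dict.fromkeys(symbols)))

    dags = {"cc": go_cc_dag, "mf": go_mf_dag, "bp": go_bp_dag}
    genes: Dict[str, GeneAnnotation] = {}
    for sym, ann in gene_annotations.items():
        kept_aspects = {}
        for aspect, dag in dags.items():
            kept_set = set()
            for t in ann.aspect(aspect):
                try:
                    kept_set.add(dag.resolve(t))
                except Exception:
                    logger.warning("gene %s: GO term %s does not resolve; dropped", sym, t)
                    dropped += 1
            kept_aspects[aspect] = frozenset(kept_set)
        genes[sym] = GeneAnnotation(
            symbol=sym,
            cc_terms=kept_aspects["cc"],
            mf_terms=kept_aspects["mf"],
            bp_terms=kept_aspects["bp"],
        )

    kb = KnowledgeBase(
        diseases=diseases,
        genes=genes,
        phenotype_dag=phenotype_dag,
        go_cc_dag=go_cc_dag,
        go_mf_dag=go_mf_dag,
        go_bp_dag=go_bp_dag,
        dropped_terms=dropped,
    )
    if not kb.diseases:
        raise ValidationError("knowledge base is empty")
    census = kb.census
    logger.info(
        "knowledge base: %d phenotype diseases, %d gene diseases, %d overlapping",
        census["phenotype_diseases"], census["gene_diseases"], census["overlap"],
    )
    return kb
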