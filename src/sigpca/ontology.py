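"""Gene Ontology handling: OBO parsing, GAF annotations, propagation, gene sets.

This module turns an OBO ontology plus a GAF annotation file into a
:class:`GeneSetCollection` — the curated mapping ``term id -> set of gene
symbols`` that the enrichment engine tests.  The processing chain is

1. parse the ontology (``is_a`` everywhere, ``part_of`` additionally for
   cellular_component terms), dropping obsolete terms and resolving alt_ids;
2. parse the annotation file, keeping only manually curated evidence codes
   and dropping negated (``NOT``) annotations;
3. propagate every annotation to all ancestor terms (a gene annotated with a
   term is implicitly annotated with every more general term);
4. restrict to gene sets within a size window (default 5–200 genes);
5. remove parent terms whose propagated gene set is identical to that of a
   direct child (the child is the more specific, hence preferred, label).

Collections can also be written to / read from a plain-text tab-delimited
file, which doubles as an interchange format for arbitrary (non-GO) gene
sets.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
from Bio.UniProt.GOA import gafiterator

logger = logging.getLogger(__name__)

#: Evidence codes regarded as manually curated; all others are discarded.
CURATED_EVIDENCE_CODES = frozenset(
    {"IDA", "IGI", "IMP", "ISO", "ISS", "IC", "NAS", "TAS"}
)

#: Number of tab-separated columns in a GAF 2.x row.
_GAF_NCOLS = 17

_NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


class OntologyError(ValueError):
    """Raised for malformed or inconsistent ontology / annotation input."""


@dataclass
class OntologyTerm:
    """A single non-obsolete ontology term."""

    id: str
    name: str
    namespace: str
    is_a_parents: list[str] = field(default_factory=list)
    part_of_parents: list[str] = field(default_factory=list)


class Ontology:
    """A DAG of :class:`OntologyTerm` objects with relatedness queries.

    Parameters
    ----------
    terms
        Terms keyed by their primary id.
    alt_ids
        Mapping from secondary (merged) accessions to primary ids.
    """

    def __init__(self, terms: Mapping[str, OntologyTerm], alt_ids: Mapping[str, str] | None = None):
        self.terms: dict[str, OntologyTerm] = dict(terms)
        self.alt_ids: dict[str, str] = dict(alt_ids or {})
        self._graph = self._build_graph()

    def _build_graph(self) -> nx.DiGraph:
        # edge child -> parent; part_of participates only for CC terms
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for term in self.terms.values():
            for parent in self._effective_parents(term):
                if parent not in self.terms:
                    raise OntologyError(
                        f"term {term.id} references unknown parent {parent}"
                    )
                g.add_edge(term.id, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(f"ontology relations contain a cycle: {cycle}")
        return g

    def _effective_parents(self, term: OntologyTerm) -> list[str]:
        parents = list(term.is_a_parents)
        if term.namespace == "cellular_component":
            parents.extend(term.part_of_parents)
        return parents

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, term_id: str) -> str | None:
        """Map an accession (possibly an alt_id) to its primary id."""
        if term_id in self.terms:
            return term_id
        return self.alt_ids.get(term_id)

    def parents(self, term_id: str) -> set[str]:
        """Direct parents, with part_of counted only for CC terms."""
        return set(self._graph.successors(term_id))

    def children(self, term_id: str) -> set[str]:
        return set(self._graph.predecessors(term_id))

    def ancestors(self, term_id: str) -> set[str]:
        """All transitive ancestors (more general terms), excluding the term."""
        if term_id not in self.terms:
            raise KeyError(f"unknown term: {term_id}")
        return set(nx.descendants(self._graph, term_id))

    def descendants(self, term_id: str) -> set[str]:
        """All transitive descendants (more specific terms), excluding the term."""
        if term_id not in self.terms:
            raise KeyError(f"unknown term: {term_id}")
        return set(nx.ancestors(self._graph, term_id))

    def related_terms(self, term_id: str) -> set[str]:
        """All ancestors and descendants of a term (the term excluded).

        Two terms are *related* if one lies on a directed path to the other
        in the ontology DAG.  This is the notion used both by the cross-PC
        signature filter and by bootstrap "related term" detection.
        """
        return self.ancestors(term_id) | self.descendants(term_id)


def related_terms(ontology: Ontology, term_id: str) -> set[str]:
    """Functional alias for :meth:`Ontology.related_terms`."""
    return ontology.related_terms(term_id)


@dataclass
class GeneSetCollection:
    """A curated collection of gene sets, keyed by term id.

    Attributes
    ----------
    sets
        Mapping ``term id -> frozen set of gene symbols``.
    term_meta
        Mapping ``term id -> (name, namespace)``.  For custom gene sets the
        namespace may be any short label.
    """

    sets: dict[str, frozenset[str]]
    term_meta: dict[str, tuple[str, str]]

    @property
    def m(self) -> int:
        """Number of gene sets (the number of terms tested)."""
        return len(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.sets

    def subset(self, term_ids: Iterable[str]) -> "GeneSetCollection":
        ids = [t for t in term_ids if t in self.sets]
        return GeneSetCollection(
            sets={t: self.sets[t] for t in ids},
            term_meta={t: self.term_meta[t] for t in ids},
        )


# ---------------------------------------------------------------------------
# OBO / GAF parsing


def parse_obo(path: str | Path) -> Ontology:
    """Parse an OBO 1.2/1.4 ontology file.

    Obsolete terms are excluded (their count is logged); ``alt_id``
    accessions resolve to their primary term.  ``is_a`` and ``part_of``
    relations are captured; any other relationship type is ignored.
    """
    try:
        graph = obonet.read_obo(str(path), ignore_obsolete=False)
    except Exception as exc:  # pragma: no cover - passthrough formatting
        raise OntologyError(f"failed to parse OBO file {path}: {exc}") from exc

    terms: dict[str, OntologyTerm] = {}
    alt_ids: dict[str, str] = {}
    n_obsolete = 0
    obsolete_ids = set()
    for node, data in graph.nodes(data=True):
        if data.get("is_obsolete") == "true":
            n_obsolete += 1
            obsolete_ids.add(node)
            continue
        part_of = []
        for rel in data.get("relationship", []):
            parts = rel.split()
            if len(parts) >= 2 and parts[0] == "part_of":
                part_of.append(parts[1])
        terms[node] = OntologyTerm(
            id=node,
            name=data.get("name", node),
            namespace=data.get("namespace", "biological_process"),
            is_a_parents=list(data.get("is_a", [])),
            part_of_parents=part_of,
        )
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    # drop edges to obsolete terms (they can linger in malformed files)
    for term in terms.values():
        term.is_a_parents = [p for p in term.is_a_parents if p not in obsolete_ids]
        term.part_of_parents = [p for p in term.part_of_parents if p not in obsolete_ids]
    if n_obsolete:
        logger.info("parse_obo: dropped %d obsolete terms", n_obsolete)
    logger.info("parse_obo: %d terms retained", len(terms))
    return Ontology(terms, alt_ids)


def parse_gaf(
    path: str | Path,
    allowed_evidence: frozenset[str] | set[str] = CURATED_EVIDENCE_CODES,
) -> list[tuple[str, str, str]]:
    """Parse a GAF 2.x association file into ``(gene, term id, evidence)`` rows.

    Rows with a ``NOT`` qualifier are dropped (negated annotations would
    corrupt enrichment), as are rows whose evidence code is not in
    ``allowed_evidence``.  Duplicate (gene, term, evidence) triples collapse
    to one.  Gene identity is the DB_Object_Symbol column (column 3), which
    matches expression-matrix row labels.
    """
    path = Path(path)
    # Validate column counts up front so errors carry a line number;
    # field semantics are delegated to Biopython's GAF reader.
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            ncols = line.rstrip("\n").count("\t") + 1
            if ncols != _GAF_NCOLS:
                raise OntologyError(
                    f"{path}:{lineno}: expected {_GAF_NCOLS} tab-separated "
                    f"columns, found {ncols}"
                )
    kept: "OrderedDict[tuple[str, str, str], None]" = OrderedDict()
    n_rows = n_not = n_evidence = 0
    with open(path, encoding="utf-8") as fh:
        for rec in gafiterator(fh):
            n_rows += 1
            if any(q.strip().upper().startswith("NOT") for q in rec["Qualifier"] if q):
                n_not += 1
                continue
            if rec["Evidence"] not in allowed_evidence:
                n_evidence += 1
                continue
            kept[(rec["DB_Object_Symbol"], rec["GO_ID"], rec["Evidence"])] = None
    n_pairs_dropped = len({(g, t) for g, t, _ in kept})
    logger.info(
        "parse_gaf: %d rows read, %d dropped (NOT qualifier), %d dropped "
        "(evidence filter: %.1f%% of rows), %d kept (%d unique gene-term pairs)",
        n_rows, n_not, n_evidence,
        100.0 * n_evidence / n_rows if n_rows else 0.0,
        len(kept), n_pairs_dropped,
    )
    return list(kept)


# ---------------------------------------------------------------------------
# Propagation and filtering


def propagate(
    ontology: Ontology, annotations: Iterable[tuple[str, str, str]]
) -> dict[str, set[str]]:
    """Propagate annotations up the ontology graph.

    A gene annotated with a term is considered annotated with every ancestor
    reached through ``is_a`` edges; for cellular_component terms ``part_of``
    edges are traversed the same way.  Annotations to unknown terms are
    skipped with a logged count; alt_id accessions are resolved first.
    """
    sets: dict[str, set[str]] = {}
    n_unknown = 0
    for gene, term_id, _evidence in annotations:
        resolved = ontology.resolve(term_id)
        if resolved is None:
            n_unknown += 1
            continue
        sets.setdefault(resolved, set()).add(gene)
        for anc in ontology.ancestors(resolved):
            sets.setdefault(anc, set()).add(gene)
    if n_unknown:
        logger.warning("propagate: skipped %d annotations to unknown terms", n_unknown)
    return sets


def filter_by_size(
    sets: Mapping[str, set[str] | frozenset[str]],
    ontology_or_meta: Ontology | Mapping[str, tuple[str, str]],
    min_genes: int = 5,
    max_genes: int = 200,
) -> GeneSetCollection:
    """Keep only gene sets whose size lies in ``[min_genes, max_genes]``.

    Sets smaller than ``min_genes`` are too specific to generate stable
    signatures; sets larger than ``max_genes`` are too broad to yield an
    informative label.  Both bounds are inclusive.
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    if max_genes < min_genes:
        raise ValueError("max_genes must be >= min_genes")
    if isinstance(ontology_or_meta, Ontology):
        meta = {
            t: (ontology_or_meta.terms[t].name, ontology_or_meta.terms[t].namespace)
            for t in sets
            if t in ontology_or_meta
        }
    else:
        meta = dict(ontology_or_meta)
    kept = {
        t: frozenset(genes)
        for t, genes in sets.items()
        if min_genes <= len(genes) <= max_genes
    }
    logger.info(
        "filter_by_size: kept %d of %d sets within [%d, %d]",
        len(kept), len(sets), min_genes, max_genes,
    )
    return GeneSetCollection(
        sets=kept, term_meta={t: meta.get(t, (t, "biological_process")) for t in kept}
    )


def collapse_identical_parents(
    collection: GeneSetCollection, ontology: Ontology
) -> GeneSetCollection:
    """Remove parent terms whose gene set equals that of a direct child.

    After propagation a parent's set is a superset of each child's; equality
    means the parent carries no information beyond the child's, and the more
    specific child is the better signature label.  Only *direct* parent/child
    pairs (``is_a``, plus ``part_of`` within cellular_component) are
    compared; children are never removed by this rule.
    """
    removed: set[str] = set()
    for term_id in collection.sets:
        if term_id not in ontology:
            continue
        child_set = collection.sets[term_id]
        for parent in ontology.parents(term_id):
            if parent in collection.sets and collection.sets[parent] == child_set:
                removed.add(parent)
    if removed:
        logger.info(
            "collapse_identical_parents: removed %d redundant parent terms",
            len(removed),
        )
    kept = [t for t in collection.sets if t not in removed]
    return collection.subset(kept)


def build_gene_set_collection(
    ontology: Ontology,
    annotations: Iterable[tuple[str, str, str]],
    min_genes: int = 5,
    max_genes: int = 200,
) -> GeneSetCollection:
    """Full chain: propagate, size-filter, collapse identical parents."""
    sets = propagate(ontology, annotations)
    collection = filter_by_size(sets, ontology, min_genes, max_genes)
    return collapse_identical_parents(collection, ontology)


# ---------------------------------------------------------------------------
# Plain-text gene-set interchange format

_GS_HEADER = "id\tname\tnamespace\tgenes"


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as a tab-delimited text file, one set per line.

    Columns: ``id``, ``name``, ``namespace``, comma-separated gene symbols.
    The file is UTF-8 and trivially hand-editable, which allows analyses on
    arbitrary user-defined gene sets rather than ontology-derived ones.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_GS_HEADER + "\n")
        for term_id, genes in collection.sets.items():
            name, namespace = collection.term_meta[term_id]
            fh.write(f"{term_id}\t{name}\t{namespace}\t{','.join(sorted(genes))}\n")


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a collection written by :func:`write_gene_sets`.

    Round-trips exactly: ``read_gene_sets(write_gene_sets(c)) == c``.
    Duplicate ids are an error.
    """
    sets: dict[str, frozenset[str]] = {}
    meta: dict[str, tuple[str, str]] = {}
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != _GS_HEADER:
            raise OntologyError(
                f"{path}:1: expected header {_GS_HEADER!r}, found {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise OntologyError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, "
                    f"found {len(fields)}"
                )
            term_id, name, namespace, genes = fields
            if term_id in sets:
                raise OntologyError(f"{path}:{lineno}: duplicate set id {term_id}")
            sets[term_id] = frozenset(g for g in genes.split(",") if g)
            meta[term_id] = (name, namespace)
    logger.info("read_gene_sets: loaded %d sets from %s", len(sets), path)
    return GeneSetCollection(sets=sets, term_meta=meta)
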