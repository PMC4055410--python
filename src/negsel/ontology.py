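"""Gene Ontology structure, annotation sets and the propagated annotation matrix.

The ontology is modelled as a DAG over GO term identifiers with typed
child->parent edges (``is_a`` and ``part_of`` are retained by default; other
relationship types are dropped at parse time).  Annotations are (gene, term,
evidence-code) triples.  Positive annotations propagate upward to every
ancestor (the "true path rule"); asserted negatives propagate downward to
every descendant (the inverse rule).  All selection algorithms consume the
binary gene-by-term incidence matrix built after upward propagation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import obonet
from scipy import sparse

__all__ = [
    "BRANCHES",
    "IEA",
    "Ontology",
    "AnnotationSet",
    "AnnotationMatrix",
    "OboParseError",
    "OntologyStructureError",
    "parse_obo",
    "parse_annotations",
    "write_annotations",
    "propagate",
    "propagate_negatives_down",
    "build_matrix",
    "annotated_direct_descendants",
]

BRANCHES = ("BP", "MF", "CC")
IEA = "IEA"

_NAMESPACE_TO_BRANCH = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}

DEFAULT_RELATIONS = ("is_a", "part_of")


class OboParseError(ValueError):
    """Raised when an OBO file cannot be parsed."""


class OntologyStructureError(ValueError):
    """Raised when the term graph violates a structural requirement (e.g. a cycle)."""


@dataclass(frozen=True)
class Ontology:
    """A DAG of GO terms in up to three rooted branches.

    Parameters
    ----------
    edges
        Directed child -> parent links with a relation label.
    branch
        Branch (``BP``/``MF``/``CC``) of every term.
    roots
        The parentless root term of each populated branch.
    """

    terms: frozenset[str]
    edges: frozenset[tuple[str, str, str]]  # (child, parent, relation)
    branch: Mapping[str, str]
    roots: Mapping[str, str]

    def __post_init__(self) -> None:
        parent_map: dict[str, set[str]] = {t: set() for t in self.terms}
        child_map: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, parent, _rel in self.edges:
            parent_map[child].add(parent)
            child_map[parent].add(child)
        object.__setattr__(self, "_parents", parent_map)
        object.__setattr__(self, "_children", child_map)
        object.__setattr__(self, "_anc_cache", {})
        object.__setattr__(self, "_desc_cache", {})

    # -- queries ---------------------------------------------------------
    def parents(self, term: str) -> set[str]:
        return set(self._parents[term])

    def children(self, term: str) -> set[str]:
        return set(self._children[term])

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable via retained edges, excluding ``term`` itself."""
        cache = self._anc_cache
        if term not in cache:
            out: set[str] = set()
            stack = list(self._parents[term])
            while stack:
                t = stack.pop()
                if t not in out:
                    out.add(t)
                    stack.extend(self._parents[t])
            cache[term] = frozenset(out)
        return cache[term]

    def descendants(self, term: str) -> frozenset[str]:
        cache = self._desc_cache
        if term not in cache:
            out: set[str] = set()
            stack = list(self._children[term])
            while stack:
                t = stack.pop()
                if t not in out:
                    out.add(t)
                    stack.extend(self._children[t])
            cache[term] = frozenset(out)
        return cache[term]

    def validate(self) -> None:
        """Check acyclicity, per-branch rooting and branch consistency."""
        g = nx.DiGraph((c, p) for c, p, _ in self.edges)
        g.add_nodes_from(self.terms)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyStructureError(f"term graph contains a cycle: {cycle}")
        root_set = set(self.roots.values())
        for t in self.terms:
            if t in root_set:
                continue
            ps = self._parents[t]
            if not ps:
                raise OntologyStructureError(f"non-root term {t} has no parent")
            for p in ps:
                if self.branch[p] != self.branch[t]:
                    raise OntologyStructureError(
                        f"edge {t} -> {p} crosses branches "
                        f"({self.branch[t]} vs {self.branch[p]})"
                    )


def parse_obo(path: str | Path, relations: Iterable[str] = DEFAULT_RELATIONS) -> Ontology:
    """Load an OBO 1.2 ontology file.

    Non-obsolete ``[Term]`` stanzas are loaded; ``is_a`` and
    ``relationship: part_of`` edges are retained by default and every other
    relationship type is dropped.  A cycle among retained edges raises
    :class:`OntologyStructureError`.
    """
    path = Path(path)
    _prevalidate_obo(path)
    relations = tuple(relations)
    try:
        graph = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # pragma: no cover - defensive
        raise OboParseError(f"{path}: {exc}") from exc

    terms: set[str] = set()
    branch: dict[str, str] = {}
    edges: set[tuple[str, str, str]] = set()
    for node, data in graph.nodes(data=True):
        terms.add(node)
        ns = data.get("namespace")
        if ns in _NAMESPACE_TO_BRANCH:
            branch[node] = _NAMESPACE_TO_BRANCH[ns]
    # obonet stores edges child -> parent keyed by relation type
    for child, parent, rel in graph.edges(keys=True):
        if rel in relations and parent in terms:
            edges.add((child, parent, rel))

    # infer missing namespaces from parents (common in hand-written fixtures)
    parent_of = {t: set() for t in terms}
    for c, p, _ in edges:
        parent_of[c].add(p)
    changed = True
    while changed:
        changed = False
        for t in terms:
            if t not in branch:
                for p in parent_of[t]:
                    if p in branch:
                        branch[t] = branch[p]
                        changed = True
                        break
    unknown = sorted(t for t in terms if t not in branch)
    if unknown:
        raise OboParseError(
            f"{path}: cannot determine namespace for terms {unknown[:5]}"
        )

    roots: dict[str, str] = {}
    for t in sorted(terms):
        if not parent_of[t]:
            b = branch[t]
            if b in roots:
                raise OntologyStructureError(
                    f"branch {b} has multiple parentless terms: {roots[b]}, {t}"
                )
            roots[b] = t

    ont = Ontology(frozenset(terms), frozenset(edges), branch, roots)
    ont.validate()
    return ont


def _prevalidate_obo(path: Path) -> None:
    """Cheap line-level scan so malformed stanzas fail with a line number."""
    in_term = False
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("!"):
                continue
            if s.startswith("["):
                if not s.endswith("]"):
                    raise OboParseError(f"{path}: malformed stanza header at line {i}")
                in_term = s == "[Term]"
                continue
            if in_term and ":" not in s:
                raise OboParseError(f"{path}: malformed tag-value pair at line {i}")


# ---------------------------------------------------------------------------
# Annotation sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationSet:
    """A dated collection of (gene, term, evidence-code) records.

    ``gene_universe`` may exceed the annotated genes: the random baseline
    samples negatives from the full universe, while every other algorithm
    only scores genes that carry at least one annotation.
    """

    records: frozenset[tuple[str, str, str]]
    snapshot_label: str = ""
    gene_universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.gene_universe:
            object.__setattr__(
                self, "gene_universe", frozenset(g for g, _, _ in self.records)
            )
        missing = {g for g, _, _ in self.records} - set(self.gene_universe)
        if missing:
            object.__setattr__(
                self, "gene_universe", frozenset(self.gene_universe) | missing
            )

    @property
    def genes(self) -> frozenset[str]:
        """Genes carrying at least one record."""
        return frozenset(g for g, _, _ in self.records)

    def terms_for(self, gene: str) -> set[str]:
        return {t for g, t, _ in self.records if g == gene}

    def genes_for(self, term: str, include_iea: bool = True) -> set[str]:
        return {
            g
            for g, t, ev in self.records
            if t == term and (include_iea or ev != IEA)
        }

    def filter_iea(self) -> "AnnotationSet":
        """Drop IEA-evidenced records, keeping the gene universe."""
        return replace(
            self,
            records=frozenset(r for r in self.records if r[2] != IEA),
        )

    def counts_per_term(self, include_iea: bool = True) -> dict[str, int]:
        counts: dict[str, set[str]] = {}
        for g, t, ev in self.records:
            if include_iea or ev != IEA:
                counts.setdefault(t, set()).add(g)
        return {t: len(gs) for t, gs in counts.items()}


def parse_annotations(
    path: str | Path,
    ontology: Ontology,
    format: str = "tsv",
    snapshot_label: str = "",
    gene_universe: Iterable[str] | None = None,
) -> AnnotationSet:
    """Read annotations from GAF 2.x or the 3-column TSV dialect.

    GAF rows carrying a ``NOT`` qualifier are excluded from the positive
    records; evidence codes are preserved verbatim; duplicate triples
    collapse.  Records whose term is absent from ``ontology`` are skipped
    with a single summary warning.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "gaf":
        rows = _read_gaf(path)
    elif fmt == "tsv":
        rows = _read_tsv(path)
    else:
        raise ValueError(f"unknown annotation format: {format!r}")

    records: set[tuple[str, str, str]] = set()
    skipped = 0
    for gene, term, evidence in rows:
        if term not in ontology.terms:
            skipped += 1
            continue
        records.add((gene, term, evidence))
    if skipped:
        warnings.warn(
            f"{path}: skipped {skipped} record(s) with terms absent from the ontology",
            stacklevel=2,
        )
    return AnnotationSet(
        records=frozenset(records),
        snapshot_label=snapshot_label or path.stem,
        gene_universe=frozenset(gene_universe or ()),
    )


def _read_gaf(path: Path) -> list[tuple[str, str, str]]:
    # GAF 2.x columns (1-based): 3 = object symbol, 4 = qualifier,
    # 5 = GO id, 7 = evidence code.
    out: list[tuple[str, str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 7:
                raise ValueError(f"{path}: unreadable GAF row at line {i}")
            symbol, qualifier, go_id, evidence = cols[2], cols[3], cols[4], cols[6]
            if "NOT" in qualifier.split("|"):
                continue
            out.append((symbol, go_id, evidence))
    return out


def _read_tsv(path: Path) -> list[tuple[str, str, str]]:
    out: list[tuple[str, str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}: unreadable row at line {i}")
            gene, term, evidence = cols[0], cols[1], cols[2]
            if i == 1 and not term.startswith("GO:"):
                continue  # optional header line
            out.append((gene, term, evidence))
    return out


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    """Write the TSV dialect: gene \\t GO-term \\t evidence-code."""
    with open(path, "w", encoding="utf-8") as fh:
        for gene, term, ev in sorted(ann.records):
            fh.write(f"{gene}\t{term}\t{ev}\n")


# ---------------------------------------------------------------------------
# Propagation
# ---------------------------------------------------------------------------


def _best_code(codes: Iterable[str]) -> str:
    """Most reliable contributing code: any non-IEA code beats IEA."""
    non_iea = sorted(c for c in codes if c != IEA)
    return non_iea[0] if non_iea else IEA


def propagate(ann: AnnotationSet, ont: Ontology) -> AnnotationSet:
    """Upward closure under the true path rule.

    An inferred ancestor record inherits the most reliable evidence code
    among the records that imply it (non-IEA preferred), so that IEA
    filtering commutes with propagation for any term that has at least one
    curated supporting descendant.  Idempotent.
    """
    by_gene: dict[str, dict[str, set[str]]] = {}
    for gene, term, ev in ann.records:
        if term not in ont.terms:
            raise KeyError(f"annotation term {term} absent from ontology")
        by_gene.setdefault(gene, {}).setdefault(term, set()).add(ev)

    out: set[tuple[str, str, str]] = set()
    for gene, term_codes in by_gene.items():
        implied: dict[str, set[str]] = {}
        for term, codes in term_codes.items():
            implied.setdefault(term, set()).update(codes)
            for anc in ont.ancestors(term):
                implied.setdefault(anc, set()).update(codes)
        for term, codes in implied.items():
            out.add((gene, term, _best_code(codes)))
    return replace(ann, records=frozenset(out))


def propagate_negatives_down(
    negatives: Iterable[str], term: str, ont: Ontology
) -> dict[str, set[str]]:
    """Inverse true path rule: a negative for ``term`` is a negative for
    every descendant of ``term``."""
    if term not in ont.terms:
        raise KeyError(f"term {term} absent from ontology")
    neg = set(negatives)
    out = {term: set(neg)}
    for d in ont.descendants(term):
        out[d] = set(neg)
    return out


# ---------------------------------------------------------------------------
# Annotation matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationMatrix:
    """Binary gene x term incidence after true-path propagation.

    Rows cover only genes with >= 1 surviving annotation; columns cover every
    ontology term (sorted), so unannotated terms appear as all-zero columns.
    ``W_diag`` holds per-gene annotation totals (row sums), the diagonal of
    the weight matrix W in the SNOB score S = W^-1 A P.
    """

    A: sparse.csr_matrix
    genes: tuple[str, ...]
    terms: tuple[str, ...]
    W_diag: np.ndarray

    @property
    def row_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    @property
    def col_index(self) -> dict[str, int]:
        return {t: j for j, t in enumerate(self.terms)}

    def column(self, term: str) -> np.ndarray:
        j = self.col_index[term]
        return np.asarray(self.A[:, j].todense()).ravel()

    def save(self, prefix: str | Path) -> None:
        """Cache as Matrix Market plus two plain-text index files."""
        prefix = Path(prefix)
        from scipy.io import mmwrite

        mmwrite(str(prefix.with_suffix(".mtx")), self.A)
        prefix.with_suffix(".genes.txt").write_text("\n".join(self.genes) + "\n")
        prefix.with_suffix(".terms.txt").write_text("\n".join(self.terms) + "\n")

    @staticmethod
    def load(prefix: str | Path) -> "AnnotationMatrix":
        prefix = Path(prefix)
        from scipy.io import mmread

        A = sparse.csr_matrix(mmread(str(prefix.with_suffix(".mtx"))))
        genes = tuple(prefix.with_suffix(".genes.txt").read_text().split())
        terms = tuple(prefix.with_suffix(".terms.txt").read_text().split())
        return AnnotationMatrix(
            A=A, genes=genes, terms=terms, W_diag=np.asarray(A.sum(axis=1)).ravel()
        )


def build_matrix(
    ann: AnnotationSet,
    ont: Ontology,
    include_iea: bool = True,
    assume_propagated: bool = False,
) -> AnnotationMatrix:
    """Build the propagated binary annotation matrix.

    ``include_iea=False`` drops IEA records before construction.  Propagation
    is applied internally unless ``assume_propagated`` (it is idempotent, so
    passing an already-propagated set is always safe).
    """
    if not include_iea:
        ann = ann.filter_iea()
    if not assume_propagated:
        ann = propagate(ann, ont)
    pairs = {(g, t) for g, t, _ in ann.records}
    if not pairs:
        raise ValueError("no annotated genes")
    genes = tuple(sorted({g for g, _ in pairs}))
    terms = tuple(sorted(ont.terms))
    row = {g: i for i, g in enumerate(genes)}
    col = {t: j for j, t in enumerate(terms)}
    rows = np.fromiter((row[g] for g, _ in pairs), dtype=np.int64, count=len(pairs))
    cols = np.fromiter((col[t] for _, t in pairs), dtype=np.int64, count=len(pairs))
    data = np.ones(len(pairs), dtype=np.int8)
    A = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(genes), len(terms)), dtype=np.int8
    )
    W = np.asarray(A.sum(axis=1)).ravel().astype(np.int64)
    return AnnotationMatrix(A=A, genes=genes, terms=terms, W_diag=W)


def annotated_direct_descendants(ont: Ontology, ann: AnnotationSet) -> dict[str, int]:
    """Per branch, the number of direct root children carrying >= 1 annotated
    gene (``ann`` must be propagated).  Their total fixes the topic count of
    the topic-model ranker."""
    annotated_terms = {t for _, t, _ in ann.records}
    out: dict[str, int] = {}
    for b in BRANCHES:
        root = ont.roots.get(b)
        if root is None:
            out[b] = 0
            continue
        out[b] = sum(1 for c in ont.children(root) if c in annotated_terms)
    return out
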