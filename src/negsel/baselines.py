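"""Comparison methods for negative-example selection.

All of these treat a gene as a "document" over the GO-term vocabulary:

* Rocchio — PU-style tf-idf prototype classifier; candidates scored by
  cosine(unlabeled prototype) - cosine(positive prototype), descending.
* 1-DNF — excludes every candidate carrying a term enriched among the
  positive class; fixed-size output.
* Sibling heuristic — genes annotated to a parent of the target term but
  not to the term itself; falls back to all non-positive genes when empty.
* Random baseline — uniform sampling without replacement from the full gene
  universe (annotated or not), replicated to smooth the noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import sparse

from .ontology import AnnotationMatrix, AnnotationSet, Ontology

__all__ = [
    "TfidfCorpus",
    "tfidf_corpus",
    "rocchio_scores",
    "one_dnf_negatives",
    "sibling_negatives",
    "random_negatives",
    "ROCCHIO_ALPHA",
    "ROCCHIO_BETA",
]

# Classic PU-Rocchio prototype weights.
ROCCHIO_ALPHA = 16.0
ROCCHIO_BETA = 4.0


@dataclass(frozen=True)
class TfidfCorpus:
    """Per-gene tf-idf vectors over the full GO-term vocabulary.

    tf is the raw (binary, post-propagation) count; idf = log(N / df), so a
    term annotated to every gene contributes nothing.
    """

    X: sparse.csr_matrix  # genes x terms, tf-idf weighted
    idf: np.ndarray
    genes: tuple[str, ...]
    terms: tuple[str, ...]

    @property
    def row_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


def tfidf_corpus(A: AnnotationMatrix) -> TfidfCorpus:
    n_genes = A.A.shape[0]
    df = np.asarray(A.A.sum(axis=0)).ravel().astype(np.float64)
    idf = np.zeros_like(df)
    nz = df > 0
    idf[nz] = np.log(n_genes / df[nz])
    X = A.A.astype(np.float64).multiply(idf[None, :]).tocsr()
    return TfidfCorpus(X=X, idf=idf, genes=A.genes, terms=A.terms)


def _l2_normalize(X: sparse.csr_matrix) -> sparse.csr_matrix:
    norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1)).ravel())
    inv = np.divide(1.0, norms, out=np.zeros_like(norms), where=norms > 0)
    return sparse.diags(inv) @ X


def rocchio_scores(
    corpus: TfidfCorpus,
    positives: Iterable[str],
    alpha: float = ROCCHIO_ALPHA,
    beta: float = ROCCHIO_BETA,
) -> pd.Series:
    """Negativity-confidence score for each unlabeled gene.

    Prototypes from length-normalized document vectors:

        c_pos = alpha * mean(P) - beta * mean(U)
        c_unl = alpha * mean(U) - beta * mean(P)

    score(v) = cos(v, c_unl) - cos(v, c_pos); HIGHER score = more confident
    negative, so rank descending.
    """
    pos = sorted(set(positives))
    row = corpus.row_index
    pos_rows = [row[g] for g in pos if g in row]
    unl_rows = [i for g, i in row.items() if g not in set(pos)]
    if not pos_rows:
        raise ValueError("empty positive class")
    if not unl_rows:
        raise ValueError("no unlabeled genes")
    Xn = _l2_normalize(corpus.X)
    mean_pos = np.asarray(Xn[pos_rows].mean(axis=0)).ravel()
    mean_unl = np.asarray(Xn[unl_rows].mean(axis=0)).ravel()
    c_pos = alpha * mean_pos - beta * mean_unl
    c_unl = alpha * mean_unl - beta * mean_pos
    # rows of Xn are unit-norm (or zero), so cos(v, c) = v.c / |c|
    U = Xn[unl_rows]
    sim_unl = _proto_cos(U, c_unl)
    sim_pos = _proto_cos(U, c_pos)
    genes = [corpus.genes[i] for i in unl_rows]
    return pd.Series(sim_unl - sim_pos, index=genes, dtype=float).sort_index()


def _proto_cos(U: sparse.csr_matrix, c: np.ndarray) -> np.ndarray:
    nc = np.linalg.norm(c)
    if nc == 0:
        return np.zeros(U.shape[0])
    return np.asarray(U @ c).ravel() / nc


def one_dnf_negatives(
    A: AnnotationMatrix, positives: Iterable[str], term: str = ""
) -> set[str]:
    """1-DNF rule: find terms whose document frequency among positives
    strictly exceeds that among unlabeled genes ("enriched words"); return
    all non-positive genes carrying none of them.  Fixed-size output."""
    pos = set(positives)
    if not pos:
        raise ValueError("empty positive class")
    row = {g: i for i, g in enumerate(A.genes)}
    pos_rows = [row[g] for g in sorted(pos) if g in row]
    unl_rows = [i for g, i in row.items() if g not in pos]
    if not unl_rows:
        return set()
    dense = A.A
    df_pos = np.asarray(dense[pos_rows].sum(axis=0)).ravel() / max(len(pos_rows), 1)
    df_unl = np.asarray(dense[unl_rows].sum(axis=0)).ravel() / len(unl_rows)
    enriched = df_pos > df_unl
    out: set[str] = set()
    for i in unl_rows:
        terms_i = dense[i].indices
        if not np.any(enriched[terms_i]):
            out.add(A.genes[i])
    return out


def sibling_negatives(
    ann: AnnotationSet,
    ont: Ontology,
    term: str,
    include_iea: bool = False,
) -> set[str]:
    """Sibling heuristic: genes annotated to a direct parent of ``term``
    (via retained edge types) but not to ``term`` itself.

    The positive class here excludes IEA annotations by default.  When the
    primary rule yields nothing, falls back to all annotated non-positive
    genes.  ``ann`` must be propagated.
    """
    parents = ont.parents(term)
    if not parents:
        raise ValueError(f"term {term} is a branch root")
    positives = ann.genes_for(term, include_iea=include_iea)
    candidates: set[str] = set()
    for p in parents:
        candidates |= ann.genes_for(p, include_iea=include_iea)
    negatives = candidates - positives
    if negatives:
        return negatives
    return set(ann.genes) - positives


def random_negatives(
    universe: Iterable[str],
    positives: Iterable[str],
    n: int,
    reps: int = 100,
    seed: int = 0,
) -> list[set[str]]:
    """Uniform samples without replacement from universe minus positives.

    Returns ``reps`` independent negative sets; evaluation averages their
    false-negative counts.  Unlike the other methods, the pool is the full
    gene universe, unannotated genes included.
    """
    pool = sorted(set(universe) - set(positives))
    if n > len(pool):
        raise ValueError(f"n={n} exceeds candidate pool of {len(pool)}")
    rng = np.random.default_rng(seed)
    pool_arr = np.array(pool)
    return [set(rng.choice(pool_arr, size=n, replace=False)) for _ in range(reps)]
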