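"""SNOB: Selection of Negatives through Observed Bias.

For a target GO term *a*, every candidate gene is scored by the average
empirical conditional probability of seeing *a* alongside each of the gene's
own annotations:

    p(a|m) = n_{m,a} / n_m        (co-annotation counts over all genes)
    s_i    = (1 / W_ii) * sum_{m : A[i,m]=1} p(a|m)

which is column *a* of S = W^-1 A P, where A is the propagated binary
annotation matrix, W the diagonal matrix of per-gene annotation totals and
P the pairwise conditional-probability matrix.  Low scores mark the genes
least likely to ever acquire the target annotation — the negative examples.

The module also provides ALBNeg, the stricter predecessor rule: a gene is a
negative for *a* iff none of its most specific (leaf-most) annotations has
ever co-occurred with *a*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .ontology import AnnotationMatrix, Ontology

__all__ = [
    "ConditionalProbabilityMatrix",
    "NegativeRanking",
    "conditional_probability",
    "snob_scores",
    "snob_rank",
    "rank_candidates",
    "albneg_negatives",
    "write_ranking",
    "point_ranking",
]


@dataclass(frozen=True)
class ConditionalProbabilityMatrix:
    """Dense pairwise conditional probabilities P[m, a] = p(a | m).

    Rows for terms never annotated (n_m = 0) are all-zero by convention,
    which avoids 0/0; such terms never contribute to any annotated gene's
    score.  Shares its term index with the annotation matrix columns.
    """

    P: np.ndarray
    terms: tuple[str, ...]
    n_term: np.ndarray  # per-term annotated gene counts n_m

    @property
    def col_index(self) -> dict[str, int]:
        return {t: j for j, t in enumerate(self.terms)}


@dataclass
class NegativeRanking:
    """Ordered candidate negatives for one target term, most confident first
    (ascending negativity-confidence score)."""

    term: str
    entries: list[tuple[str, float]]
    method_label: str = ""

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    def top(self, n: int) -> list[str]:
        return self.genes[:n]


def conditional_probability(A: AnnotationMatrix) -> ConditionalProbabilityMatrix:
    """Compute P[m, a] = |{i : A[i,m]=1 and A[i,a]=1}| / |{i : A[i,m]=1}|
    jointly across all three branches."""
    Af = A.A.astype(np.float64)
    co = np.asarray((Af.T @ Af).todense())  # n_{m,a}
    n = np.diag(co).copy()  # n_m
    with np.errstate(divide="ignore", invalid="ignore"):
        P = co / n[:, None]
    P[n == 0, :] = 0.0
    return ConditionalProbabilityMatrix(P=P, terms=A.terms, n_term=n.astype(np.int64))


def snob_scores(
    A: AnnotationMatrix, P: ConditionalProbabilityMatrix, term: str
) -> pd.Series:
    """Column ``term`` of S = W^-1 A P, indexed by gene.

    All annotations contribute — IEA included, all three branches.  Genes
    without annotations are not rows of A and are therefore not scored.
    """
    j = P.col_index[term]
    if P.n_term[j] == 0:
        raise ValueError(f"term {term} has no positive examples")
    raw = A.A @ P.P[:, j]
    scores = np.asarray(raw).ravel() / A.W_diag
    return pd.Series(scores, index=list(A.genes), name=term)


def rank_candidates(
    scores: Mapping[str, float] | pd.Series,
    positives: Iterable[str],
    n: int,
    *,
    term: str = "",
    method_label: str = "",
    ascending: bool = True,
) -> NegativeRanking:
    """Shared ranking step: drop positives, sort by score (ties broken by
    gene identifier), truncate to ``n``.

    ``ascending=True`` for scores where low means "more negative" (SNOB,
    DOS); ``False`` for confidence-of-negativity scores (Rocchio).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    pos = set(positives)
    s = pd.Series(scores, dtype=float)
    cand = s[~s.index.isin(pos)]
    key = cand if ascending else -cand
    order = sorted(cand.index, key=lambda g: (key[g], g))
    if n > len(order):
        warnings.warn(
            f"requested {n} negatives but only {len(order)} candidates; "
            "returning all",
            stacklevel=2,
        )
    chosen = order[:n]
    return NegativeRanking(
        term=term,
        entries=[(g, float(cand[g])) for g in chosen],
        method_label=method_label,
    )


def snob_rank(
    scores: Mapping[str, float] | pd.Series,
    positives: Iterable[str],
    n: int,
    term: str = "",
) -> NegativeRanking:
    """The n lowest-scoring non-positive genes, most confident negatives first."""
    return rank_candidates(
        scores, positives, n, term=term, method_label="snob", ascending=True
    )


def albneg_negatives(
    A: AnnotationMatrix,
    P: ConditionalProbabilityMatrix,
    ont: Ontology,
    term: str,
    positives: Iterable[str] | None = None,
) -> set[str]:
    """ALBNeg rule: genes none of whose most-specific annotations ever
    co-occurred with ``term``.

    ``A``/``P`` are expected to be built from curated (non-IEA) annotations;
    the positive class may be supplied separately (IEA included) to keep the
    candidate pool consistent with the other methods.  Fixed-size output:
    the rule admits no size parameter.
    """
    j = P.col_index[term]
    if P.n_term[j] == 0:
        raise ValueError(f"term {term} has no positive examples")
    pos = set(positives) if positives is not None else None
    col = P.P[:, j]
    out: set[str] = set()
    indptr, indices = A.A.indptr, A.A.indices
    for i, gene in enumerate(A.genes):
        ann_idx = indices[indptr[i] : indptr[i + 1]]
        ann_terms = {A.terms[k] for k in ann_idx}
        if term in ann_terms:
            continue
        if pos is not None and gene in pos:
            continue
        leaves = _leaf_most(ann_terms, ont)
        if all(col[A.col_index[t]] == 0.0 for t in leaves):
            out.add(gene)
    return out


def _leaf_most(terms: set[str], ont: Ontology) -> set[str]:
    """Terms in the set with no proper descendant also in the set."""
    return {t for t in terms if not (ont.descendants(t) & terms)}


def write_ranking(ranking: NegativeRanking, path: str | Path) -> None:
    """Write rank \\t gene \\t score; score 'NA' for scoreless (point) methods."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tgene\tscore\n")
        for r, (g, s) in enumerate(ranking.entries, start=1):
            sval = "NA" if s is None or (isinstance(s, float) and np.isnan(s)) else f"{s:.6g}"
            fh.write(f"{r}\t{g}\t{sval}\n")


def point_ranking(
    genes: Iterable[str], term: str = "", method_label: str = ""
) -> NegativeRanking:
    """Wrap an unscored negative set as a ranking (score NaN, sorted by id)."""
    return NegativeRanking(
        term=term,
        entries=[(g, float("nan")) for g in sorted(genes)],
        method_label=method_label,
    )
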