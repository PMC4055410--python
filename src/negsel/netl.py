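"""NETL: Negative Examples from Topic Likelihood.

Each gene is a "document" whose words are its propagated GO annotations
(IEA included, all three branches).  A latent Dirichlet allocation model
with t topics — t fixed to the total number of annotated direct children of
the three branch roots, so that w >> t while the topics still cover the
whole ontology — yields a posterior topic distribution per gene.  Candidates
are ranked by the Distributional-Overlap Score (DOS) between their posterior
and the positive class's average posterior; low overlap marks likely
negatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.decomposition import LatentDirichletAllocation

from .ontology import AnnotationMatrix, AnnotationSet, Ontology, annotated_direct_descendants
from .snob import NegativeRanking, rank_candidates

__all__ = [
    "TopicModel",
    "choose_topic_count",
    "fit_lda",
    "dos",
    "netl_rank",
]


def choose_topic_count(ont: Ontology, ann: AnnotationSet) -> int:
    """Topic count = total annotated direct descendants of the branch roots
    (``ann`` must be propagated)."""
    counts = annotated_direct_descendants(ont, ann)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no annotated root children")
    return total


@dataclass
class TopicModel:
    """Fitted LDA model with per-gene normalized posterior topic vectors."""

    lda: LatentDirichletAllocation
    theta: np.ndarray  # genes x topics, rows sum to 1
    genes: tuple[str, ...]
    terms: tuple[str, ...]

    @property
    def n_topics(self) -> int:
        return self.theta.shape[1]

    def posterior(self, gene: str) -> np.ndarray:
        return self.theta[self.genes.index(gene)]

    def save(self, prefix: str | Path) -> None:
        """Dump topics-by-terms and per-gene posteriors as TSV."""
        prefix = Path(prefix)
        pd.DataFrame(self.lda.components_, columns=list(self.terms)).to_csv(
            prefix.with_suffix(".topics.tsv"), sep="\t", index=False
        )
        pd.DataFrame(self.theta, index=list(self.genes)).to_csv(
            prefix.with_suffix(".theta.tsv"), sep="\t"
        )


def fit_lda(
    A: AnnotationMatrix,
    n_topics: int,
    seed: int,
    max_iter: int = 100,
) -> TopicModel:
    """Fit variational-Bayes LDA on the gene/annotation corpus.

    Symmetric Dirichlet priors alpha = 1/t on topics and eta = 0.01 on
    words.  The posterior is the normalized variational Dirichlet parameter
    vector (gamma / sum gamma).  The same seed yields identical posteriors.
    """
    n_terms_used = int((np.asarray(A.A.sum(axis=0)).ravel() > 0).sum())
    if not 1 <= n_topics < n_terms_used:
        raise ValueError(
            f"topic count {n_topics} must be in [1, vocabulary size {n_terms_used})"
        )
    if np.any(A.W_diag < 1):
        raise ValueError("every document (gene) must be non-empty")
    lda = LatentDirichletAllocation(
        n_components=n_topics,
        doc_topic_prior=1.0 / n_topics,
        topic_word_prior=0.01,
        max_iter=max_iter,
        random_state=seed,
        learning_method="batch",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn convergence chatter
        theta = lda.fit_transform(A.A)
    theta = np.asarray(theta, dtype=np.float64)
    theta /= theta.sum(axis=1, keepdims=True)
    return TopicModel(lda=lda, theta=theta, genes=A.genes, terms=A.terms)


def dos(p: np.ndarray, q: np.ndarray) -> float:
    """Distributional-Overlap Score between two normalized topic vectors.

    DOS(p, q) = sum_i min(p_i, q_i): a symmetric overlap bounded by [0, 1]
    for unit-sum vectors (equivalently 1 minus the total variation
    distance); 1 iff p = q, 0 iff their supports are disjoint.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    return float(np.minimum(p, q).sum())


def netl_rank(
    model: TopicModel,
    positives: Iterable[str],
    n: int,
    term: str = "",
) -> NegativeRanking:
    """Rank annotated non-positive genes by ascending DOS to the positive
    class's mean posterior (renormalized); lowest overlap = most likely
    negative.  Ties break by gene identifier."""
    pos = set(positives)
    gene_index = {g: i for i, g in enumerate(model.genes)}
    pos_rows = [gene_index[g] for g in sorted(pos) if g in gene_index]
    if not pos_rows:
        raise ValueError("no positive gene has a topic posterior")
    centroid = model.theta[pos_rows].mean(axis=0)
    centroid = centroid / centroid.sum()
    overlap = np.minimum(model.theta, centroid[None, :]).sum(axis=1)
    scores = pd.Series(overlap, index=list(model.genes), name=term)
    return rank_candidates(
        scores, pos, n, term=term, method_label="netl", ascending=True
    )
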