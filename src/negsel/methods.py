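"""Uniform rankers over the individual selection algorithms.

Every method becomes a callable ``ranker(term, n) -> list[genes]`` so the
evaluation harness and the CLI can treat ranked methods (SNOB, NETL,
Rocchio, random) and fixed-size point methods (ALBNeg, 1-DNF, sibling)
through one interface.  Point methods ignore ``n``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable

from . import baselines, netl, snob
from .ontology import AnnotationSet, Ontology, build_matrix, propagate
from .snob import NegativeRanking, point_ranking

RANKED_METHODS = ("snob", "netl", "rocchio", "random")
POINT_METHODS = ("albneg", "one_dnf", "sibling")
ALL_METHODS = RANKED_METHODS + POINT_METHODS

__all__ = ["MethodRanker", "make_ranker", "RANKED_METHODS", "POINT_METHODS", "ALL_METHODS"]


@dataclass
class MethodRanker:
    """A prepared method bound to one training snapshot."""

    name: str
    kind: str  # "ranked" | "point"
    _rank: Callable[[str, int], NegativeRanking]

    def ranking(self, term: str, n: int) -> NegativeRanking:
        return self._rank(term, n)

    def __call__(self, term: str, n: int) -> list[str]:
        return self._rank(term, n).genes


def make_ranker(
    name: str,
    ann: AnnotationSet,
    ont: Ontology,
    include_iea: bool = True,
    seed: int = 0,
    lda_max_iter: int = 100,
) -> MethodRanker:
    """Prepare ``name`` on the (raw or propagated) training snapshot ``ann``.

    The positive class for every method includes IEA annotations of the
    target term; ALBNeg and the sibling heuristic additionally restrict
    their own evidence usage to curated records, per their definitions.
    """
    prop = propagate(ann, ont)

    def positives(term: str) -> set[str]:
        return prop.genes_for(term, include_iea=True)

    if name == "snob":
        A = build_matrix(prop, ont, include_iea=include_iea, assume_propagated=True)
        cp = snob.conditional_probability(A)

        def rank(term: str, n: int) -> NegativeRanking:
            scores = snob.snob_scores(A, cp, term)
            return snob.snob_rank(scores, positives(term), n, term=term)

        return MethodRanker(name, "ranked", rank)

    if name == "netl":
        A = build_matrix(prop, ont, include_iea=include_iea, assume_propagated=True)
        t = netl.choose_topic_count(ont, prop)
        model = netl.fit_lda(A, t, seed=seed, max_iter=lda_max_iter)

        def rank(term: str, n: int) -> NegativeRanking:
            return netl.netl_rank(model, positives(term), n, term=term)

        return MethodRanker(name, "ranked", rank)

    if name == "rocchio":
        A = build_matrix(prop, ont, include_iea=include_iea, assume_propagated=True)
        corpus = baselines.tfidf_corpus(A)

        def rank(term: str, n: int) -> NegativeRanking:
            scores = baselines.rocchio_scores(corpus, positives(term))
            return snob.rank_candidates(
                scores, positives(term), n, term=term,
                method_label="rocchio", ascending=False,
            )

        return MethodRanker(name, "ranked", rank)

    if name == "random":
        universe = sorted(prop.gene_universe)

        def rank(term: str, n: int) -> NegativeRanking:
            # per-term deterministic sub-seed; a single replicate
            sub = (seed * 1_000_003 + zlib.crc32(term.encode())) % 2**31
            reps = baselines.random_negatives(
                universe, positives(term), min(n, len(universe) - len(positives(term))),
                reps=1, seed=sub,
            )
            return point_ranking(reps[0], term=term, method_label="random")

        return MethodRanker(name, "ranked", rank)

    if name == "albneg":
        A = build_matrix(prop, ont, include_iea=False, assume_propagated=True)
        cp = snob.conditional_probability(A)

        def rank(term: str, n: int) -> NegativeRanking:
            return point_ranking(
                snob.albneg_negatives(A, cp, ont, term, positives=positives(term)),
                term=term, method_label="albneg",
            )

        return MethodRanker(name, "point", rank)

    if name == "one_dnf":
        A = build_matrix(prop, ont, include_iea=include_iea, assume_propagated=True)

        def rank(term: str, n: int) -> NegativeRanking:
            return point_ranking(
                baselines.one_dnf_negatives(A, positives(term), term),
                term=term, method_label="one_dnf",
            )

        return MethodRanker(name, "point", rank)

    if name == "sibling":

        def rank(term: str, n: int) -> NegativeRanking:
            return point_ranking(
                baselines.sibling_negatives(prop, ont, term),
                term=term, method_label="sibling",
            )

        return MethodRanker(name, "point", rank)

    raise ValueError(f"unknown method {name!r}; choose from {ALL_METHODS}")
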