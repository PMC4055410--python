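"""Temporal-holdout evaluation of negative-example selection.

A method is trained on an older annotation snapshot (t0) and judged against
a newer one (t1): every predicted negative that acquires a positive
annotation for the target term by t1 is a false negative (FN).  Because the
trivial empty prediction has zero FNs, performance is summarized as a curve
of FN count versus negative-set size, compared against the random-sampling
baseline through the ratio of areas under the two curves.  A golden set —
a term with exhaustively verified positive and negative labels — instead
supports a conventional cross-validated ROC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .ontology import AnnotationSet, Ontology

__all__ = [
    "DEFAULT_GRID",
    "GENOME_FRACTION_GRID",
    "SPECIFICITY_BUCKETS",
    "HoldoutPair",
    "FNCurve",
    "ROCResult",
    "count_false_negatives",
    "eligible_terms",
    "fn_curve",
    "fn_point",
    "average_curves",
    "bucketed_average",
    "area_ratio",
    "equal_positives_fn_rate",
    "golden_set_roc",
    "point_roc",
    "cross_validated_negativity_scores",
    "fractional_grid",
]

#: FN sampling grid for genome-scale runs (negative-set sizes).
DEFAULT_GRID = (100, 200, 500, 1000, 2000, 3000)

#: Alternative grid expressed as fractions of the genome size.
GENOME_FRACTION_GRID = (0.001, 0.005, 0.01, 0.025, 0.05, 0.10, 0.15, 0.20)

#: Term-specificity buckets by training annotation count.
SPECIFICITY_BUCKETS = ((3, 10), (11, 30), (31, 100), (101, 300))


def fractional_grid(genome_size: int, fractions: Sequence[float] = GENOME_FRACTION_GRID) -> tuple[int, ...]:
    """Convert genome-size fractions to integer negative-set sizes (>= 1)."""
    return tuple(max(1, int(round(f * genome_size))) for f in fractions)


@dataclass(frozen=True)
class HoldoutPair:
    """Propagated training (t0) and validation (t1) snapshots over one ontology."""

    train: AnnotationSet
    validate: AnnotationSet
    ontology: Ontology
    include_iea_validation: bool = True

    def __post_init__(self) -> None:
        if self.train.snapshot_label == self.validate.snapshot_label:
            warnings.warn(
                "training and validation snapshots carry the same label",
                stacklevel=2,
            )

    @classmethod
    def build(
        cls,
        train: AnnotationSet,
        validate: AnnotationSet,
        ontology: Ontology,
        include_iea_validation: bool = True,
    ) -> "HoldoutPair":
        from .ontology import propagate

        return cls(
            train=propagate(train, ontology),
            validate=propagate(validate, ontology),
            ontology=ontology,
            include_iea_validation=include_iea_validation,
        )

    def validation_positives(self, term: str) -> set[str]:
        return self.validate.genes_for(term, include_iea=self.include_iea_validation)

    def training_positives(self, term: str, include_iea: bool = True) -> set[str]:
        return self.train.genes_for(term, include_iea=include_iea)

    def new_positives(self, term: str) -> set[str]:
        """Genes gaining the term between t0 and t1 (observable FN pool)."""
        return self.validation_positives(term) - self.training_positives(term)


@dataclass
class FNCurve:
    """False negatives as a function of negative-set size for one term (or
    an average across terms; counts may then be fractional)."""

    term: str
    sizes: list[float]
    fn: list[float]
    new_annotation_count: int = 0
    clamped: list[bool] = field(default_factory=list)

    def area(self) -> float:
        """Trapezoid area under the curve, anchored at (0, 0)."""
        xs = np.concatenate([[0.0], np.asarray(self.sizes, dtype=float)])
        ys = np.concatenate([[0.0], np.asarray(self.fn, dtype=float)])
        return float(np.trapezoid(ys, xs))


def count_false_negatives(
    negatives: Iterable[str], term: str, holdout: HoldoutPair
) -> int:
    """Predicted negatives that are annotated to ``term`` in the validation
    snapshot (IEA counted iff the holdout says so)."""
    return len(set(negatives) & holdout.validation_positives(term))


def eligible_terms(
    holdout: HoldoutPair, min_ann: int = 3, max_ann: int = 300
) -> dict[str, set[str]]:
    """Per branch, terms with a t0 annotation count in [min_ann, max_ann]
    and at least one new t1 annotation (otherwise no FN is observable)."""
    counts = holdout.train.counts_per_term(include_iea=True)
    out: dict[str, set[str]] = {b: set() for b in holdout.ontology.roots}
    for term, c in counts.items():
        if not min_ann <= c <= max_ann:
            continue
        if not holdout.new_positives(term):
            continue
        out[holdout.ontology.branch[term]].add(term)
    return out


Ranker = Callable[[str, int], Sequence[str]]


def fn_curve(
    ranker: Ranker,
    holdout: HoldoutPair,
    term: str,
    grid: Sequence[int] = DEFAULT_GRID,
) -> FNCurve:
    """Sample FN counts at each grid size: rank, truncate, count.

    A grid value exceeding the candidate pool is clamped to the pool size
    and flagged.
    """
    sizes: list[float] = []
    fns: list[float] = []
    clamped: list[bool] = []
    for n in grid:
        negs = list(ranker(term, n))
        sizes.append(float(len(negs)))
        fns.append(float(count_false_negatives(negs, term, holdout)))
        clamped.append(len(negs) < n)
    return FNCurve(
        term=term,
        sizes=sizes,
        fn=fns,
        new_annotation_count=len(holdout.new_positives(term)),
        clamped=clamped,
    )


def fn_point(
    negatives: Iterable[str], holdout: HoldoutPair, term: str
) -> FNCurve:
    """Single-point curve for fixed-size (point) methods."""
    negs = set(negatives)
    return FNCurve(
        term=term,
        sizes=[float(len(negs))],
        fn=[float(count_false_negatives(negs, term, holdout))],
        new_annotation_count=len(holdout.new_positives(term)),
        clamped=[False],
    )


def average_curves(curves: Sequence[FNCurve], term: str = "average") -> FNCurve:
    """Unweighted elementwise mean across terms sharing a grid.

    Point-method curves of varying size average both coordinates (the
    resulting single point sits at the mean size / mean FN).
    """
    if not curves:
        raise ValueError("no curves to average")
    n_pts = {len(c.sizes) for c in curves}
    if len(n_pts) != 1:
        raise ValueError("curves have differing numbers of sample points")
    sizes = np.mean([c.sizes for c in curves], axis=0)
    fns = np.mean([c.fn for c in curves], axis=0)
    return FNCurve(
        term=term,
        sizes=list(map(float, sizes)),
        fn=list(map(float, fns)),
        new_annotation_count=int(sum(c.new_annotation_count for c in curves)),
    )


def bucketed_average(
    curves: Mapping[str, FNCurve],
    t0_counts: Mapping[str, int],
    buckets: Sequence[tuple[int, int]] = SPECIFICITY_BUCKETS,
) -> dict[tuple[int, int], FNCurve]:
    """Average curves within term-specificity buckets by t0 annotation count."""
    out: dict[tuple[int, int], FNCurve] = {}
    for lo, hi in buckets:
        members = [c for t, c in curves.items() if lo <= t0_counts.get(t, 0) <= hi]
        if members:
            out[(lo, hi)] = average_curves(members, term=f"{lo}-{hi}")
    return out


def area_ratio(
    curves: FNCurve | Mapping[str, FNCurve],
    baselines: FNCurve | Mapping[str, FNCurve],
    mode: str = "weighted",
) -> float:
    """Area under the FN curve relative to the random baseline.

    ``weighted``: sum areas over terms, then divide by the summed baseline
    areas (terms with many new annotations dominate).  ``per-term``: divide
    per term first, then average, so every term contributes equally; terms
    with zero baseline area are skipped with a warning.
    """
    if isinstance(curves, FNCurve):
        curves = {curves.term: curves}
    if isinstance(baselines, FNCurve):
        baselines = {baselines.term: baselines}
    common = sorted(set(curves) & set(baselines))
    if not common:
        raise ValueError("no common terms between curves and baselines")
    if mode == "weighted":
        num = sum(curves[t].area() for t in common)
        den = sum(baselines[t].area() for t in common)
        if den == 0:
            raise ValueError("baseline area is zero for every term")
        return num / den
    if mode == "per-term":
        ratios = []
        for t in common:
            base = baselines[t].area()
            if base == 0:
                warnings.warn(f"term {t}: zero baseline area, skipped", stacklevel=2)
                continue
            ratios.append(curves[t].area() / base)
        if not ratios:
            raise ValueError("no term with positive baseline area")
        return float(np.mean(ratios))
    raise ValueError(f"unknown mode {mode!r}")


def equal_positives_fn_rate(
    ranker: Ranker,
    holdout: HoldoutPair,
    terms: Iterable[str],
) -> float:
    """FN rate when predicting, per term, as many negatives as the term has
    t0 positive annotations; totals aggregated before dividing."""
    total_fn = 0
    total_pred = 0
    for term in sorted(terms):
        n = len(holdout.training_positives(term))
        negs = list(ranker(term, n))
        total_fn += count_false_negatives(negs, term, holdout)
        total_pred += len(negs)
    if total_pred == 0:
        return 0.0
    return total_fn / total_pred


# ---------------------------------------------------------------------------
# Golden-set ROC
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def golden_set_roc(
    scores: Mapping[str, float],
    gold_positives: Iterable[str],
    gold_negatives: Iterable[str],
    *,
    higher_is_more_negative: bool = False,
) -> ROCResult:
    """ROC over exhaustively labelled gold classes, negatives as the class
    of interest.

    ``scores`` follow the ranking convention (low = more confidently
    negative) unless ``higher_is_more_negative``.  The sweep over score
    thresholds uses trapezoid AUC; constant scores give AUC 0.5 exactly.
    """
    pos = set(gold_positives)
    neg = set(gold_negatives)
    if pos & neg:
        raise ValueError("gold classes overlap")
    genes = sorted(pos | neg)
    missing = [g for g in genes if g not in scores]
    if missing:
        raise ValueError(f"{len(missing)} gold genes lack scores (e.g. {missing[:3]})")
    y = np.array([1 if g in neg else 0 for g in genes])
    s = np.array([scores[g] for g in genes], dtype=float)
    if not higher_is_more_negative:
        s = -s
    fpr, tpr, _ = roc_curve(y, s)
    return ROCResult(fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)))


def point_roc(
    negatives: Iterable[str],
    gold_positives: Iterable[str],
    gold_negatives: Iterable[str],
) -> tuple[float, float]:
    """(FPR, TPR) of a fixed negative set against the gold labels, negatives
    as the class of interest."""
    negs = set(negatives)
    pos = set(gold_positives)
    neg = set(gold_negatives)
    tpr = len(negs & neg) / len(neg) if neg else 0.0
    fpr = len(negs & pos) / len(pos) if pos else 0.0
    return fpr, tpr


ScoreFn = Callable[[AnnotationSet], Mapping[str, float]]


def cross_validated_negativity_scores(
    score_fn: ScoreFn,
    ann: AnnotationSet,
    ont: Ontology,
    term: str,
    gold_positives: Iterable[str],
    gold_negatives: Iterable[str],
    folds: int = 5,
    seed: int = 0,
    missing_score: float = 0.0,
) -> dict[str, float]:
    """Stratified k-fold scores with the gold term masked from held-out genes.

    In each fold the raw (unpropagated) annotations of held-out genes to the
    gold term and its descendants are removed, ``score_fn`` rescoring the
    masked snapshot; only held-out genes' scores are collected.  A held-out
    gene left without annotations (hence unscorable) receives
    ``missing_score`` — no annotation evidence, maximal negativity under the
    low-score-is-negative convention.
    """
    masked_terms = {term} | set(ont.descendants(term))
    genes = sorted(set(gold_positives) | set(gold_negatives))
    labels = np.array([1 if g in set(gold_positives) else 0 for g in genes])
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("gold set must contain both classes")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    out: dict[str, float] = {}
    gene_arr = np.array(genes)
    for _, test_idx in skf.split(gene_arr, labels):
        held = set(gene_arr[test_idx])
        masked_records = frozenset(
            r
            for r in ann.records
            if not (r[0] in held and r[1] in masked_terms)
        )
        masked = AnnotationSet(
            records=masked_records,
            snapshot_label=ann.snapshot_label + "+masked",
            gene_universe=ann.gene_universe,
        )
        fold_scores = score_fn(masked)
        for g in sorted(held):
            out[g] = float(fold_scores.get(g, missing_score)) if hasattr(
                fold_scores, "get"
            ) else float(fold_scores[g])
    return out
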