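"""Shared fixtures: hand-built toy ontologies/annotations and the synthetic
benchmark results reused by the slower end-to-end assertions."""

from __future__ import annotations

import numpy as np
import pytest

from negsel.ontology import AnnotationSet, Ontology
from negsel.synthetic import SyntheticSpec, generate


def make_toy_ontology() -> Ontology:
    """Three small branches:

    BP: R1 -> {B1, B2}; B1 -> {B3, B4}; B2 -> B4 (diamond at B4)
    MF: R2 -> M1 -> M2
    CC: R3 -> C1
    """
    edges = {
        ("GO:0000011", "GO:0000001", "is_a"),  # B1 -> R1
        ("GO:0000012", "GO:0000001", "is_a"),  # B2 -> R1
        ("GO:0000013", "GO:0000011", "is_a"),  # B3 -> B1
        ("GO:0000014", "GO:0000011", "is_a"),  # B4 -> B1
        ("GO:0000014", "GO:0000012", "part_of"),  # B4 -> B2
        ("GO:0000021", "GO:0000002", "is_a"),  # M1 -> R2
        ("GO:0000022", "GO:0000021", "is_a"),  # M2 -> M1
        ("GO:0000031", "GO:0000003", "is_a"),  # C1 -> R3
    }
    terms = {t for e in edges for t in e[:2]}
    branch = {}
    for t in terms:
        if t in {"GO:0000001", "GO:0000011", "GO:0000012", "GO:0000013", "GO:0000014"}:
            branch[t] = "BP"
        elif t in {"GO:0000002", "GO:0000021", "GO:0000022"}:
            branch[t] = "MF"
        else:
            branch[t] = "CC"
    roots = {"BP": "GO:0000001", "MF": "GO:0000002", "CC": "GO:0000003"}
    ont = Ontology(frozenset(terms), frozenset(edges), branch, roots)
    ont.validate()
    return ont


# readable aliases used throughout the tests
R1, B1, B2, B3, B4 = "GO:0000001", "GO:0000011", "GO:0000012", "GO:0000013", "GO:0000014"
R2, M1, M2 = "GO:0000002", "GO:0000021", "GO:0000022"
R3, C1 = "GO:0000003", "GO:0000031"


@pytest.fixture(scope="session")
def toy_ontology() -> Ontology:
    return make_toy_ontology()


@pytest.fixture()
def toy_annotations() -> AnnotationSet:
    """Unpropagated: Ga -> B3 (EXP), B4 (IEA); Gb -> B4 (IDA); Gc -> M2 (IEA)."""
    return AnnotationSet(
        frozenset(
            {
                ("Ga", B3, "EXP"),
                ("Ga", B4, "IEA"),
                ("Gb", B4, "IDA"),
                ("Gc", M2, "IEA"),
            }
        ),
        snapshot_label="toy",
    )


def random_layered_dag(rng: np.random.Generator, n_terms: int = 20) -> Ontology:
    """Single-branch random layered DAG for property tests."""
    terms = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    root = terms[0]
    edges = set()
    branch = {t: "BP" for t in terms}
    for i, t in enumerate(terms[1:], start=1):
        n_par = 1 + int(rng.random() < 0.4)
        parents = rng.choice(i, size=min(n_par, i), replace=False)
        for p in parents:
            rel = "part_of" if rng.random() < 0.2 else "is_a"
            edges.add((t, terms[int(p)], rel))
    ont = Ontology(frozenset(terms), frozenset(edges), branch, {"BP": root})
    ont.validate()
    return ont


def random_annotations(
    rng: np.random.Generator, ont: Ontology, n_genes: int = 20, p: float = 0.2
) -> AnnotationSet:
    genes = [f"G{i:03d}" for i in range(n_genes)]
    terms = sorted(ont.terms)
    records = set()
    for g in genes:
        drawn = [t for t in terms if rng.random() < p]
        if not drawn:
            drawn = [terms[int(rng.integers(len(terms)))]]
        for t in drawn:
            ev = "IEA" if rng.random() < 0.3 else "EXP"
            records.add((g, t, ev))
    return AnnotationSet(frozenset(records), snapshot_label="rand")


@pytest.fixture(scope="session")
def synthetic_default():
    """One default-condition synthetic dataset, shared across test modules."""
    return generate(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def benchmark_results():
    """Area-ratio benchmark over 3 seeds for the ranked methods + sibling.

    Session-scoped because the ordering assertions in several modules reuse
    it; the dedicated multi-seed acceptance checks recompute at 5 seeds.
    """
    import warnings

    from negsel.pipeline import run_benchmark

    out = []
    for seed in (0, 1, 2):
        data = generate(SyntheticSpec(seed=seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_benchmark(
                ["snob", "netl", "rocchio", "sibling"],
                data.train,
                data.validate,
                data.ontology,
                seed=seed,
                baseline_reps=50,
            )
        out.append(res)
    return out
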