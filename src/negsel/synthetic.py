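"""Synthetic GO-like benchmark with planted negative-example ground truth.

The generator builds a three-branch layered DAG ontology, assigns each gene
to one of several mutually exclusive "function modules" (or to an unmodular
background), draws within-module annotations with a fixed co-occurrence
probability, and splits the truth into two temporal snapshots by hiding a
fraction of the true annotations at t0 and revealing them at t1.  Because
modules never share genes, every gene of another module is a certain
negative for each module term — exactly the co-annotation structure the
selection algorithms are meant to exploit, with a known answer key.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ontology import BRANCHES, AnnotationSet, Ontology

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate", "golden_set", "write_dataset"]

_NAMESPACES = {"BP": "biological_process", "MF": "molecular_function", "CC": "cellular_component"}
_NON_IEA_CODES = ("EXP", "IDA", "IMP")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic benchmark.

    Defaults give a seconds-scale dataset with enough signal for a stable
    ordering of the selection methods: 500 genes, 60 terms per branch in a
    depth-4 DAG, 3 exclusive modules of 8 terms, within-module annotation
    probability 0.6, 20% of true annotations hidden until t1, and 30% of
    records carrying the uncurated IEA evidence code.
    """

    n_genes: int = 500
    terms_per_branch: int = 60
    dag_depth: int = 4
    n_modules: int = 3
    module_size: int = 8
    co_occurrence: float = 0.6
    holdout_fraction: float = 0.2
    iea_fraction: float = 0.3
    module_gene_fraction: float = 0.75
    background_rate: float = 1.5  # Poisson mean of background annotations per gene
    part_of_fraction: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in [0, 1)")
        if not 0 < self.co_occurrence <= 1:
            raise ValueError("co_occurrence must be in (0, 1]")
        if self.n_modules < 1 or self.module_size < 1:
            raise ValueError("need at least one module with at least one term")
        deep_terms = self.terms_per_branch // 2  # layers >= 2 hold about half
        per_branch = -(-self.n_modules // len(BRANCHES)) * self.module_size
        if per_branch > deep_terms:
            raise ValueError(
                f"infeasible spec: {self.n_modules} modules x {self.module_size} "
                f"terms do not fit in {self.terms_per_branch} terms/branch"
            )
        if self.dag_depth < 2:
            raise ValueError("dag_depth must be >= 2")


@dataclass
class SyntheticDataset:
    ontology: Ontology
    train: AnnotationSet  # t0
    validate: AnnotationSet  # t1 = t0 plus revealed annotations
    truth: dict[str, frozenset[str]]  # module term -> planted true negatives
    modules: dict[int, tuple[str, ...]]  # module -> its terms (sorted)
    module_roots: dict[int, str]  # module -> designated representative term
    gene_module: dict[str, int | None]
    spec: SyntheticSpec = field(default_factory=SyntheticSpec)

    @property
    def genome_size(self) -> int:
        return len(self.train.gene_universe)


def _term_id(k: int) -> str:
    return f"GO:{k:07d}"


def _build_branch_dag(
    rng: np.random.Generator,
    first_id: int,
    n_terms: int,
    depth: int,
    part_of_fraction: float,
    branch: str,
) -> tuple[str, list[str], dict[int, list[str]], set[tuple[str, str, str]]]:
    """Layered random DAG: one root, ``n_terms`` further terms spread over
    ``depth`` layers, each term linked to 1-2 parents in the layer above."""
    root = _term_id(first_id)
    terms = [_term_id(first_id + 1 + i) for i in range(n_terms)]
    layer_of: dict[str, int] = {}
    layers: dict[int, list[str]] = {0: [root]}
    for i, t in enumerate(terms):
        layer = 1 + (i * depth) // n_terms  # balanced layers 1..depth
        layer_of[t] = layer
        layers.setdefault(layer, []).append(t)
    edges: set[tuple[str, str, str]] = set()
    for layer in range(1, depth + 1):
        above = layers.get(layer - 1, [root])
        for t in layers.get(layer, []):
            k = 1 + int(rng.random() < 0.5 and len(above) > 1)
            parents = rng.choice(len(above), size=min(k, len(above)), replace=False)
            for pi in parents:
                rel = "part_of" if rng.random() < part_of_fraction else "is_a"
                edges.add((t, above[int(pi)], rel))
    return root, terms, layers, edges


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one synthetic benchmark: ontology, two snapshots, ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    all_terms: set[str] = set()
    all_edges: set[tuple[str, str, str]] = set()
    branch_map: dict[str, str] = {}
    roots: dict[str, str] = {}
    deep_terms: dict[str, list[str]] = {}  # branch -> terms in layers >= 2
    next_id = 1
    for b in BRANCHES:
        root, terms, layers, edges = _build_branch_dag(
            rng, next_id, spec.terms_per_branch, spec.dag_depth,
            spec.part_of_fraction, b,
        )
        next_id += 1 + spec.terms_per_branch
        roots[b] = root
        all_terms.update([root], terms)
        all_edges.update(edges)
        for t in [root] + terms:
            branch_map[t] = b
        deep_terms[b] = sorted(
            t for layer, ts in layers.items() if layer >= 2 for t in ts
        )
    ont = Ontology(frozenset(all_terms), frozenset(all_edges), branch_map, roots)
    ont.validate()

    # --- plant modules: antichains of deep terms, one branch per module ---
    modules: dict[int, tuple[str, ...]] = {}
    taken: set[str] = set()  # module terms + their ancestors/descendants
    for m in range(spec.n_modules):
        b = BRANCHES[m % len(BRANCHES)]
        pool = [t for t in deep_terms[b] if t not in taken]
        chosen: list[str] = []
        order = rng.permutation(len(pool))
        for idx in order:
            t = pool[int(idx)]
            if t in taken:
                continue
            # keep module terms pairwise non-ancestral (an antichain) so the
            # designated representative has no module-term descendants
            if any(t in ont.ancestors(c) or c in ont.ancestors(t) for c in chosen):
                continue
            chosen.append(t)
            if len(chosen) == spec.module_size:
                break
        if len(chosen) < spec.module_size:
            raise ValueError(
                f"infeasible spec: could not place module {m} in branch {b}"
            )
        modules[m] = tuple(sorted(chosen))
        for c in chosen:
            taken.add(c)
            taken |= ont.ancestors(c) & set(deep_terms[b])
            taken |= ont.descendants(c)
    module_roots = {m: ts[0] for m, ts in modules.items()}
    module_terms = {t for ts in modules.values() for t in ts}

    # background pool: never a module term, never below one (so upward
    # propagation of a background annotation cannot fabricate module terms)
    below_modules: set[str] = set()
    for t in module_terms:
        below_modules |= ont.descendants(t)
    background_pool = sorted(all_terms - module_terms - below_modules - set(roots.values()))

    # --- genes and true annotations ---
    genes = [f"G{i:05d}" for i in range(1, spec.n_genes + 1)]
    gene_module: dict[str, int | None] = {}
    true_records: list[tuple[str, str]] = []
    for g in genes:
        if rng.random() < spec.module_gene_fraction:
            m = int(rng.integers(spec.n_modules))
        else:
            m = None
        gene_module[g] = m
        own: list[str] = []
        if m is not None:
            for t in modules[m]:
                if rng.random() < spec.co_occurrence:
                    own.append(t)
            if not own:  # every module gene carries >= 1 module term
                own.append(modules[m][int(rng.integers(len(modules[m])))])
        n_bg = int(rng.poisson(spec.background_rate)) + (1 if m is None else 0)
        if n_bg and background_pool:
            picks = rng.choice(len(background_pool), size=min(n_bg, len(background_pool)), replace=False)
            own.extend(background_pool[int(i)] for i in picks)
        for t in set(own):
            true_records.append((g, t))

    # --- evidence codes and temporal split ---
    # Each record is hidden at t0 independently with holdout_fraction, except
    # that a module gene always keeps >= 1 module annotation visible: a
    # "held-out positive" must still carry the planted co-occurrence
    # structure at t0, otherwise it degenerates into an unlabeled background
    # gene and the planted ground truth loses its meaning.
    t0: set[tuple[str, str, str]] = set()
    t1: set[tuple[str, str, str]] = set()
    visible_module_terms: dict[str, list[str]] = {}
    hidden_module_recs: dict[str, list[tuple[str, str, str]]] = {}
    for g, t in sorted(true_records):
        ev = (
            "IEA"
            if rng.random() < spec.iea_fraction
            else _NON_IEA_CODES[int(rng.integers(len(_NON_IEA_CODES)))]
        )
        rec = (g, t, ev)
        t1.add(rec)
        is_module_term = t in module_terms
        if rng.random() >= spec.holdout_fraction:
            t0.add(rec)
            if is_module_term:
                visible_module_terms.setdefault(g, []).append(t)
        elif is_module_term:
            hidden_module_recs.setdefault(g, []).append(rec)
    for g, m in gene_module.items():
        if m is None or g in visible_module_terms:
            continue
        hid = hidden_module_recs.get(g, [])
        if hid:
            t0.add(hid[int(rng.integers(len(hid)))])

    universe = frozenset(genes)
    train = AnnotationSet(frozenset(t0), snapshot_label="t0", gene_universe=universe)
    validate = AnnotationSet(frozenset(t1), snapshot_label="t1", gene_universe=universe)

    truth = {
        t: frozenset(
            g for g, gm in gene_module.items() if gm is not None and gm != m
        )
        for m, ts in modules.items()
        for t in ts
    }
    return SyntheticDataset(
        ontology=ont,
        train=train,
        validate=validate,
        truth=truth,
        modules=modules,
        module_roots=module_roots,
        gene_module=gene_module,
        spec=spec,
    )


def golden_set(
    data: SyntheticDataset, module: int = 0
) -> tuple[str, frozenset[str], frozenset[str]]:
    """Complete labelling for one module's representative term: positives
    are the module's genes, negatives every other gene in the genome."""
    term = data.module_roots[module]
    pos = frozenset(g for g, m in data.gene_module.items() if m == module)
    neg = frozenset(data.train.gene_universe) - pos
    return term, pos, neg


def write_dataset(data: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit OBO + TSV snapshots + truth/golden JSON so the full file-based
    workflow can be exercised end to end."""
    from .ontology import write_annotations

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "obo": outdir / "ontology.obo",
        "train": outdir / "annotations_t0.tsv",
        "validate": outdir / "annotations_t1.tsv",
        "truth": outdir / "truth.json",
        "golden": outdir / "golden_set.json",
    }
    _write_obo(data.ontology, paths["obo"])
    write_annotations(data.train, paths["train"])
    write_annotations(data.validate, paths["validate"])
    paths["truth"].write_text(
        json.dumps(
            {t: sorted(gs) for t, gs in sorted(data.truth.items())}, indent=1
        )
    )
    term, pos, neg = golden_set(data)
    paths["golden"].write_text(
        json.dumps(
            {"term": term, "positives": sorted(pos), "negatives": sorted(neg)},
            indent=1,
        )
    )
    return paths


def _write_obo(ont: Ontology, path: Path) -> None:
    by_child: dict[str, list[tuple[str, str]]] = {}
    for c, p, rel in ont.edges:
        by_child.setdefault(c, []).append((rel, p))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")
        for t in sorted(ont.terms):
            fh.write(f"\n[Term]\nid: {t}\nname: synthetic term {t}\n")
            fh.write(f"namespace: {_NAMESPACES[ont.branch[t]]}\n")
            for rel, p in sorted(by_child.get(t, [])):
                if rel == "is_a":
                    fh.write(f"is_a: {p} ! parent\n")
                else:
                    fh.write(f"relationship: {rel} {p} ! parent\n")
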