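# negsel — negative-example selection for protein function annotation

Gene Ontology (GO) databases record which functions a gene *has*, almost
never which functions it does *not* have. Machine-learning methods for
protein function prediction still need a negative class, and careless
choices (random genes, "everything unannotated", sibling-annotated genes)
silently train on future positives. `negsel` selects reliable negative
examples from positive-only annotation data and measures how often such
selections go wrong.

It implements, behind one library/CLI surface:

* **SNOB** — ranks each candidate gene for a target term *a* by the
  average empirical conditional probability of *a* given the gene's own
  annotations: `p(a|m) = n_{m,a}/n_m`, score vector `S = W⁻¹AP` where
  **A** is the propagated binary gene×term matrix, **W** the diagonal
  per-gene annotation totals and **P** the pairwise conditional-probability
  matrix. Lowest scores = most confident negatives.
* **ALBNeg** — the stricter fixed-size rule: admit a gene iff none of its
  most specific annotations ever co-occurred with the target term.
* **NETL** — fits latent Dirichlet allocation on the gene/annotation
  corpus (genes as documents, GO terms as words; topic count = number of
  annotated direct children of the three branch roots) and ranks by
  ascending Distributional-Overlap Score `DOS(p,q) = Σᵢ min(pᵢ,qᵢ)` to the
  positive class's mean topic posterior.
* **PU baselines** — Rocchio (tf-idf prototypes, score
  `cos(v,c_unl) − cos(v,c_pos)`), 1-DNF (enriched-term exclusion), the
  sibling heuristic, and a replicated uniform-random baseline.
* **Temporal-holdout evaluation** — train on an old snapshot, count as
  false negatives all predicted negatives that gain the annotation in a
  newer snapshot; false-negative curves over negative-set sizes, areas
  relative to the random baseline, equal-positives error rates,
  specificity buckets, and cross-validated golden-set ROC/AUC.
* **Synthetic benchmark generator** — three-branch DAG ontologies with
  planted, mutually exclusive co-annotation modules and two temporal
  snapshots, so every algorithm is testable with known ground truth.

File formats: OBO 1.2 ontologies, GAF 2.x or a 3-column TSV dialect
(`gene	GO-term	evidence-code`) for annotations, Matrix Market for cached
matrices, TSV/CSV/JSON for outputs. See `docs/methods.md` for the model
details and design decisions.

## Worked example

Generate a synthetic benchmark, rank negatives for its golden-set term,
and evaluate two methods against the random baseline:

```sh
negsel generate --out demo --n-genes 200 --seed 42
negsel rank --method snob --obo demo/ontology.obo \
    --train demo/annotations_t0.tsv --term GO:0000022 --n 5 \
    --out demo/ranks --seed 42
cat demo/ranks/snob_GO_0000022.tsv
```

```text
rank    gene    score
1       G00060  0.00366903
2       G00015  0.00387286
3       G00071  0.00410068
4       G00122  0.00410068
5       G00150  0.00410068
```

The five genes are those whose annotations have essentially never been
seen alongside `GO:0000022`; the score is the mean conditional probability
of the term given each gene's annotations (0 would mean "never
co-annotated at all", 1 "always").

```sh
negsel evaluate --methods snob,rocchio --obo demo/ontology.obo \
    --train demo/annotations_t0.tsv --validate demo/annotations_t1.tsv \
    --baseline-reps 50 --seed 42 --out demo/eval
```

`demo/eval/summary.json` then contains, per branch, the area under each
method's false-negative curve as a fraction of the random baseline's
(below 1 = fewer errors than random sampling), e.g.

```json
"area_ratios": {
 "snob":    {"BP": 0.314, "MF": 0.055, "CC": 0.136},
 "rocchio": {"BP": 0.110, "MF": 0.007, "CC": 0.451}
}
```

together with equal-positives FN rates and the plot-ready
`fn_curves.csv`. The same computation on real data takes `--format gaf`
with two dated GAF files.

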