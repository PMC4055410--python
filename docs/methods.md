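# Methods

## Problem setting

Gene Ontology (GO) annotation is positive-only: a missing annotation does
not assert that a gene lacks a function, only that nobody has recorded it.
Binary classifiers for protein function prediction nevertheless need a
negative class, and naive choices (everything unannotated, random genes,
sibling-annotated genes) plant future positives into the training set.
`negsel` treats this as a positive-unlabeled (PU) selection problem: rank
unlabeled genes by how confidently the existing positive annotations imply
they will *never* receive the target annotation.

Throughout, annotations are first closed upward under the true path rule
(an annotation to a term implies annotations to all its ancestors via
`is_a` and, configurably, `part_of` edges), and asserted negatives close
downward under the inverse rule (a negative for a term is a negative for
all of its descendants).

## Selection methods

Let **A** be the propagated binary gene-by-term matrix, **W** the diagonal
matrix of per-gene annotation totals, and

    p(a|m) = n_{m,a} / n_m

the empirical conditional probability of seeing term *a* on a gene that
carries term *m* (co-annotation counts over all genes, all three GO
branches jointly; rows with n_m = 0 are set to zero to avoid 0/0 — such
terms cannot occur on any annotated gene).

* **SNOB** scores gene *i* for target term *a* as the average conditional
  probability over all of the gene's annotations, IEA included:
  `s_i = (1/W_ii) Σ_{m: A[i,m]=1} p(a|m)`, i.e. column *a* of
  `S = W⁻¹AP`. The *n* lowest-scoring non-positive genes are the predicted
  negatives. Any positive gene scores at least `1/W_ii` because its
  identity term contributes `p(a|a) = 1`.
* **ALBNeg** is the stricter predecessor rule: a gene qualifies iff *every*
  one of its most specific annotations (those with no annotated descendant
  on the same gene) has conditional probability exactly zero with the
  target. It uses curated (non-IEA) annotations and yields a fixed-size
  set.
* **NETL** fits latent Dirichlet allocation on the gene/annotation corpus
  (genes as documents, propagated annotations as words) and ranks
  candidates by ascending Distributional-Overlap Score between their
  posterior topic vector and the renormalized mean posterior of the
  positive class. The topic count is the total number of annotated direct
  children of the three branch roots — few enough that the vocabulary
  dwarfs the topic space, while the topics still cover the whole ontology
  through the inverse true path rule.
* **Rocchio** (PU variant) builds tf-idf prototypes from length-normalized
  document vectors, `c_pos = α·mean(P) − β·mean(U)` and symmetrically for
  the unlabeled class, with α = 16, β = 4, tf = the binary post-propagation
  count and idf = log(N/df). Candidates are ranked descending by
  `cos(v, c_unl) − cos(v, c_pos)`.
* **1-DNF** marks terms whose document frequency among positives strictly
  exceeds that among unlabeled genes as "enriched", and returns every
  non-positive gene carrying none of them (fixed size).
* **Sibling heuristic**: genes annotated to a direct parent of the target
  term but not to the term itself (curated evidence only), falling back to
  all non-positive annotated genes when that set is empty.
* **Random baseline**: uniform samples without replacement from the full
  gene universe minus the positives, replicated (default 100×) and
  averaged. Unlike the algorithms, which can only score annotated genes,
  the baseline draws from the whole universe — which is why an algorithm
  can in principle trail it when new annotations concentrate on
  already-annotated genes.

The positive class of a target term includes its IEA annotations for every
method except the sibling heuristic, whose published form is curated-only.
Ties in every ranking break by gene identifier so results are reproducible.

### DOS

The Distributional-Overlap Score between two unit-sum topic vectors is
implemented as `DOS(p, q) = Σ_i min(p_i, q_i)`, which is symmetric, bounded
by [0, 1], equals 1 iff p = q and 0 iff the supports are disjoint, and is
identically `1 − total-variation distance`. Tests verify all of these
properties; any symmetric overlap with them would order candidates
equivalently in the regimes we exercise.

### LDA settings

Variational-Bayes LDA (scikit-learn) with symmetric priors α = 1/t on
topics and η = 0.01 on words, batch updates, 100 iterations, seeded.
The per-gene posterior is the normalized variational Dirichlet parameter
vector (γ/Σγ). LDA results are reproducible under a fixed seed but not
transferable across implementations, so every NETL guarantee in this
package is statistical (planted-cluster recovery, baseline-relative error)
rather than a numeric equality.

## Temporal-holdout evaluation

Train on an older snapshot t0, validate on a newer snapshot t1: each
predicted negative that is annotated to the target term in t1 (IEA counted
by default, for extra stringency; switchable) is a false negative (FN).
Only terms with 3–300 training annotations and at least one *new* t1
annotation are evaluated — more general terms are uninteresting and
saturated, more specific ones have essentially no chance of being
validated, and a term with no new annotations can expose no errors.
Branch roots are additionally excluded: at genome scale the 300-annotation
cap removes them anyway, and on small synthetic genomes they would
otherwise slip in (and the sibling heuristic is undefined on a root).

Because predicting nothing is trivially error-free, performance is a curve
of FN count versus negative-set size, sampled on a grid (100–3000 at
genome scale, or fractions 0.1%–20% of the genome for database-style
summaries; grid points beyond the candidate pool are clamped and flagged).
Fixed-size methods appear as single points. Summaries:

* **Area ratio** — trapezoid area under the FN curve (anchored at (0,0))
  divided by the area under the random-baseline curve; `weighted` mode
  sums areas over terms before dividing, `per-term` mode divides per term
  and then averages so every term counts equally. Point methods are
  compared against the baseline evaluated at their own (variable) sizes.
* **Equal-positives FN rate** — per term, predict as many negatives as the
  term has training positives; aggregate FN and prediction totals over
  terms before dividing.
* **Specificity buckets** — curves averaged within training-annotation
  count windows 3–10, 11–30, 31–100, 101–300.

### Golden-set ROC

For a term whose positive and negative labels are exhaustively known, a
conventional ROC is computed with *negatives* as the class of interest,
sweeping the negativity score (trapezoid AUC; constant scores give exactly
0.5). Cross-validation uses stratified k-folds over the gold labels; in
each fold the held-out genes' raw annotations to the gold term *and its
descendants* are removed before rescoring, so the scorer never sees the
label it is being tested on while all other annotations stay intact. A
held-out gene left with no annotations is unscorable and receives the most
negative score — it carries no evidence of positivity. This masking scheme
is this package's design; published descriptions of such evaluations say
only that GO terms are held out.

## Synthetic benchmark

The generator emulates the statistical structure the selection methods
exploit — co-annotation bias — with a known answer key:

* Three branches, each a layered random DAG (default 60 terms over 4
  layers below the root; each term has 1–2 parents in the layer above;
  ~15% of edges are `part_of`).
* Three mutually exclusive "function modules", one per branch: antichains
  of 8 deep terms. 75% of genes belong to a module, the rest are
  background. A module gene carries each of its module's terms with
  probability 0.6 (at least one guaranteed); every gene also draws
  Poisson(1.5) background annotations from terms that are neither module
  terms nor below one, so upward propagation can never fabricate module
  membership. No gene ever carries terms of two modules, so all genes of
  the other modules are certain negatives for every module term.
* Evidence codes are IEA with probability 0.3, otherwise a curated code.
* Temporal split: each record is hidden from t0 with probability 0.2 and
  revealed at t1, except that a module gene always keeps at least one
  module annotation visible. A "held-out positive" must still carry the
  planted co-occurrence structure at t0; a gene stripped of every module
  annotation is indistinguishable from background by construction, and the
  planted ground truth would no longer describe it.
* The golden set labels one module's designated term completely: positives
  are the module's genes, negatives everyone else.

Defaults (500 genes, co-occurrence 0.6, holdout 0.2, IEA 0.3) run in
seconds and give a stable method ordering. What the benchmark does *not*
model: realistic GO topology statistics, homology-correlated annotation
bias (which violates the labeled-at-random assumption in real data),
annotation errors, or moonlighting genes with cross-module function — so
passing tests demonstrate correct mechanics and sensitivity to
co-annotation signal, not genome-scale error magnitudes.

## Numerical and design notes

* Matrices are scipy CSR; the conditional-probability matrix is dense
  (terms² doubles), fine up to a few thousand terms. For genome-scale term
  counts, compute per-target columns from `AᵀA[:, a] / n_m` instead.
* All orderings (genes, terms, ranking ties) use sorted identifiers;
  stochastic components (LDA, random baseline, fold assignment) take
  explicit seeds, with per-term sub-seeds derived via CRC32 so results are
  process-independent.
* Evidence codes of propagated ancestor records inherit the most reliable
  contributing code (any curated code beats IEA), so IEA filtering
  commutes with propagation for any term with curated support below it.
* FN counts may be fractional after averaging across baseline replicates
  or terms.
* On the synthetic benchmark, SNOB and NETL area ratios are statistically
  indistinguishable (both far below 1, seed-dependent order), while at
  genome scale the two are reported to differ; the benchmark's planted
  signal is strong enough that all co-annotation methods approach it.
* Known limitations: obsolete-term remapping (`replaced_by`) is not
  performed; GAF taxon filtering beyond file choice is out of scope; the
  NOT qualifier only excludes rows from positives and is not otherwise
  used; cross-organism transfer of the conditional-probability matrix is
  not supported.

## Problem sizes used by the test suite and acceptance script

The acceptance script runs five replicate synthetic datasets at the
default 500-gene conditions, the full benchmark over all eligible terms
(~140 per dataset), 100 baseline replicates per term, 5-fold golden-set
cross-validation per dataset, and a 1000-replicate analytic check of the
random baseline — a few minutes on one CPU. The test suite uses the same
conditions at 3–5 seeds plus toy fixtures small enough to verify by hand.
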