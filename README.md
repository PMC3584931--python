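# hominf — homology-based inference of GO annotations

`hominf` is a toolkit for predicting protein function by homology
transfer and for assessing such predictions rigorously. It is aimed at
people building or benchmarking Gene Ontology (GO) annotation
predictors: given an ontology (a rooted DAG of terms), a database of
proteins with GO annotations, and tabular homology hits (BLAST outfmt-6
style), it transfers annotations from the hits to a query, scores each
term with a reliability in [0, 1], and evaluates the result against
experimental annotations.

## What is inside

**Propagation algebra.** Annotating a protein with a GO term implies all
ancestral terms (the true-path rule). Scores propagate by the max rule
(`score(parent) = max over scored children`) or cumulatively (counts of
all distinct descendants summed into each ancestor, normalized by the
root total). Leaf extraction, per-leaf branches, branch overlap
(`|b1 ∩ b2| / ((|b1|+|b2|)/2)`) and lowest-common-term queries support
the predictors and measures.

**Three nearest-neighbor predictors** transfer terms from a query's hit
list:

- *StudentA* — consensus scoring: a term in the annotation of **all**
  retained hits (default: the 6 best below E-value 0.1) scores 1.0,
  others 0.5, followed by a branch-overlap redundancy reduction
  (single-linkage clustering at ≥ 10 % overlap, deepest leaf kept, and a
  correction re-injecting the lowest common term of pairs overlapping
  > 90 %).
- *StudentB* — E-value weighting: the query-level *template quality
  score* TQS (the percentile of `mean(ln E) + 2·sd(ln E)` against a
  background of database queries) multiplies each leaf's *combined leaf
  score*, the mean over the leaf and its ancestors of the term's
  *support* `Σ ln E(hits with term) / Σ ln E(all hits)`.
- *StudentC* — count scoring: occurrences of each directly annotated
  term across hits are propagated cumulatively, normalized at the root,
  and multiplied by the best percent-positives (or percent-identity) of
  the hits carrying the term; only the highest-scoring leaf's branch is
  emitted unless all branches are requested.

**Four baselines**: *Priors* (every term, scored by database frequency),
*Priors'* (the annotation of one random database protein, Priors-scored),
*BLAST* (best percent identity per term) and *GOtcha* (per-term I-score
`Σ −ln E`, normalized by the root's I-score). A Monte-Carlo helper
quantifies why Priors' loses true positives: a term of frequency *p* is
both picked and true with probability *p²* (0.15² ≈ 0.02).

**Assessment.** Three recall–precision measures — *top-20* (grow the
prediction tier by tier over distinct reliabilities), *threshold* (cut
at t = 1.00 … 0.00 in 0.01 steps) and the stricter *leaf threshold*
measure, which reduces both prediction and truth to their leaf terms so
that over-general or bloated predictions stop being rewarded. Curves are
summarized by F_max = max 2PR/(P+R), and methods are ranked by F_max
with ties sharing the better rank. Recall is averaged over all targets
(an unpredicted target counts 0); precision only over predicted targets.
The root never counts in any measure.

**Optimization and combination.** Each predictor has an option grid
(36 / 54 / 72 settings for A / B / C: hit counts, E-value cutoffs,
search-iteration hit file, evidence-code filter, method-specific
switches) searched exhaustively for the best threshold-measure F_max.
A two-fold protocol (optimize on one half of the targets, predict the
other, switch roles) yields out-of-fold scores on which a weighted
least-squares model `p = x·A + y·B + z·C + i` is fitted; the fused score
p, clamped to [0, 1], is the meta prediction.

**Synthetic benchmarks.** A seeded generator produces random rooted
DAGs, annotated protein databases with configurable evidence-code
mixes, and hit tables whose E-values and identities correlate with
annotation overlap through a *fidelity* parameter — enough to exercise
every code path without any external data.

## Worked example

`python examples/assess_measures.py` walks one annotated target (11
experimental terms, 3 experimental leaves) and a prediction whose top
tier holds two terms at reliability 0.8, one of them correct:

```
top-20, tier 1:   recall=0.09 precision=0.50
threshold t=0.80: recall=0.09 precision=0.50
leaf      t=0.80: recall=0.00 precision=0.00
Fmax: threshold=0.400  leaf=0.000
```

Tier 1 hits 1 of 11 truth terms with 2 predicted terms (1/11 ≈ 0.09,
1/2 = 0.5). The leaf measure tells a different story: the only predicted
leaf above 0.8 is not an experimental leaf, so recall and precision are
0/3 and 0/1 — the prediction never names an exact function correctly.

Other examples: `predict_from_homologs.py` (the three predictors on a
hand-built hit list), `benchmark_and_baselines.py` (simulate, predict,
rank against baselines), `optimize_and_combine.py` (grid search,
two-fold protocol and the least-squares combination).

## Command line

```bash
hominf simulate --seed 17 --out-dir data/
hominf predict --method studentc --ontology data/ontology.tsv \
    --annotations data/annotations.tsv --hits data/hits_iter2.tsv --out pred.tsv
hominf assess --measure leaf --predictions pred.tsv --truth data/truth.tsv \
    --ontology data/ontology.tsv --out curve.tsv
hominf optimize / meta-train / meta-predict / rank ...
```

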