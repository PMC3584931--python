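# Methods

This note records the models implemented in `hominf`, the choices made
where the methods' informal descriptions left room, and what the
synthetic benchmarks do and do not establish.

## Ontology model and propagation

A GO namespace is modeled as a directed acyclic graph with edges
pointing from child to parent and exactly one root (a unique sink
implies every term reaches the root, so no separate connectivity check
is needed). Relation labels (`is_a`, `part_of`) are carried on edges but
not distinguished during propagation: every operation walks all edges.
Term depth is the **longest** path to the root, matching the path-table
semantics used for "longest path" tie language in the redundancy
reduction.

Max propagation assigns each ancestor the maximum input score of its
descendants-or-self; it is idempotent and makes score sets monotone
toward the root. Cumulative propagation sums each term's raw count plus
the raw counts of all **distinct** descendants. A naive depth-first
accumulation would count a descendant once per path in a multi-parent
DAG; counting each descendant once keeps the root equal to the grand
total, which makes the subsequent division by the maximum (attained at
the root) interpretable as a fraction of all observations. All-zero
count vectors are rejected because that normalization is undefined.

Ties anywhere a "deepest" element is selected (lowest common term,
deepest leaf of a cluster, best leaf of StudentC) are broken
lexicographically on the term identifier, purely for reproducibility.

The root participates in propagation but is stripped from every
prediction and ignored by every measure — it carries no information.

## Annotations and hits

Annotations are (protein, term, evidence) records; duplicates of the
same (protein, term) pair collapse to the first record. The
experimental-evidence filter keeps IDA, IMP, IPI, IGI, IEP, TAS, IC and
EXP by default. Term frequency is a **document frequency over
proteins**: the fraction of database proteins whose propagated
annotation contains the term ("the probability of the term occurring"
for a random protein), not a fraction of annotation records.

Hit tables are BLAST tabular rows sorted by ascending E-value with
stable order for ties. E-value cutoffs are strict (`E < cutoff`), and
truncation to the best N hits happens after the cutoff. Self-hits
(subject = query) are removed by default, since in benchmarking a
target must not inherit its own annotation. Hits whose subject has no
annotation in the database are dropped inside the predictors: a search
against an annotated database cannot return such subjects, and they
carry no transferable signal. Before any logarithm, E-values are floored
at 1e-180 (so `ln` is finite) and clamped below 1 (at 0.999) so every
log is strictly negative; this keeps support ratios in (0, 1] and
GOtcha I-score contributions positive. Natural logarithms are used
throughout; the support ratio and percentile mapping are base-invariant,
so the choice only matters for reproducing raw intermediate values.

The number of search iterations is **not** simulated: a hit file per
iteration setting is supplied by the caller, and the `iterations`
parameter selects the file.

## Predictor details

*StudentA.* "A term in the annotation of all N hits" is evaluated
against each hit's **propagated** annotation (otherwise a general term
annotated at different depths in different hits could never reach
consensus), but only directly annotated terms are scored. When fewer
than N hits survive the filters, "all" means all retained hits. The
redundancy reduction clusters leaf branches by single linkage at
pairwise overlap ≥ 0.10, which guarantees any two branches in different
clusters overlap below 10 %. The >90 %-overlap correction operates on
the pre-clustering branch set, and the re-injected common term receives
the maximum of the two leaf scores, consistent with max propagation.

*StudentB.* The background for the template quality score is compiled
by running the raw template score over the provided hit tables (all of
them by default; a sample may be passed). With no background, TQS
defaults to 1.0 and the method reduces to a pure combined-leaf-score
ranking. The combined leaf score averages support over the leaf and its
ancestors **excluding the root**, whose support is 1.0 by construction
and which is discarded from every evaluation anyway; including it would
inflate all scores uniformly. The support denominator sums the log
E-values of **all retained hits** of the query, whether or not a hit
carries any term of interest.

*StudentC.* Term counts are of direct (unpropagated) annotations, once
per hit. The identity factor per term is the maximum percent positives
(or percent identity) over the hits whose propagated annotation carries
the term; since both the normalized cumulative count and this maximum
are monotone toward the root, the product is a valid propagated score
set. With `all_branches` off only the best leaf's branch is output, each
branch term keeping its own product score.

Empty hit tables yield empty predictions, which the measures score as
recall 0 without affecting precision averages.

## Assessment

Top-20 tiers are defined by **distinct** reliability values per target:
the first tier is the full score class of the best reliability (a tie at
the top enters together), matching the worked single-target instance in
which two terms share the top score. Threshold sweeps run from 1.00 down
to 0.00 in steps of 0.01 (101 points) with an inclusive boundary
(score ≥ t), using a 1e-9 tolerance so 3-decimal prediction files hit
0.82-style cutoffs deterministically. The leaf measure reduces the truth
to its leaves once and the prediction to the leaves of its full
propagation before thresholding. Macro-averaging is asymmetric by
construction: recall over all targets, precision over targets with a
non-empty cut. Ranking uses competition ranking (tied methods share the
better rank).

## Grid optimization and the meta model

The option grids are the full Cartesian products —
A: exclude-0.5 × hits {1,5,9} × iterations {1,2,3} × evidence filter
(36); B: E-value {1e0,1e-3,1e-6} × hits {5,50,500} × iterations ×
evidence (54); C: E-value × identity kind × all-branches × iterations ×
evidence (72) — searched exhaustively for the highest threshold-measure
F_max, ties keeping the earliest setting in enumeration order.

The meta model is an ordinary linear fusion `p = x·A + y·B + z·C + i`
fitted by weighted least squares on rows built **only from out-of-fold
predictions** of a seeded two-fold split (odd target counts split
floor/ceil). Candidate rows are the union of the three methods'
predicted terms per target, labeled by membership in the target's true
propagation; a method that did not predict a term contributes 0. The
weighting scheme is a free choice: the default balances the positive
and negative label classes to equal total weight, because candidate
rows are overwhelmingly negative; uniform weighting is available. A
rank-deficient design falls back to the minimum-norm least-squares
solution and is flagged on the model. One model serves all targets of a
namespace; per-namespace models are obtained by running the pipeline
per namespace.

## Synthetic benchmarks

The generator emulates the *shape* of a homology study, not its
content: random single-rooted DAGs built level by level (optional
multi-parent "diamond" edges, acyclic by construction); proteins
annotated with 1–k random ontology leaves under a configurable
evidence-code mix (defaults roughly two-thirds experimental, one-third
IEA); and hit tables whose subject sampling, E-values and identities
correlate with annotation overlap through a fidelity parameter in
[0, 1]. E-values are drawn log-uniformly (default 1e-50 … 10^-0.5) and
shifted toward significance with overlap; percent positives is
50 + 50·overlap plus Gaussian noise, with percent identity at or below
it. Sequences are never simulated — the predictors consume only tabular
statistics. Benchmarks split proteins into disjoint template and target
sets (the logical analogue of a temporal annotation split), withhold the
targets' truths, and emit hit files for iteration settings 1–3 with a
few extra hits per additional iteration.

At fidelity 1.0 the benchmark plants, per target, template proteins
whose annotation equals the target's (perfect homologs) and restricts
hit sampling to full-truth carriers: the idealized regime in which
homology transfer can be exact. The noise-free recovery check runs this
regime with one annotation leaf per protein (the single-function
regime), because two of the methods cannot represent multi-branch truths
exactly by design — StudentC outputs a single leaf branch, and
StudentA's redundancy reduction merges any branches overlapping ≥ 10 %.
Under these conditions all three predictors return exactly the target's
true propagation and reach threshold-measure F_max = 1.0.

What passing synthetic tests does **not** show: real annotation
databases are biased (term frequencies are far from uniform, annotation
depths vary by organism), real E-values are not log-uniform, and hit
identity correlates with annotation similarity far more loosely than
the fidelity model assumes. Absolute F_max values on synthetic data are
therefore not comparable to values on real corpora; only the relative
behavior of methods and the correctness of the machinery are being
exercised.

## Problem sizes and numerical choices

Default tests and examples use ontologies of 40–60 terms, databases of
40–80 proteins and 6–10 hits per target; grid optimization and the
two-fold protocol run comfortably at this scale, and all random draws
flow from explicit seeds (numpy `default_rng`). The Monte-Carlo
coincidence estimate uses 100,000 draws, giving a standard error of
about 0.0005 around 0.0225. Prediction files serialize scores with 3
decimals (2 is traditional; 3 reduces tie artifacts in threshold
sweeps), and the threshold comparison tolerance (1e-9) absorbs that
rounding.

## Known limitations

- The OBO reader is minimal (`id`, `is_a`, `relationship: part_of`);
  obsolete terms, cross-namespace edges and the full OBO 1.4 feature
  set are out of scope.
- GOtcha is implemented only to its I-score definition with per-target
  root normalization, not its full per-ontology calibration machinery.
- The toolkit consumes precomputed hit tables; it never runs a search
  itself, and PSI-BLAST iteration effects exist only as alternative
  input files.
- One meta model per namespace; no nonlinear stacking.
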