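"""Simulate a benchmark and compare predictors against the baselines.

Generates a seeded synthetic benchmark (random ontology, annotated
template database, targets with withheld truths, overlap-correlated hit
tables), runs the three student predictors and the four baselines, and
ranks everything by threshold-measure Fmax.
"""

import numpy as np

from hominf import (
    PredictorParams,
    SimConfig,
    compile_background,
    fmax,
    gen_benchmark,
    predict_blast_baseline,
    predict_gotcha,
    predict_priors,
    predict_priors_random,
    predict_student_a,
    predict_student_b,
    predict_student_c,
    rank_methods,
    threshold_curve,
)

cfg = SimConfig(seed=42, n_proteins=60, n_terms=50, fidelity=0.85)
bench = gen_benchmark(cfg, iterations=(2,))
tables = bench.hits_by_iteration[2]
print(f"benchmark: {len(bench.db)} templates, {len(bench.targets)} targets")

preds = {}
preds["StudentA"] = {
    t: predict_student_a(tables[t], bench.db, bench.graph).scores for t in bench.targets
}
bg = compile_background(tables, bench.db, PredictorParams.default("B"))
preds["StudentB"] = {
    t: predict_student_b(tables[t], bench.db, bench.graph, background=bg).scores
    for t in bench.targets
}
preds["StudentC"] = {
    t: predict_student_c(tables[t], bench.db, bench.graph).scores for t in bench.targets
}
prior_scores = predict_priors(bench.db, bench.graph).scores
preds["Priors"] = {t: dict(prior_scores) for t in bench.targets}
rng = np.random.default_rng(cfg.seed)
preds["Priors'"] = {
    t: predict_priors_random(bench.db, bench.graph, rng, t).scores
    for t in bench.targets
}
preds["BLAST"] = {
    t: predict_blast_baseline(tables[t], bench.db, bench.graph).scores
    for t in bench.targets
}
preds["GOtcha"] = {
    t: predict_gotcha(tables[t], bench.db, bench.graph).scores for t in bench.targets
}

scores = {
    name: fmax(threshold_curve(p, bench.truths, bench.graph))
    for name, p in preds.items()
}
print("\nranking by threshold-measure Fmax (ties share the better rank):")
for method, score, rank in rank_methods(scores):
    print(f"  {rank:2d}. {method:10s} {score:.3f}")
print(
    "\nHomology predictors should beat the annotation-frequency baselines"
    "\nwhenever the hit lists actually carry signal (fidelity > 0)."
)
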