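"""Self-contained recovery benchmarks on the synthetic generator.

``run_recovery_benchmark`` exercises the full pipeline on the default
five-phenotype population and scores it against the generator's hidden truth:
adjusted Rand index of the attribution clusters vs planted phenotypes,
per-cluster decision-factor recall/precision vs planted signatures, and the
random-forest AUROC against a Monte-Carlo estimate of the Bayes-optimal
AUROC (the exact class posterior scored on the same test records).

The calibration experiments quantify the statistics module against ground
truth: empirical type-I error of the clustered paired-proportions test under
a null reader study, its decision agreement with the sign-flip permutation
oracle, and empirical coverage of the percentile-bootstrap confidence
interval.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .attribution import BackgroundSpec, compute_attributions
from .classifiers import ModelSpec, train
from .criteria import extract_decision_factors
from .datamodel import split_by_patient
from .evalstats import auroc, bootstrap_ci, confusion_metrics, obuchowski_test, \
    permutation_test
from .geometry import cluster, embed, select_explanation_cohort
from .synthetic import (GeneratorConfig, ReaderStudyConfig, bayes_posterior_scores,
                        default_phenotypes, generate_population,
                        generate_reader_study)

#: the paper-shaped study conditions: ~2 ECGs per patient, 9.2% prevalence,
#: 19.4% of records held out as the test split
BENCHMARK_N_PATIENTS = 5000
BENCHMARK_TEST_FRACTION = 0.194


def run_recovery_benchmark(seed: int = 0,
                           n_patients: int = BENCHMARK_N_PATIENTS,
                           model_spec: Optional[ModelSpec] = None) -> dict:
    """Full-pipeline ground-truth recovery on the default synthetic benchmark."""
    cfg = GeneratorConfig(n_patients=n_patients, seed=seed)
    phenotypes = default_phenotypes()
    ds, truth = generate_population(cfg, phenotypes=phenotypes)
    train_ds, test_ds = split_by_patient(ds, BENCHMARK_TEST_FRACTION, seed + 1)

    model = train(train_ds, model_spec or ModelSpec(seed=seed))
    probs = model.predict_proba(test_ds)
    rf_auc = auroc(probs, test_ds.reduced)
    bayes_auc = auroc(bayes_posterior_scores(test_ds.values, phenotypes, cfg),
                      test_ds.reduced)

    cohort_idx = select_explanation_cohort(test_ds, probs)
    cohort = test_ds.subset(cohort_idx)
    attr = compute_attributions(model, cohort,
                                BackgroundSpec(size=64, seed=seed),
                                train_ds.values)
    emb = embed(attr, pca_dims=20, seed=seed)
    ca = cluster(emb, K_max=10, min_cluster_size=10, seed=seed)

    truth_by_record = truth.set_index("record_id")["phenotype"]
    cohort_truth = truth_by_record.loc[cohort.record_ids].to_numpy()
    ari = float(adjusted_rand_score(cohort_truth, ca.labels))

    factors = extract_decision_factors(attr, ca)
    planted = {p.name: set(p.affected_names) for p in phenotypes}
    by_cluster: dict[int, set[str]] = {}
    for f in factors:
        by_cluster.setdefault(f.cluster, set()).add(f.parameter)
    per_cluster = []
    for c in sorted(by_cluster):
        members = cohort_truth[ca.labels == c]
        names, counts = np.unique(members, return_counts=True)
        majority = names[counts.argmax()]
        sig = planted.get(majority)
        if sig is None:           # majority-healthy cluster: no planted signature
            continue
        got = by_cluster[c]
        per_cluster.append({
            "cluster": int(c), "phenotype": str(majority),
            "recall": len(got & sig) / len(sig),
            "precision": len(got & sig) / len(got) if got else 0.0,
        })
    return {
        "n_records": len(ds),
        "cohort_size": int(len(cohort)),
        "effective_K": int(ca.effective_K),
        "ari": ari,
        "rf_auroc": float(rf_auc),
        "bayes_auroc": float(bayes_auc),
        "auroc_gap": float(bayes_auc - rf_auc),
        "per_cluster": per_cluster,
        "min_recall": min(c["recall"] for c in per_cluster),
        "min_precision": min(c["precision"] for c in per_cluster),
    }


def obuchowski_type1_error(n_sim: int = 2000, seed: int = 0,
                           alpha: float = 0.05) -> float:
    """Empirical type-I error of the clustered test under a null reader study."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sim):
        cfg = ReaderStudyConfig(sens_before=0.4, spec_before=0.88,
                                sens_after=0.4, spec_after=0.88,
                                within_reader_correlation=0.3,
                                seed=int(rng.integers(2 ** 31)))
        rs = generate_reader_study(cfg)
        rejections += obuchowski_test(rs).p_value < alpha
    return rejections / n_sim


def permutation_agreement(n_studies: int = 50, seed: int = 0,
                          alpha: float = 0.05) -> float:
    """Fraction of random studies where the clustered test and the sign-flip
    permutation oracle make the same rejection decision."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_studies):
        if rng.random() < 0.5:                     # null study
            sens_a, spec_a = 0.4, 0.88
        else:                                      # clear improvement
            sens_a, spec_a = 0.711, 0.766
        cfg = ReaderStudyConfig(sens_before=0.374, spec_before=0.883,
                                sens_after=sens_a, spec_after=spec_a,
                                within_reader_correlation=0.3,
                                seed=int(rng.integers(2 ** 31)))
        rs = generate_reader_study(cfg)
        agree += ((obuchowski_test(rs).p_value < alpha)
                  == (permutation_test(rs).p_value <= alpha))
    return agree / n_studies


def bootstrap_coverage(n_sim: int = 500, n: int = 200, B: int = 200,
                       true_accuracy: float = 0.7, seed: int = 0) -> float:
    """Empirical coverage of the 95% percentile-bootstrap CI for accuracy."""
    rng = np.random.default_rng(seed)
    covered = 0
    for s in range(n_sim):
        truth = rng.random(n) < 0.5
        correct = rng.random(n) < true_accuracy
        calls = np.where(correct, truth, ~truth)
        lo, hi = bootstrap_ci(lambda c, t: confusion_metrics(c, t)[0],
                              (calls, truth), B=B,
                              seed=int(rng.integers(2 ** 31)))
        covered += lo <= 100.0 * true_accuracy <= hi
    return covered / n_sim
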