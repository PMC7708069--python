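"""Canned study-scale experiments: the benchmark comparison of the four
estimators, the tissue-interpretability analysis and the sparse
parameter-recovery study, each on the package's synthetic compendia.

These mirror, at desk scale, the three headline analyses of the
imputation framework: method ordering within one platform and across a
platform pair, coefficient interpretability, and the identifiability of a
target's generative mixture.  All randomness derives from a single seed.
"""

from __future__ import annotations

import numpy as np

from .data import ExpressionMatrix
from .evaluate import nrmse_per_gene, win_rate
from .impute import LassoConfig, impute, sample_lasso_impute, tune_hyperparameter
from .interpret import same_tissue_top_rate, tissue_zscores_from_result
from .preprocess import temporal_dataset_split
from .synth import (
    BENCHMARK_FRACTIONS,
    INTERPRETABILITY_FRACTIONS,
    SynthConfig,
    benchmark_config,
    generate_compendium,
    generate_cross_platform_pair,
    interpretability_config,
    make_gene_split,
)

METHOD_ORDER = ("sample-lasso", "gene-lasso", "sample-knn", "gene-knn")


def _tuned_test_metrics(train, validation, targets, truth, split, n_jobs=1):
    """Tune every estimator on the validation samples, impute the test
    targets, and return per-gene NRMSE series plus chosen values."""
    out = {}
    for method in METHOD_ORDER:
        best, _ = tune_hyperparameter(
            method, train, validation, split, n_jobs=n_jobs
        )
        result = impute(
            method, targets, train, split,
            alpha=best if method.endswith("lasso") else None,
            k=int(best) if method.endswith("knn") else None,
            n_jobs=n_jobs,
        )
        out[method] = {
            "per_gene_nrmse": nrmse_per_gene(truth, result),
            "hyperparameter": best,
        }
    return out


def run_benchmark(seed: int = 0, n_jobs: int = 1) -> dict:
    """Four-method comparison on the default 6-tissue compendium (600
    train / 50 validation / 100 test samples, 1000 genes, large measured
    set) and on its cross-platform rendering.

    Returns tuned hyperparameters, median per-gene NRMSE per method, and
    the win-rate of SampleLASSO over each comparator, for both tasks.
    """
    cfg = benchmark_config(seed=seed)
    comp = generate_compendium(cfg)
    matrix = comp.matrix
    sample_split = temporal_dataset_split(matrix, BENCHMARK_FRACTIONS)
    gene_split = make_gene_split(matrix, "large_measured", seed=seed + 1)

    report: dict = {"n_train": len(sample_split.train),
                    "n_test": len(sample_split.test),
                    "n_unmeasured": len(gene_split.unmeasured)}

    def task(train_m, val_m, test_m):
        train = train_m.subset_samples(sample_split.train)
        validation = val_m.subset_samples(sample_split.validation)
        targets = test_m.subset_samples(sample_split.test)
        truth = targets.subset_genes(gene_split.unmeasured)
        metrics = _tuned_test_metrics(
            train, validation, targets, truth, gene_split, n_jobs=n_jobs
        )
        summary = {}
        ref = metrics["sample-lasso"]["per_gene_nrmse"]
        for method, m in metrics.items():
            summary[method] = {
                "median_nrmse": float(np.nanmedian(m["per_gene_nrmse"])),
                "hyperparameter": float(m["hyperparameter"]),
            }
            if method != "sample-lasso":
                summary[method]["sample_lasso_win_rate"] = win_rate(
                    ref, m["per_gene_nrmse"]
                )
        return summary

    report["within_platform"] = task(matrix, matrix, matrix)
    pair = generate_cross_platform_pair(cfg)
    report["cross_platform"] = task(pair.source, pair.target, pair.target)
    return report


def run_interpretability(seed: int = 0, n_targets: int = 200,
                         n_jobs: int = 1) -> dict:
    """Tissue z-score analysis on the labeled 6-tissue scenario.

    Fits one SampleLASSO model per test target (alpha tuned on the
    scenario's validation split), scores every tissue per target, and
    reports the fraction of targets whose top-z tissue is their own.
    """
    cfg = interpretability_config(seed=seed)
    comp = generate_compendium(cfg)
    matrix, labels = comp.matrix, comp.labels
    sample_split = temporal_dataset_split(matrix, INTERPRETABILITY_FRACTIONS)
    gene_split = make_gene_split(matrix, "large_measured", seed=seed + 1)
    train = matrix.subset_samples(sample_split.train)
    validation = matrix.subset_samples(sample_split.validation)
    targets = matrix.subset_samples(sample_split.test[:n_targets])
    alpha, _ = tune_hyperparameter(
        "sample-lasso", train, validation, gene_split, n_jobs=n_jobs
    )
    result = sample_lasso_impute(
        targets, train, gene_split, LassoConfig(alpha=alpha), n_jobs=n_jobs
    )
    ztable = tissue_zscores_from_result(result, labels)
    rate = same_tissue_top_rate(ztable, labels)
    return {"same_tissue_top_rate": rate, "n_targets": targets.n_samples,
            "alpha": float(alpha), "zscores": ztable}


def run_recovery(seed: int = 0, n_replicates: int = 100,
                 n_train: int = 50, n_measured: int = 200,
                 n_unmeasured: int = 100, noise_sd: float = 0.01,
                 weights: tuple[float, float] = (0.6, 0.4),
                 support_threshold: float = 0.01,
                 coef_tolerance: float = 0.05) -> dict:
    """Sparse mixture recovery: targets built as w1*A + w2*B (+noise) on
    the measured genes must yield SampleLASSO models supported exactly on
    {A, B} with coefficients within ``coef_tolerance``, at the
    validation-chosen alpha (scored against the known unmeasured truth).
    """
    cfg = SynthConfig(
        n_tissues=6, samples_per_tissue=9, datasets_per_tissue=3,
        n_genes=n_measured + n_unmeasured, seed=seed,
    )
    comp = generate_compendium(cfg)
    matrix = comp.matrix
    train = matrix.subset_samples(matrix.sample_ids[:n_train])
    gene_split = make_gene_split(
        matrix, "custom", sizes=(n_measured, n_unmeasured), seed=seed + 1
    )
    meas = train.gene_values(gene_split.measured)
    unmeas = train.gene_values(gene_split.unmeasured)
    rng = np.random.default_rng(seed + 2)
    w1, w2 = weights
    successes = 0
    for _ in range(n_replicates):
        a, b = rng.choice(n_train, size=2, replace=False)
        y = w1 * meas[a] + w2 * meas[b] + rng.normal(0, noise_sd, n_measured)
        target = ExpressionMatrix(
            values=y[None, :], sample_ids=["target"],
            gene_ids=gene_split.measured, dataset_ids=["query"],
        )
        truth = w1 * unmeas[a] + w2 * unmeas[b]
        best_beta, best_score = None, np.inf
        for alpha in (1e-4, 1e-3, 1e-2, 1e-1):
            res = sample_lasso_impute(
                target, train, gene_split,
                LassoConfig(alpha=alpha, max_iter=20000),
            )
            score = float(np.sqrt(np.mean((res.imputed[0] - truth) ** 2)))
            if score < best_score:
                best_score = score
                best_beta = res.diagnostics["betas"].iloc[0].to_numpy()
        support = set(np.flatnonzero(np.abs(best_beta) > support_threshold))
        ok = (
            support == {a, b}
            and abs(best_beta[a] - w1) < coef_tolerance
            and abs(best_beta[b] - w2) < coef_tolerance
        )
        successes += ok
    return {"recovery_rate": successes / n_replicates,
            "n_replicates": n_replicates}
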