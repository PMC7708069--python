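"""Per-gene imputation accuracy metrics, method comparisons and
mean/variance stratification.

The primary metric is the per-gene normalized root-mean-square error

    NRMSE(g) = sqrt( sum_j (ghat_gj - g_gj)^2 / S ) / ( sum_j g_gj / S )

over the S evaluation samples, i.e. RMSE divided by the gene's mean true
expression — a scale-free error that is comparable across genes.  Genes
whose mean true expression is not positive have an undefined NRMSE; they
are reported as NaN and excluded from aggregates rather than epsilon-padded.
Spearman correlation and mean absolute error are reported alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import DataError, ExpressionMatrix
from .impute import ImputationResult


def _aligned(truth: ExpressionMatrix, imputed: ImputationResult) -> tuple[np.ndarray, np.ndarray, list[str]]:
    genes = imputed.unmeasured_genes
    t_genes = set(truth.gene_ids)
    missing = [g for g in genes if g not in t_genes]
    if missing:
        raise DataError(f"truth lacks genes: {missing[:10]}")
    if list(truth.sample_ids) != list(imputed.target_ids):
        truth = truth.subset_samples(imputed.target_ids)
    T = truth.gene_values(genes)
    P = imputed.imputed
    if T.shape != P.shape:
        raise DataError(f"shape mismatch truth {T.shape} vs imputed {P.shape}")
    return T, P, list(genes)


def nrmse_per_gene(truth: ExpressionMatrix, imputed: ImputationResult) -> pd.Series:
    """Normalized RMSE per gene; NaN where the gene's true mean is <= 0."""
    T, P, genes = _aligned(truth, imputed)
    rmse = np.sqrt(np.mean((P - T) ** 2, axis=0))
    mean = T.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nrmse = np.where(mean > 0, rmse / np.where(mean > 0, mean, 1.0), np.nan)
    return pd.Series(nrmse, index=genes, name="nrmse")


def mae_per_gene(truth: ExpressionMatrix, imputed: ImputationResult) -> pd.Series:
    """Mean absolute error per gene over the evaluation samples."""
    T, P, genes = _aligned(truth, imputed)
    return pd.Series(np.mean(np.abs(P - T), axis=0), index=genes, name="mae")


def spearman_per_gene(truth: ExpressionMatrix, imputed: ImputationResult) -> pd.Series:
    """Spearman rank correlation per gene (average ranks for ties).

    NaN for genes whose true or imputed vector is constant (undefined rank
    correlation) or with fewer than 3 samples.
    """
    T, P, genes = _aligned(truth, imputed)
    if T.shape[0] < 3:
        raise DataError("Spearman correlation needs at least 3 samples")
    rho = np.empty(len(genes))
    for i in range(len(genes)):
        t, p = T[:, i], P[:, i]
        if np.ptp(t) == 0.0 or np.ptp(p) == 0.0:
            rho[i] = np.nan
            continue
        rho[i] = sps.spearmanr(t, p).statistic
    return pd.Series(rho, index=genes, name="spearman")


def bin_genes_by_mean_variance(truth: ExpressionMatrix) -> pd.DataFrame:
    """Assign each gene a low/medium/high tertile bin by mean and, separately,
    by variance of its true expression over the evaluation samples.

    Ranking uses stable gene order for ties; tertile sizes differ by at
    most one.
    """
    if truth.n_genes < 3:
        raise DataError("binning needs at least 3 genes")
    mean = truth.values.mean(axis=0)
    var = truth.values.var(axis=0)
    labels = ("low", "medium", "high")

    def tertiles(x: np.ndarray) -> list[str]:
        order = np.argsort(x, kind="stable")
        n = len(x)
        out = [""] * n
        edges = [round(n / 3), round(2 * n / 3)]
        for rank, idx in enumerate(order):
            b = 0 if rank < edges[0] else (1 if rank < edges[1] else 2)
            out[idx] = labels[b]
        return out

    return pd.DataFrame(
        {
            "gene": truth.gene_ids,
            "mean_bin": tertiles(mean),
            "variance_bin": tertiles(var),
        }
    )


def gene_metric_table(
    truth: ExpressionMatrix, imputed: ImputationResult
) -> pd.DataFrame:
    """Combine NRMSE/Spearman/MAE and mean/variance bins into one per-gene
    long-format table (column ``method`` records the estimator)."""
    truth_sub = truth.subset_genes(imputed.unmeasured_genes)
    if list(truth_sub.sample_ids) != list(imputed.target_ids):
        truth_sub = truth_sub.subset_samples(imputed.target_ids)
    table = bin_genes_by_mean_variance(truth_sub)
    table["nrmse"] = nrmse_per_gene(truth_sub, imputed).to_numpy()
    table["spearman"] = spearman_per_gene(truth_sub, imputed).to_numpy()
    table["mae"] = mae_per_gene(truth_sub, imputed).to_numpy()
    table["method"] = imputed.method
    return table


_LOWER_IS_BETTER = {"nrmse": True, "mae": True, "spearman": False}


def win_rate(
    metrics_a: pd.DataFrame | pd.Series,
    metrics_b: pd.DataFrame | pd.Series,
    metric: str = "nrmse",
) -> float:
    """Fraction of genes where method A beats method B on ``metric``.

    Ties count half, so win_rate(A, B) + win_rate(B, A) = 1.  Genes where
    either metric is undefined (NaN) are excluded.
    """
    a = _metric_vector(metrics_a, metric)
    b = _metric_vector(metrics_b, metric)
    if list(a.index) != list(b.index):
        if set(a.index) != set(b.index):
            raise DataError("metric tables cover different gene sets")
        b = b.loc[a.index]
    mask = a.notna() & b.notna()
    a, b = a[mask].to_numpy(), b[mask].to_numpy()
    if a.size == 0:
        raise DataError("no genes with defined metrics to compare")
    if _LOWER_IS_BETTER[metric]:
        wins = (a < b).sum()
    else:
        wins = (a > b).sum()
    ties = (a == b).sum()
    return float((wins + 0.5 * ties) / a.size)


def compare_methods_test(
    metrics_a: pd.DataFrame | pd.Series,
    metrics_b: pd.DataFrame | pd.Series,
    metric: str = "nrmse",
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two per-gene metric vectors.

    Returns (statistic, p-value); no significance threshold is applied.
    """
    a = _metric_vector(metrics_a, metric)
    b = _metric_vector(metrics_b, metric)
    a = a.dropna().to_numpy()
    b = b.dropna().to_numpy()
    if min(a.size, b.size) < 10:
        raise DataError("rank-sum comparison needs at least 10 genes per method")
    res = sps.ranksums(a, b)
    return float(res.statistic), float(res.pvalue)


def _metric_vector(table: pd.DataFrame | pd.Series, metric: str) -> pd.Series:
    if isinstance(table, pd.Series):
        return table
    if metric not in table.columns:
        raise DataError(f"metric {metric!r} not in table")
    return pd.Series(table[metric].to_numpy(), index=table["gene"].to_numpy())
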