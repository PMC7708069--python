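"""The four unmeasured-gene imputation estimators and hyperparameter tuning.

Two axes of signal, two algorithms:

* ``SampleLASSO`` (the centrepiece): for every target sample a sparse
  linear model is built on-the-fly that writes the target's measured-gene
  profile as a sparse combination of the *training samples*; the learned
  per-sample coefficients then transfer directly to the unmeasured genes.
  The coefficients are retained as diagnostics — the nonzero-β training
  samples are the "most utilized" samples for that target.
* ``GeneLASSO``: one pre-trained sparse regression per unmeasured gene on
  the measured genes (the traditional formulation).
* ``SampleKNN`` / ``GeneKNN``: inverse-distance-weighted nearest
  neighbours over samples resp. genes.

All L1 problems minimize (1/2N)‖Xβ − y‖₂² + α‖β‖₁ via cyclic coordinate
descent; for SampleLASSO the N observations are the measured genes and the
features are training samples, for GeneLASSO the observations are training
samples and the features are measured genes.

Genes are standardized with train-derived statistics before model fitting
and distances; imputed values are always returned on the original
(unstandardized) scale.  Per-target SampleLASSO fits are independent, so
results are invariant to the degree of parallelism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.spatial.distance import cdist
from sklearn.linear_model import Lasso

from .data import DataError, ExpressionMatrix, GeneSplit
from .preprocess import StandardizationStats, fit_standardizer

METHODS = ("sample-lasso", "gene-lasso", "sample-knn", "gene-knn")


@dataclass
class LassoConfig:
    """L1-regularized regression settings (strength ``alpha`` = α)."""

    alpha: float = 0.1
    fit_intercept: bool = True
    max_iter: int = 1000
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise DataError("alpha must be non-negative")
        if self.tol <= 0:
            raise DataError("tol must be positive")
        if self.max_iter <= 0:
            raise DataError("max_iter must be positive")


@dataclass
class KnnConfig:
    """K-nearest-neighbour settings (inverse-distance weighted, Euclidean)."""

    k: int = 5
    weighting: str = "inverse_distance"
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise DataError("k must be a positive integer")
        if self.weighting != "inverse_distance":
            raise DataError("only inverse_distance weighting is supported")
        if self.distance != "euclidean":
            raise DataError("only euclidean distance is supported")


@dataclass
class ImputationResult:
    """Imputed unmeasured-gene values plus per-target model diagnostics."""

    imputed: np.ndarray  # (n_targets, n_unmeasured), original scale
    target_ids: list[str]
    unmeasured_genes: list[str]
    method: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.imputed = np.asarray(self.imputed, dtype=float)
        if not np.isfinite(self.imputed).all():
            raise DataError("imputed matrix contains non-finite entries")

    def to_matrix(self, dataset_ids: Sequence[str] | None = None) -> ExpressionMatrix:
        if dataset_ids is None:
            dataset_ids = ["imputed"] * len(self.target_ids)
        return ExpressionMatrix(
            values=self.imputed,
            sample_ids=list(self.target_ids),
            gene_ids=list(self.unmeasured_genes),
            dataset_ids=list(dataset_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.imputed, index=self.target_ids, columns=self.unmeasured_genes
        )

    def most_utilized_samples(self, target_id: str) -> pd.DataFrame:
        """Training samples with nonzero β for ``target_id``, sorted by |β|.

        Only defined for SampleLASSO results.
        """
        if self.method != "sample-lasso":
            raise DataError("most_utilized_samples requires a SampleLASSO result")
        betas: pd.DataFrame = self.diagnostics["betas"]
        row = betas.loc[target_id]
        nz = row[row != 0.0]
        order = nz.abs().sort_values(ascending=False).index
        return pd.DataFrame(
            {"train_sample": order, "beta": nz.loc[order].to_numpy()}
        ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# shared plumbing


def _split_blocks(
    train: ExpressionMatrix,
    targets: ExpressionMatrix,
    split: GeneSplit,
    standardize: bool,
):
    """Extract aligned measured/unmeasured blocks, optionally standardizing
    each gene with train-derived population statistics.

    Returns (train_meas, train_unmeas, target_meas, meas_stats, unmeas_stats)
    where the stats are None when ``standardize`` is False.
    """
    split.validate_against(train)
    t_genes = set(targets.gene_ids)
    missing = [g for g in split.measured if g not in t_genes]
    if missing:
        raise DataError(
            f"targets lack measured genes: {', '.join(missing[:10])}"
        )
    train_meas = train.gene_values(split.measured)
    train_unmeas = train.gene_values(split.unmeasured)
    target_meas = targets.gene_values(split.measured)
    meas_stats = unmeas_stats = None
    if standardize:
        meas_stats = _gene_stats(train_meas, split.measured)
        unmeas_stats = _gene_stats(train_unmeas, split.unmeasured)
        train_meas = _standardize_block(train_meas, meas_stats)
        train_unmeas = _standardize_block(train_unmeas, unmeas_stats)
        target_meas = _standardize_block(target_meas, meas_stats)
    return train_meas, train_unmeas, target_meas, meas_stats, unmeas_stats


def _gene_stats(block: np.ndarray, ids: Sequence[str]) -> StandardizationStats:
    return StandardizationStats(
        mean=block.mean(axis=0),
        sd=block.std(axis=0),
        feature_axis="genes",
        feature_ids=list(ids),
    )


def _standardize_block(block: np.ndarray, stats: StandardizationStats) -> np.ndarray:
    safe = np.where(stats.sd == 0.0, 1.0, stats.sd)
    out = (block - stats.mean) / safe
    out[:, stats.sd == 0.0] = 0.0
    return out


def _unstandardize_block(block: np.ndarray, stats: StandardizationStats) -> np.ndarray:
    return block * stats.sd + stats.mean


def _fit_lasso(X: np.ndarray, y: np.ndarray, config: LassoConfig) -> Lasso:
    model = Lasso(
        alpha=config.alpha,
        fit_intercept=config.fit_intercept,
        max_iter=config.max_iter,
        tol=config.tol,
    )
    model.fit(X, y)
    return model


# ---------------------------------------------------------------------------
# SampleLASSO


def sample_lasso_impute(
    targets: ExpressionMatrix,
    train: ExpressionMatrix,
    split: GeneSplit,
    config: LassoConfig | None = None,
    standardize: bool = True,
    n_jobs: int = 1,
) -> ImputationResult:
    """Impute unmeasured genes with one on-the-fly sparse model per target.

    For each target sample, solve the L1 problem whose design matrix has
    one row per measured gene and one column per training sample, and whose
    response is the target's measured-gene vector.  The fitted coefficients
    β (one per training sample) plus intercept are applied to the training
    samples' unmeasured-gene values to impute the target, and are kept in
    ``diagnostics['betas']`` / ``diagnostics['intercepts']``.
    """
    config = config or LassoConfig()
    train_meas, train_unmeas, target_meas, _, unmeas_stats = _split_blocks(
        train, targets, split, standardize
    )
    X = np.ascontiguousarray(train_meas.T)  # (n_measured_genes, n_train)
    Z = train_unmeas.T  # (n_unmeasured_genes, n_train)

    # the per-target problems share X and are independent; they are fit in
    # fixed-width batches so the floating-point result is bit-identical
    # for every worker count (parallelism-invariance contract)
    def fit_chunk(Y: np.ndarray):
        model = _fit_lasso(X, Y, config)
        coef = np.atleast_2d(model.coef_)
        return coef, np.atleast_1d(model.intercept_).astype(float)

    n_targets = target_meas.shape[0]
    width = 64  # constant regardless of n_jobs
    chunks = [target_meas[i:i + width].T for i in range(0, n_targets, width)]
    results = Parallel(n_jobs=n_jobs)(delayed(fit_chunk)(Y) for Y in chunks)
    betas = np.vstack([r[0] for r in results])
    intercepts = np.concatenate([r[1] for r in results])
    pred = betas @ Z.T + intercepts[:, None]  # (n_targets, n_unmeasured)
    if unmeas_stats is not None:
        pred = _unstandardize_block(pred, unmeas_stats)
    return ImputationResult(
        imputed=pred,
        target_ids=list(targets.sample_ids),
        unmeasured_genes=list(split.unmeasured),
        method="sample-lasso",
        diagnostics={
            "betas": pd.DataFrame(
                betas, index=targets.sample_ids, columns=train.sample_ids
            ),
            "intercepts": pd.Series(intercepts, index=targets.sample_ids),
            "alpha": config.alpha,
        },
    )


# ---------------------------------------------------------------------------
# GeneLASSO


@dataclass
class GeneLassoModels:
    """Pre-trained per-unmeasured-gene sparse models.

    ``coefs`` has one row per unmeasured gene, one column per measured
    gene (coefficients on the standardized measured-gene scale when
    ``meas_stats`` is set); predictions are produced on the original scale
    because the responses were left unstandardized.
    """

    coefs: np.ndarray  # (n_unmeasured, n_measured)
    intercepts: np.ndarray
    measured: list[str]
    unmeasured: list[str]
    meas_stats: StandardizationStats | None
    alpha: float

    def unstandardized_coefs(self) -> np.ndarray:
        """Coefficients mapped back to raw measured-gene units."""
        if self.meas_stats is None:
            return self.coefs.copy()
        safe = np.where(self.meas_stats.sd == 0.0, 1.0, self.meas_stats.sd)
        return self.coefs / safe


def gene_lasso_fit(
    train: ExpressionMatrix,
    split: GeneSplit,
    config: LassoConfig | None = None,
    standardize: bool = True,
) -> GeneLassoModels:
    """Train one sparse regression per unmeasured gene on the measured genes."""
    config = config or LassoConfig()
    split.validate_against(train)
    X = train.gene_values(split.measured)
    Y = train.gene_values(split.unmeasured)  # responses stay on original scale
    meas_stats = None
    if standardize:
        meas_stats = _gene_stats(X, split.measured)
        X = _standardize_block(X, meas_stats)
    model = _fit_lasso(X, Y, config)
    coefs = np.atleast_2d(model.coef_)
    intercepts = np.atleast_1d(model.intercept_)
    return GeneLassoModels(
        coefs=coefs,
        intercepts=np.asarray(intercepts, dtype=float),
        measured=list(split.measured),
        unmeasured=list(split.unmeasured),
        meas_stats=meas_stats,
        alpha=config.alpha,
    )


def gene_lasso_impute(
    models: GeneLassoModels, targets: ExpressionMatrix
) -> ImputationResult:
    """Apply pre-trained per-gene models to new partially-measured samples."""
    t_genes = set(targets.gene_ids)
    missing = [g for g in models.measured if g not in t_genes]
    if missing:
        raise DataError(f"targets lack measured genes: {missing[:10]}")
    X = targets.gene_values(models.measured)
    if models.meas_stats is not None:
        X = _standardize_block(X, models.meas_stats)
    pred = X @ models.coefs.T + models.intercepts[None, :]
    return ImputationResult(
        imputed=pred,
        target_ids=list(targets.sample_ids),
        unmeasured_genes=list(models.unmeasured),
        method="gene-lasso",
        diagnostics={"models": models, "alpha": models.alpha},
    )


# ---------------------------------------------------------------------------
# KNN methods


def _inverse_distance_weights(d: np.ndarray) -> np.ndarray:
    """Inverse-distance weights; exact (zero-distance) matches share
    uniform weight and all others get zero."""
    zero = d == 0.0
    if zero.any():
        w = np.zeros_like(d)
        w[zero] = 1.0 / zero.sum()
        return w
    w = 1.0 / d
    return w / w.sum()


def sample_knn_impute(
    targets: ExpressionMatrix,
    train: ExpressionMatrix,
    split: GeneSplit,
    config: KnnConfig | None = None,
    standardize: bool = True,
) -> ImputationResult:
    """Impute each target from its k nearest training samples.

    Neighbours by Euclidean distance on the (standardized) measured genes;
    each unmeasured gene is the inverse-distance-weighted average of that
    gene's expression in the neighbours.  Equidistant neighbours are broken
    by stored training order.
    """
    config = config or KnnConfig()
    if config.k > train.n_samples:
        raise DataError(
            f"k={config.k} exceeds number of training samples {train.n_samples}"
        )
    train_meas, _, target_meas, _, _ = _split_blocks(
        train, targets, split, standardize
    )
    # averages use original-scale unmeasured values
    train_unmeas = train.gene_values(split.unmeasured)
    D = cdist(target_meas, train_meas, metric="euclidean")
    n_targets = D.shape[0]
    imputed = np.empty((n_targets, len(split.unmeasured)))
    neighbor_ids, neighbor_dists, neighbor_weights = [], [], []
    for i in range(n_targets):
        order = np.argsort(D[i], kind="stable")[: config.k]
        d = D[i, order]
        w = _inverse_distance_weights(d)
        imputed[i] = w @ train_unmeas[order]
        neighbor_ids.append([train.sample_ids[j] for j in order])
        neighbor_dists.append(d)
        neighbor_weights.append(w)
    return ImputationResult(
        imputed=imputed,
        target_ids=list(targets.sample_ids),
        unmeasured_genes=list(split.unmeasured),
        method="sample-knn",
        diagnostics={
            "neighbors": neighbor_ids,
            "distances": neighbor_dists,
            "weights": neighbor_weights,
            "k": config.k,
        },
    )


def gene_knn_impute(
    targets: ExpressionMatrix,
    train: ExpressionMatrix,
    split: GeneSplit,
    config: KnnConfig | None = None,
    standardize: bool = True,
) -> ImputationResult:
    """Impute each unmeasured gene from its k nearest measured genes.

    Gene neighbours by Euclidean distance between (standardized) gene
    columns in the training matrix; the imputed value is the
    inverse-distance-weighted average of the target sample's own
    expression values at those neighbour genes.
    """
    config = config or KnnConfig()
    if config.k > len(split.measured):
        raise DataError(
            f"k={config.k} exceeds number of measured genes {len(split.measured)}"
        )
    train_meas, train_unmeas, _, _, _ = _split_blocks(
        train, targets, split, standardize
    )
    # averages use the target's original-scale measured values
    target_meas = targets.gene_values(split.measured)
    # columns are genes: distances between unmeasured and measured columns
    D = cdist(train_unmeas.T, train_meas.T, metric="euclidean")
    n_targets = target_meas.shape[0]
    n_unmeas = len(split.unmeasured)
    pred = np.empty((n_targets, n_unmeas))
    neighbor_genes, neighbor_dists, neighbor_weights = [], [], []
    for u in range(n_unmeas):
        order = np.argsort(D[u], kind="stable")[: config.k]
        d = D[u, order]
        w = _inverse_distance_weights(d)
        pred[:, u] = target_meas[:, order] @ w
        neighbor_genes.append([split.measured[m] for m in order])
        neighbor_dists.append(d)
        neighbor_weights.append(w)
    return ImputationResult(
        imputed=pred,
        target_ids=list(targets.sample_ids),
        unmeasured_genes=list(split.unmeasured),
        method="gene-knn",
        diagnostics={
            "neighbor_genes": neighbor_genes,
            "distances": neighbor_dists,
            "weights": neighbor_weights,
            "k": config.k,
        },
    )


# ---------------------------------------------------------------------------
# dispatch + tuning

DEFAULT_ALPHA_GRID = tuple(np.logspace(-3, 2, 10))
DEFAULT_K_GRID = (1, 2, 5, 10, 20, 50, 100)


def impute(
    method: str,
    targets: ExpressionMatrix,
    train: ExpressionMatrix,
    split: GeneSplit,
    *,
    alpha: float | None = None,
    k: int | None = None,
    standardize: bool = True,
    n_jobs: int = 1,
    lasso_config: LassoConfig | None = None,
) -> ImputationResult:
    """Uniform dispatch over the four estimators."""
    if method not in METHODS:
        raise DataError(f"unknown method {method!r}; choose from {METHODS}")
    if method.endswith("lasso"):
        config = lasso_config or LassoConfig()
        if alpha is not None:
            config = LassoConfig(
                alpha=alpha,
                fit_intercept=config.fit_intercept,
                max_iter=config.max_iter,
                tol=config.tol,
            )
        if method == "sample-lasso":
            return sample_lasso_impute(
                targets, train, split, config, standardize=standardize,
                n_jobs=n_jobs,
            )
        models = gene_lasso_fit(train, split, config, standardize=standardize)
        return gene_lasso_impute(models, targets)
    config_k = KnnConfig(k=k if k is not None else KnnConfig().k)
    if method == "sample-knn":
        return sample_knn_impute(targets, train, split, config_k,
                                 standardize=standardize)
    return gene_knn_impute(targets, train, split, config_k,
                           standardize=standardize)


def tune_hyperparameter(
    method: str,
    train: ExpressionMatrix,
    validation: ExpressionMatrix,
    split: GeneSplit,
    grid: Sequence[float] | None = None,
    metric: str = "nrmse",
    standardize: bool = True,
    n_jobs: int = 1,
) -> tuple[float, pd.DataFrame]:
    """Grid-search α (LASSO) or k (KNN) against held-out validation samples.

    Each grid point is scored by the median per-gene metric over the
    validation set's unmeasured genes (genes whose metric is undefined are
    excluded).  Returns the argmin grid value and the full score table;
    deterministic given inputs (first grid point wins ties).
    """
    from .evaluate import mae_per_gene, nrmse_per_gene

    if method not in METHODS:
        raise DataError(f"unknown method {method!r}")
    if validation.n_samples == 0:
        raise DataError("validation set is empty")
    if grid is None:
        grid = DEFAULT_ALPHA_GRID if method.endswith("lasso") else [
            kk for kk in DEFAULT_K_GRID
            if kk <= (train.n_samples if method == "sample-knn"
                      else len(split.measured))
        ]
    grid = list(grid)
    if not grid:
        raise DataError("empty hyperparameter grid")
    truth = validation.subset_genes(split.unmeasured)
    rows = []
    for value in grid:
        if method.endswith("lasso"):
            result = impute(method, validation, train, split, alpha=float(value),
                            standardize=standardize, n_jobs=n_jobs)
        else:
            result = impute(method, validation, train, split, k=int(value),
                            standardize=standardize)
        if metric == "nrmse":
            per_gene = nrmse_per_gene(truth, result)
        elif metric == "mae":
            per_gene = mae_per_gene(truth, result)
        else:
            raise DataError(f"unsupported tuning metric {metric!r}")
        score = float(np.nanmedian(per_gene.to_numpy()))
        rows.append({"value": value, "score": score})
    table = pd.DataFrame(rows)
    best = table.loc[table["score"].idxmin(), "value"]
    best = float(best) if method.endswith("lasso") else int(best)
    return best, table
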