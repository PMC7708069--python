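"""Transforms, train-derived standardization, quantile normalization and
the temporal dataset-preserving sample split.

Standardization follows the train-only discipline: feature means and
standard deviations are estimated on the training set and reused verbatim
for validation and test data, so no information can leak backwards from
held-out samples.  The standard deviation uses the population (divide-by-n)
convention.  Genes are the features throughout: every gene is centred and
scaled over the training samples, and the sample-based methods operate on
the transposed standardized block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import DataError, ExpressionMatrix, SampleSplit


def archsinh_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Apply the inverse hyperbolic sine elementwise.

    asinh(x) = ln(x + sqrt(x^2 + 1)) is a variance-stabilizing transform
    for TPM-scale RNA-seq values: linear near zero, logarithmic for large
    values, and defined at zero (unlike log).
    """
    out = matrix.copy()
    out.values = np.arcsinh(out.values)
    return out


@dataclass
class StandardizationStats:
    """Per-feature mean/sd learned on a training matrix.

    ``feature_axis`` records which axis was treated as features ("genes" or
    "samples"); ``feature_ids`` names them so application can verify
    alignment.  Zero-sd (constant) features are flagged; they standardize
    to zero rather than NaN so they cannot poison distances or regressions.
    """

    mean: np.ndarray
    sd: np.ndarray
    feature_axis: str
    feature_ids: list[str]

    @property
    def constant_features(self) -> list[str]:
        return [f for f, s in zip(self.feature_ids, self.sd) if s == 0.0]


def fit_standardizer(
    train: ExpressionMatrix, feature_axis: str = "genes"
) -> StandardizationStats:
    """Estimate per-feature mean and population sd on the training set."""
    if feature_axis not in ("genes", "samples"):
        raise DataError("feature_axis must be 'genes' or 'samples'")
    if train.n_samples == 0 or train.n_genes == 0:
        raise DataError("cannot standardize an empty matrix")
    axis = 0 if feature_axis == "genes" else 1
    mean = train.values.mean(axis=axis)
    sd = train.values.std(axis=axis)  # population convention (ddof=0)
    ids = train.gene_ids if feature_axis == "genes" else train.sample_ids
    return StandardizationStats(mean=mean, sd=sd, feature_axis=feature_axis,
                                feature_ids=list(ids))


def apply_standardizer(
    stats: StandardizationStats, matrix: ExpressionMatrix
) -> ExpressionMatrix:
    """Standardize ``matrix`` with train-derived stats: (x - mean) / sd.

    Constant (zero-sd) features map to 0.  Features must align exactly with
    those the stats were fitted on.
    """
    ids = matrix.gene_ids if stats.feature_axis == "genes" else matrix.sample_ids
    if list(ids) != list(stats.feature_ids):
        missing = [f for f in stats.feature_ids if f not in set(ids)]
        extra = [f for f in ids if f not in set(stats.feature_ids)]
        raise DataError(
            f"feature mismatch: missing={missing[:5]} extra={extra[:5]}"
        )
    out = matrix.copy()
    safe_sd = np.where(stats.sd == 0.0, 1.0, stats.sd)
    if stats.feature_axis == "genes":
        out.values = (out.values - stats.mean) / safe_sd
        out.values[:, stats.sd == 0.0] = 0.0
    else:
        out.values = (out.values - stats.mean[:, None]) / safe_sd[:, None]
        out.values[stats.sd == 0.0, :] = 0.0
    return out


def invert_standardizer(
    stats: StandardizationStats, matrix: ExpressionMatrix
) -> ExpressionMatrix:
    """Map standardized values back to the original scale (x * sd + mean)."""
    out = matrix.copy()
    if stats.feature_axis == "genes":
        out.values = out.values * stats.sd + stats.mean
    else:
        out.values = out.values * stats.sd[:, None] + stats.mean[:, None]
    return out


def joint_quantile_normalize(
    matrices: list[ExpressionMatrix],
) -> list[ExpressionMatrix]:
    """Quantile-normalize every sample across all matrices jointly.

    The reference distribution is the mean of the sorted rows pooled over
    all samples of all matrices; after normalization every sample's sorted
    values equal that reference, forcing one common empirical distribution
    across datasets/platforms.
    """
    if not matrices:
        raise DataError("no matrices given")
    genes0 = matrices[0].gene_ids
    for m in matrices[1:]:
        if set(m.gene_ids) != set(genes0):
            raise DataError("matrices do not share a gene universe")
    total = sum(m.n_samples for m in matrices)
    if total < 2:
        raise DataError("joint quantile normalization needs >= 2 samples")
    n_genes = len(genes0)
    reference = np.zeros(n_genes)
    for m in matrices:
        reference += np.sort(m.values, axis=1).sum(axis=0)
    reference /= total
    out = []
    for m in matrices:
        norm = m.copy()
        order = np.argsort(m.values, axis=1, kind="stable")
        ranks = np.empty_like(order)
        rows = np.arange(m.n_samples)[:, None]
        ranks[rows, order] = np.arange(n_genes)[None, :]
        norm.values = reference[ranks]
        out.append(norm)
    return out


def _dataset_order(matrix: ExpressionMatrix) -> list[str]:
    """Datasets ordered by earliest sample date (undated datasets last, in
    first-appearance order)."""
    first_seen: dict[str, int] = {}
    earliest: dict[str, str | None] = {}
    for i, d in enumerate(matrix.dataset_ids):
        if d not in first_seen:
            first_seen[d] = i
            earliest[d] = None
        if matrix.dates is not None:
            date = matrix.dates[i]
            if date is not None and (earliest[d] is None or date < earliest[d]):
                earliest[d] = date
    def key(d: str):
        e = earliest[d]
        # dated datasets first (ISO strings compare ordinally), then file order
        return (e is None, e if e is not None else "", first_seen[d])
    return sorted(first_seen, key=key)


def temporal_dataset_split(
    matrix: ExpressionMatrix,
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
) -> SampleSplit:
    """Split samples into train/validation/test, oldest datasets first,
    never splitting a dataset across sets.

    Datasets are ordered by their earliest sample date and assigned whole,
    greedily, to train until the train sample-count fraction is first met
    or exceeded, then to validation likewise, with the remainder going to
    test.  Because whole datasets are assigned, realized fractions can
    deviate from the targets.
    """
    f_train, f_val, f_test = fractions
    if min(f_train, f_val, f_test) <= 0:
        raise DataError("fractions must be positive")
    if abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise DataError("fractions must sum to 1")
    order = _dataset_order(matrix)
    if len(order) < 3:
        raise DataError(
            "need at least 3 datasets for a dataset-preserving 3-way split"
        )
    sizes = {d: 0 for d in order}
    members: dict[str, list[str]] = {d: [] for d in order}
    for s, d in zip(matrix.sample_ids, matrix.dataset_ids):
        sizes[d] += 1
        members[d].append(s)
    n = matrix.n_samples
    n_ds = len(order)
    cum = np.cumsum([sizes[d] for d in order])
    # contiguous temporal segments: train = order[:i], val = order[i:j],
    # test = order[j:]; greedy boundaries, clamped so no segment is empty
    i = int(np.searchsorted(cum, f_train * n)) + 1
    i = min(i, n_ds - 2)
    j = i + 1
    while j < n_ds and cum[j - 1] - cum[i - 1] < f_val * n:
        j += 1
    j = min(j, n_ds - 1)
    train = [s for d in order[:i] for s in members[d]]
    validation = [s for d in order[i:j] for s in members[d]]
    test = [s for d in order[j:] for s in members[d]]
    split = SampleSplit(train=train, validation=validation, test=test)
    split.validate_against(matrix)
    return split


def subsample_validation(
    matrix: ExpressionMatrix,
    split: SampleSplit,
    rate: float = 0.10,
    small_dataset_min: int = 2,
    small_dataset_threshold: int = 20,
    seed: int = 0,
) -> list[str]:
    """Thin the validation set for hyperparameter tuning.

    Per validation dataset of size n: keep ``ceil(rate * n)`` samples when
    ``n >= small_dataset_threshold``, else ``min(n, small_dataset_min)``.
    Selection is uniform at random and deterministic under ``seed``.
    """
    if not split.validation:
        raise DataError("validation set is empty")
    ds_of = dict(zip(matrix.sample_ids, matrix.dataset_ids))
    groups: dict[str, list[str]] = {}
    for s in split.validation:
        groups.setdefault(ds_of[s], []).append(s)
    rng = np.random.default_rng(seed)
    kept: list[str] = []
    for d in sorted(groups):
        samples = groups[d]
        n = len(samples)
        if n >= small_dataset_threshold:
            keep = math.ceil(rate * n)
        else:
            keep = min(n, small_dataset_min)
        idx = rng.choice(n, size=keep, replace=False)
        kept.extend(samples[i] for i in sorted(idx))
    return kept
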