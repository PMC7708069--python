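"""Tissue-level interpretability of SampleLASSO coefficient vectors.

For a target sample s with coefficients beta_j over training samples, the
aggregate signal attributed to tissue T is the standardized score

    z_{s,T} = ( mean_{j in T} beta_j - mu_s ) / ( sigma_s / sqrt(|T|) )

where mu_s and sigma_s are the mean and (population) standard deviation of
the beta-coefficients of *all* tissue-labeled training samples — any
tissue, not just the queried ones — and |T| is the number of labeled
training samples of tissue T.  A high z_{s,T} means the model leaned on
tissue-T training samples far more than a random |T|-subset of labeled
samples; if the top-scoring tissue is the target's own tissue, the model's
support is biologically coherent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import DataError, TissueLabels
from .impute import ImputationResult


def tissue_zscores(
    betas: pd.DataFrame,
    labels: TissueLabels,
    tissues: list[str] | None = None,
) -> pd.DataFrame:
    """Compute the per-target, per-tissue coefficient z-score table.

    Parameters
    ----------
    betas
        SampleLASSO coefficients, one row per target sample and one column
        per training sample (``result.diagnostics['betas']``).
    labels
        Tissue labels resolving (a subset of) the training samples.
    tissues
        Tissues to score; defaults to every tissue with at least one
        labeled training sample.  A queried tissue with no labeled training
        sample is an error.

    Returns a dense targets x tissues DataFrame with the per-target
    background mean ``mu`` and sd ``sigma`` attached as extra columns.
    Targets with ``sigma == 0`` (e.g. all-zero coefficient vectors) get NaN
    z-scores — flagged, not scored.
    """
    train_samples = list(betas.columns)
    labeled = [s for s in train_samples if labels.tissue_of(s) is not None]
    if not labeled:
        raise DataError("no training sample carries a tissue label")
    tissue_of = {s: labels.tissue_of(s) for s in labeled}
    present = {}
    for s in labeled:
        present.setdefault(tissue_of[s], []).append(s)
    if tissues is None:
        tissues = list(present)
    else:
        missing = [t for t in tissues if t not in present]
        if missing:
            raise DataError(
                f"tissue(s) with no labeled training samples: {missing}"
            )
    B = betas[labeled].to_numpy()  # (n_targets, n_labeled)
    mu = B.mean(axis=1)
    sigma = B.std(axis=1)  # population sd, matching the standardizer
    z = np.full((B.shape[0], len(tissues)), np.nan)
    ok = sigma > 0
    # constant nonzero coefficients: every subset mean equals mu, so the
    # numerator vanishes identically and z = 0; all-zero coefficient
    # vectors (no model signal) stay flagged as NaN
    const = (~ok) & (mu != 0.0)
    for t_idx, tissue in enumerate(tissues):
        members = present[tissue]
        size = len(members)
        subset_mean = betas[members].to_numpy().mean(axis=1)
        z[ok, t_idx] = (subset_mean[ok] - mu[ok]) / (sigma[ok] / np.sqrt(size))
        z[const, t_idx] = 0.0
    out = pd.DataFrame(z, index=betas.index, columns=tissues)
    out["mu"] = mu
    out["sigma"] = sigma
    return out


def tissue_zscores_from_result(
    result: ImputationResult,
    labels: TissueLabels,
    tissues: list[str] | None = None,
) -> pd.DataFrame:
    if result.method != "sample-lasso":
        raise DataError("tissue z-scores require a SampleLASSO result")
    return tissue_zscores(result.diagnostics["betas"], labels, tissues)


def same_tissue_top_rate(
    table: pd.DataFrame, target_labels: TissueLabels
) -> float:
    """Fraction of targets whose top-z tissue is their own tissue.

    Ties at the maximum are broken *against* the hypothesis: a target
    only counts if its own tissue's z strictly exceeds every other
    tissue's.  Every target must carry a label within the table's tissues.
    """
    tissues = [c for c in table.columns if c not in ("mu", "sigma")]
    hits = 0
    total = 0
    for target in table.index:
        own = target_labels.tissue_of(str(target))
        if own is None:
            raise DataError(f"target {target} has no tissue label")
        if own not in tissues:
            raise DataError(
                f"target {target} labeled {own!r}, absent from the z-score table"
            )
        row = table.loc[target, tissues].to_numpy(dtype=float)
        if np.isnan(row).any():
            continue  # flagged target (sigma == 0): not scored
        own_z = table.loc[target, own]
        others = [table.loc[target, t] for t in tissues if t != own]
        if own_z > max(others):
            hits += 1
        total += 1
    if total == 0:
        raise DataError("no scorable targets")
    return hits / total
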