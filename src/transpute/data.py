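"""Core in-memory containers for expression compendia and their partitions.

The universal currency of the package is :class:`ExpressionMatrix`: a dense
samples-by-genes matrix carrying sample identifiers, experiment (dataset)
membership and optional sample dates.  Gene partitions
(:class:`GeneSplit`), sample partitions (:class:`SampleSplit`) and tissue
annotations (:class:`TissueLabels`) are thin validated wrappers used by the
preprocessing, imputation and interpretation layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np


class DataError(ValueError):
    """Raised when an input violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    if dups:
        raise DataError(f"duplicate {what}: {', '.join(map(str, dups[:10]))}")


@dataclass
class ExpressionMatrix:
    """Dense expression matrix (samples x genes) with sample metadata.

    Parameters
    ----------
    values
        Array of shape ``(n_samples, n_genes)`` on whatever scale the data
        were stored (e.g. fRMA intensity, asinh(TPM)).
    sample_ids, gene_ids
        Unique identifiers for the rows and columns, order-preserving.
    dataset_ids
        Experiment/series membership of each sample; mandatory because the
        sample-splitting scheme assigns whole datasets to splits.
    dates
        Optional per-sample ISO-8601 date strings (``None`` for undated
        samples); compared ordinally by the temporal split.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    dataset_ids: list[str]
    dates: list[str | None] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.dataset_ids = [str(d) for d in self.dataset_ids]
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D array (samples x genes)")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise DataError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(self.gene_ids) != p:
            raise DataError(f"{len(self.gene_ids)} gene ids for {p} columns")
        if len(self.dataset_ids) != n:
            raise DataError("every sample needs a dataset_id")
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.gene_ids, "gene ids")
        if self.dates is not None and len(self.dates) != n:
            raise DataError("dates length must match number of samples")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"non-finite value at sample {self.sample_ids[bad[0]]}, "
                f"gene {self.gene_ids[bad[1]]}"
            )

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.sample_ids)}

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    # -- subsetting ----------------------------------------------------------
    def subset_samples(self, ids: Iterable[str]) -> "ExpressionMatrix":
        idx = self.sample_index()
        ids = list(ids)
        missing = [s for s in ids if s not in idx]
        if missing:
            raise DataError(f"unknown sample ids: {', '.join(missing[:10])}")
        rows = [idx[s] for s in ids]
        return ExpressionMatrix(
            values=self.values[rows],
            sample_ids=ids,
            gene_ids=list(self.gene_ids),
            dataset_ids=[self.dataset_ids[r] for r in rows],
            dates=None if self.dates is None else [self.dates[r] for r in rows],
        )

    def subset_genes(self, ids: Iterable[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        ids = list(ids)
        missing = [g for g in ids if g not in idx]
        if missing:
            raise DataError(f"unknown gene ids: {', '.join(missing[:10])}")
        cols = [idx[g] for g in ids]
        return ExpressionMatrix(
            values=self.values[:, cols],
            sample_ids=list(self.sample_ids),
            gene_ids=ids,
            dataset_ids=list(self.dataset_ids),
            dates=None if self.dates is None else list(self.dates),
        )

    def gene_values(self, split_genes: Sequence[str]) -> np.ndarray:
        """Return the value block for ``split_genes`` in that order."""
        idx = self.gene_index()
        cols = [idx[g] for g in split_genes]
        return self.values[:, cols]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            sample_ids=list(self.sample_ids),
            gene_ids=list(self.gene_ids),
            dataset_ids=list(self.dataset_ids),
            dates=None if self.dates is None else list(self.dates),
        )


@dataclass
class GeneSplit:
    """Ordered partition of a gene universe into measured and unmeasured sets."""

    measured: list[str]
    unmeasured: list[str]

    def __post_init__(self) -> None:
        self.measured = [str(g) for g in self.measured]
        self.unmeasured = [str(g) for g in self.unmeasured]
        if not self.measured or not self.unmeasured:
            raise DataError("both measured and unmeasured gene sets must be non-empty")
        _check_unique(self.measured, "measured gene ids")
        _check_unique(self.unmeasured, "unmeasured gene ids")
        overlap = set(self.measured) & set(self.unmeasured)
        if overlap:
            raise DataError(
                f"genes in both measured and unmeasured sets: "
                f"{', '.join(sorted(overlap)[:10])}"
            )

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        universe = set(matrix.gene_ids)
        missing = [g for g in self.measured + self.unmeasured if g not in universe]
        if missing:
            raise DataError(
                f"split genes absent from matrix: {', '.join(missing[:10])}"
            )


@dataclass
class TissueLabels:
    """Mapping from sample id to a single tissue-of-origin label."""

    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = {str(k): str(v) for k, v in self.labels.items()}

    def tissue_of(self, sample_id: str) -> str | None:
        return self.labels.get(sample_id)

    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.labels.values():
            seen.setdefault(t, None)
        return list(seen)

    def labeled_samples(self, among: Iterable[str] | None = None) -> list[str]:
        if among is None:
            return list(self.labels)
        return [s for s in among if s in self.labels]

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class SampleSplit:
    """Assignment of samples to train / validation / test sets.

    The splitting scheme keeps all samples of an experiment (dataset)
    together, so the invariant checked by :meth:`validate_against` is that no
    dataset straddles two sets.
    """

    train: list[str]
    validation: list[str]
    test: list[str]

    def __post_init__(self) -> None:
        for part in ("train", "validation", "test"):
            setattr(self, part, [str(s) for s in getattr(self, part)])
        all_ids = self.train + self.validation + self.test
        _check_unique(all_ids, "sample ids across splits")

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        known = set(matrix.sample_ids)
        stray = [s for s in self.train + self.validation + self.test if s not in known]
        if stray:
            raise DataError(f"split samples absent from matrix: {stray[:10]}")
        ds_of = dict(zip(matrix.sample_ids, matrix.dataset_ids))
        seen: dict[str, str] = {}
        for part in ("train", "validation", "test"):
            for s in getattr(self, part):
                d = ds_of[s]
                if d in seen and seen[d] != part:
                    raise DataError(
                        f"dataset {d} straddles splits {seen[d]} and {part}"
                    )
                seen[d] = part


def align_metadata(
    matrix: ExpressionMatrix, labels: TissueLabels
) -> dict[str, str]:
    """Resolve tissue labels against a matrix, returning only labels whose
    sample ids occur in the matrix."""
    present = set(matrix.sample_ids)
    return {s: t for s, t in labels.labels.items() if s in present}
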