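"""Synthetic expression-compendium generator.

Emulates the statistical structure the imputation methods exploit, so the
whole pipeline is testable without multi-gigabyte downloads:

* tissue-block correlation among samples (samples of one tissue share a
  latent gene profile),
* experiment (dataset) structure with synthetic dates, so the temporal
  dataset-preserving split is exercisable,
* gene co-expression modules (shared per-sample module factors),
* strictly positive expression on an additive scale, so per-gene NRMSE
  denominators are valid and linear generative ground truth is exactly
  recoverable by linear methods,
* an optional cross-"technology" rendering with per-gene affine distortion
  (gain and offset) plus extra noise, mimicking the distribution shift
  between RNA-seq-like and microarray-like renderings of the same samples.

The generative model for sample i, gene g is

    x_ig = b_g + sqrt(v0) z0_g + sqrt(vt) z_{t(i),g} + sqrt(vd) w_{d(i),g}
           + s_mod l_g f_{i,m(g)} + sqrt(veps) e_ig + n_g eps_ig

with all latent vectors standard normal.  The component variances are
solved from the requested within/between-tissue sample-correlation targets
(raw Pearson correlation between sample vectors across genes), so the
generator is calibrated by construction; infeasible targets raise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DataError, ExpressionMatrix, GeneSplit, TissueLabels

# gene-count ratios of the two canonical measured/unmeasured designs:
# a large measured set imputing a smaller one (11678 : 5277) and a small
# landmark-style set imputing the rest of the genome (964 : 15991)
LARGE_MEASURED_RATIO = 11678 / (11678 + 5277)
SMALL_MEASURED_RATIO = 964 / (964 + 15991)


@dataclass
class CrossPlatformConfig:
    """Distortion model for the second 'platform' rendering.

    Two layers mimic how an unnormalized RNA-seq-like compendium differs
    from a microarray-like one: a per-sample affine distortion (each
    profile has its own scale and shift, as when samples are not
    quantile-normalized against each other and sequencing depth varies),
    then a per-gene affine distortion (probe-efficiency-like gain and
    background offset), plus heavier-tailed extra noise (Student-t).
    """

    gain_range: tuple[float, float] = (0.5, 2.0)
    offset_range: tuple[float, float] = (0.0, 2.0)
    sample_scale_range: tuple[float, float] = (0.75, 1.25)
    sample_offset_sd: float = 0.5
    extra_noise_sd: float = 0.25
    extra_noise_df: float = 4.0  # dof of the t-distributed extra noise


@dataclass
class SynthConfig:
    n_tissues: int = 6
    samples_per_tissue: int = 125
    datasets_per_tissue: int = 5
    n_genes: int = 1000
    n_modules: int = 10
    within_tissue_corr: float = 0.7
    between_tissue_corr: float = 0.1
    noise_sd: float = 0.25
    positive_shift: float = 10.0
    baseline_spread: float = 0.4  # half-width of per-gene baseline means
    module_sd: float = 0.387  # modules carry ~15% of per-gene variance
    dataset_effect_sd: float = 0.05
    seed: int = 0
    cross_platform: CrossPlatformConfig | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.between_tissue_corr <= self.within_tissue_corr < 1):
            raise DataError(
                "need 0 <= between_tissue_corr <= within_tissue_corr < 1"
            )
        if self.noise_sd <= 0:
            raise DataError("noise_sd must be positive")
        if self.positive_shift <= 3 * self.noise_sd:
            raise DataError("positive_shift must exceed 3 * noise_sd")
        if self.samples_per_tissue < self.datasets_per_tissue:
            raise DataError("each dataset needs at least one sample")

    def component_variances(self) -> dict[str, float]:
        """Solve the variance budget from the correlation targets.

        Total across-gene variance of a sample vector is normalized to 1;
        shared components must supply exactly ``between_tissue_corr``
        (baseline + global profile) and ``within_tissue_corr`` (plus the
        tissue profile) of it.
        """
        v_b = self.baseline_spread**2 / 3.0  # Var of U(-d, d)
        v0 = self.between_tissue_corr - v_b
        if v0 < 0:
            raise DataError(
                "infeasible correlation targets: baseline_spread variance "
                f"({v_b:.3f}) exceeds between_tissue_corr"
            )
        v_t = self.within_tissue_corr - self.between_tissue_corr
        v_mod = self.module_sd**2
        v_d = self.dataset_effect_sd**2
        # per-gene noise sd is noise_sd * U(0.5, 1.5): E[u^2] = 1 + 1/12
        v_noise = self.noise_sd**2 * (1 + 1 / 12)
        v_eps = 1.0 - self.within_tissue_corr - v_mod - v_d - v_noise
        if v_eps < 0:
            raise DataError(
                "infeasible correlation targets: noise/module/dataset "
                "variance exceeds the idiosyncratic budget "
                f"(1 - within_tissue_corr = {1 - self.within_tissue_corr:.3f})"
            )
        return {
            "v_b": v_b, "v0": v0, "v_t": v_t, "v_mod": v_mod,
            "v_d": v_d, "v_noise": v_noise, "v_eps": v_eps,
        }


@dataclass
class Compendium:
    """A generated compendium plus its ground truth."""

    matrix: ExpressionMatrix
    labels: TissueLabels
    latent: np.ndarray = field(repr=False)  # noiseless expression values


def generate_compendium(config: SynthConfig) -> Compendium:
    """Draw a tissue-structured, dataset-annotated expression compendium.

    Deterministic given ``config.seed``.  Datasets are interleaved across
    tissues in date order so every temporal split stratum contains all
    tissues.
    """
    v = config.component_variances()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    T = config.n_tissues
    n = T * config.samples_per_tissue

    baseline = config.positive_shift + rng.uniform(
        -config.baseline_spread, config.baseline_spread, size=G
    )
    z0 = rng.standard_normal(G)
    z_tissue = rng.standard_normal((T, G))
    module_of = rng.integers(0, config.n_modules, size=G)
    loading = rng.standard_normal(G)
    noise_scale = config.noise_sd * rng.uniform(0.5, 1.5, size=G)

    # datasets interleaved across tissues, dated in generation order
    datasets = []  # (tissue, dataset_name, date)
    per_ds = config.samples_per_tissue // config.datasets_per_tissue
    extras = config.samples_per_tissue - per_ds * config.datasets_per_tissue
    counter = 0
    for d in range(config.datasets_per_tissue):
        for t in range(T):
            size = per_ds + (1 if d < extras else 0)
            year = 2000 + counter // 12
            month = counter % 12 + 1
            datasets.append((t, f"DS{counter:04d}", f"{year:04d}-{month:02d}-01", size))
            counter += 1

    sample_ids, dataset_ids, dates, tissues_of = [], [], [], []
    rows_latent = []
    rows_noise = []
    sidx = 0
    for t, ds_name, date, size in datasets:
        w_dataset = rng.standard_normal(G)
        for _ in range(size):
            f_mod = rng.standard_normal(config.n_modules)
            e = rng.standard_normal(G)
            latent = (
                baseline
                + np.sqrt(v["v0"]) * z0
                + np.sqrt(v["v_t"]) * z_tissue[t]
                + np.sqrt(v["v_d"]) * w_dataset
                + config.module_sd * loading * f_mod[module_of]
                + np.sqrt(v["v_eps"]) * e
            )
            rows_latent.append(latent)
            rows_noise.append(noise_scale * rng.standard_normal(G))
            sample_ids.append(f"S{sidx:05d}")
            dataset_ids.append(ds_name)
            dates.append(date)
            tissues_of.append(f"tissue_{t + 1}")
            sidx += 1
    latent = np.vstack(rows_latent)
    values = latent + np.vstack(rows_noise)
    matrix = ExpressionMatrix(
        values=values,
        sample_ids=sample_ids,
        gene_ids=[f"G{g:05d}" for g in range(G)],
        dataset_ids=dataset_ids,
        dates=dates,
    )
    labels = TissueLabels(dict(zip(sample_ids, tissues_of)))
    return Compendium(matrix=matrix, labels=labels, latent=latent)


@dataclass
class CrossPlatformPair:
    """Two renderings of the same samples plus the distortion ground truth."""

    source: ExpressionMatrix
    target: ExpressionMatrix
    labels: TissueLabels
    gains: np.ndarray
    offsets: np.ndarray
    sample_scales: np.ndarray
    sample_offsets: np.ndarray


def generate_cross_platform_pair(config: SynthConfig) -> CrossPlatformPair:
    """Render the same latent samples on two 'platforms'.

    The source matrix is a plain compendium; the target applies, per
    sample, an affine distortion (scale, shift) and then, per gene, an
    affine distortion (gain, offset), finally adding heavier-tailed extra
    noise.  All distortion parameters are returned as ground truth.
    """
    cp = config.cross_platform or CrossPlatformConfig()
    comp = generate_compendium(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    G = config.n_genes
    n = comp.matrix.n_samples
    gains = rng.uniform(*cp.gain_range, size=G)
    offsets = rng.uniform(*cp.offset_range, size=G)
    sample_scales = rng.uniform(*cp.sample_scale_range, size=n)
    sample_offsets = (
        cp.sample_offset_sd * rng.standard_normal(n)
        if cp.sample_offset_sd > 0 else np.zeros(n)
    )
    src = comp.matrix
    per_sample = src.values * sample_scales[:, None] + sample_offsets[:, None]
    tgt_values = per_sample * gains + offsets
    if cp.extra_noise_sd > 0:
        # Student-t noise scaled to sd = extra_noise_sd (heavier tails)
        df = cp.extra_noise_df
        scale = cp.extra_noise_sd / np.sqrt(df / (df - 2))
        tgt_values = tgt_values + scale * rng.standard_t(df, size=src.values.shape)
    target = ExpressionMatrix(
        values=tgt_values,
        sample_ids=list(src.sample_ids),
        gene_ids=list(src.gene_ids),
        dataset_ids=list(src.dataset_ids),
        dates=None if src.dates is None else list(src.dates),
    )
    return CrossPlatformPair(
        source=src, target=target, labels=comp.labels,
        gains=gains, offsets=offsets,
        sample_scales=sample_scales, sample_offsets=sample_offsets,
    )


def make_gene_split(
    matrix: ExpressionMatrix,
    mode: str = "large_measured",
    sizes: tuple[int, int] | None = None,
    seed: int = 0,
) -> GeneSplit:
    """Randomly partition the gene universe into measured/unmeasured sets.

    ``large_measured`` scales the 11678:5277 design down to the matrix's
    gene count; ``small_measured`` scales 964:15991; ``custom`` takes
    explicit ``sizes = (n_measured, n_unmeasured)``.
    """
    genes = list(matrix.gene_ids)
    G = len(genes)
    if mode == "large_measured":
        n_meas = round(LARGE_MEASURED_RATIO * G)
        n_unmeas = G - n_meas
    elif mode == "small_measured":
        n_meas = round(SMALL_MEASURED_RATIO * G)
        n_unmeas = G - n_meas
    elif mode == "custom":
        if sizes is None:
            raise DataError("custom mode requires sizes=(n_measured, n_unmeasured)")
        n_meas, n_unmeas = sizes
        if n_meas + n_unmeas > G:
            raise DataError(
                f"requested {n_meas}+{n_unmeas} genes from a universe of {G}"
            )
    else:
        raise DataError(f"unknown mode {mode!r}")
    if n_meas < 1 or n_unmeas < 1:
        raise DataError("both gene sets must be non-empty")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(G)
    measured = [genes[i] for i in perm[:n_meas]]
    unmeasured = [genes[i] for i in perm[n_meas:n_meas + n_unmeas]]
    return GeneSplit(measured=measured, unmeasured=unmeasured)


# ---------------------------------------------------------------------------
# canned study scenarios


def benchmark_config(seed: int = 0, **overrides) -> SynthConfig:
    """Default 6-tissue benchmark compendium: 750 samples, 1000 genes.

    With split fractions (0.8, 1/15, 2/15) the temporal dataset-preserving
    split yields exactly 600 train / 50 validation / 100 test samples.
    """
    params = dict(
        n_tissues=6, samples_per_tissue=125, datasets_per_tissue=5,
        n_genes=1000, seed=seed,
    )
    params.update(overrides)
    return SynthConfig(**params)


BENCHMARK_FRACTIONS = (0.8, 1 / 15, 2 / 15)


def interpretability_config(seed: int = 0, **overrides) -> SynthConfig:
    """Labeled 6-tissue scenario sized so the test split holds >= 200
    targets with >= 10 labeled training samples per tissue from >= 3
    datasets."""
    params = dict(
        n_tissues=6, samples_per_tissue=150, datasets_per_tissue=5,
        n_genes=1000, seed=seed,
    )
    params.update(overrides)
    return SynthConfig(**params)


INTERPRETABILITY_FRACTIONS = (0.7, 1 / 15, 1 - 0.7 - 1 / 15)
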