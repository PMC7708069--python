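import warnings

import numpy as np
import pytest
from sklearn.exceptions import ConvergenceWarning

from transpute import (
    DataError,
    ExpressionMatrix,
    GeneSplit,
    KnnConfig,
    LassoConfig,
    gene_knn_impute,
    gene_lasso_fit,
    gene_lasso_impute,
    impute,
    sample_knn_impute,
    sample_lasso_impute,
    tune_hyperparameter,
)

from conftest import make_matrix


def toy_matrix(values, prefix="s", datasets=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ExpressionMatrix(
        values=values,
        sample_ids=[f"{prefix}{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(p)],
        dataset_ids=datasets or [f"d{i}" for i in range(n)],
    )


@pytest.fixture
def train_and_split():
    train = make_matrix(30, 20, seed=1)
    genes = train.gene_ids
    split = GeneSplit(measured=genes[:12], unmeasured=genes[12:])
    return train, split


class TestSampleLasso:
    def test_exact_copy_limit(self, train_and_split):
        """A target equal to one training sample's measured genes is imputed
        as (approximately) that sample's unmeasured genes at small alpha."""
        train, split = train_and_split
        t = train.subset_samples([train.sample_ids[4]])
        target = ExpressionMatrix(
            values=t.gene_values(split.measured),
            sample_ids=["tgt"], gene_ids=split.measured, dataset_ids=["dt"],
        )
        res = sample_lasso_impute(
            target, train, split, LassoConfig(alpha=1e-4, max_iter=50000)
        )
        expected = t.gene_values(split.unmeasured)[0]
        assert np.abs(res.imputed[0] - expected).max() < 0.05
        beta = res.diagnostics["betas"].iloc[0]
        assert beta.idxmax() == train.sample_ids[4]

    def test_full_shrinkage_gives_intercept_only(self, train_and_split):
        train, split = train_and_split
        target = make_matrix(2, 20, seed=9)
        res = sample_lasso_impute(target, train, split, LassoConfig(alpha=1e6))
        betas = res.diagnostics["betas"].to_numpy()
        np.testing.assert_array_equal(betas, 0.0)
        # imputed values are the per-gene back-transformed intercepts:
        # constant across unmeasured genes in standardized space
        train_unmeas = train.gene_values(split.unmeasured)
        mean = train_unmeas.mean(axis=0)
        sd = train_unmeas.std(axis=0)
        intercepts = res.diagnostics["intercepts"].to_numpy()
        expected = intercepts[:, None] * sd + mean
        np.testing.assert_allclose(res.imputed, expected, atol=1e-10)

    def test_parameter_recovery_two_sample_mixture(self):
        """A target built as 0.6*A + 0.4*B (+tiny noise) on measured genes
        yields a SampleLASSO model supported on {A, B} with coefficients
        near (0.6, 0.4) at a validation-chosen alpha."""
        rng = np.random.default_rng(7)
        train = make_matrix(50, 300, seed=2)
        genes = train.gene_ids
        split = GeneSplit(measured=genes[:200], unmeasured=genes[200:])
        A, B = 3, 17
        meas = train.gene_values(split.measured)
        y = 0.6 * meas[A] + 0.4 * meas[B] + rng.normal(0, 0.01, 200)
        target = ExpressionMatrix(
            values=y[None, :], sample_ids=["tgt"],
            gene_ids=split.measured, dataset_ids=["dt"],
        )
        best = None
        best_score = np.inf
        truth_unmeas = (0.6 * train.gene_values(split.unmeasured)[A]
                        + 0.4 * train.gene_values(split.unmeasured)[B])
        for alpha in (1e-4, 1e-3, 1e-2, 1e-1):
            res = sample_lasso_impute(
                target, train, split, LassoConfig(alpha=alpha, max_iter=50000)
            )
            score = np.sqrt(np.mean((res.imputed[0] - truth_unmeas) ** 2))
            if score < best_score:
                best_score, best = score, res
        beta = best.diagnostics["betas"].iloc[0].to_numpy()
        support = set(np.flatnonzero(np.abs(beta) > 0.01))
        assert support == {A, B}
        assert abs(beta[A] - 0.6) < 0.05
        assert abs(beta[B] - 0.4) < 0.05

    def test_negative_alpha_rejected(self):
        with pytest.raises(DataError):
            LassoConfig(alpha=-1.0)

    def test_measured_gene_mismatch_rejected(self, train_and_split):
        train, split = train_and_split
        target = make_matrix(2, 5, seed=0)  # lacks most measured genes
        with pytest.raises(DataError, match="measured genes"):
            sample_lasso_impute(target, train, split)

    def test_parallelism_invariance(self, train_and_split):
        train, split = train_and_split
        target = make_matrix(4, 20, seed=11)
        a = sample_lasso_impute(target, train, split, LassoConfig(alpha=0.05))
        b = sample_lasso_impute(
            target, train, split, LassoConfig(alpha=0.05), n_jobs=2
        )
        np.testing.assert_array_equal(a.imputed, b.imputed)

    def test_most_utilized_samples_sorted(self, train_and_split):
        train, split = train_and_split
        target = make_matrix(1, 20, seed=13)
        res = sample_lasso_impute(target, train, split, LassoConfig(alpha=0.05))
        top = res.most_utilized_samples(target.sample_ids[0])
        mags = np.abs(top["beta"].to_numpy())
        assert (np.diff(mags) <= 1e-15).all()
        assert (top["beta"] != 0).all()


class TestGeneLasso:
    def test_duplicated_gene_recovered(self):
        """An unmeasured gene that copies a measured gene gets a single
        dominant coefficient at small alpha."""
        rng = np.random.default_rng(3)
        meas = rng.normal(10, 1, size=(40, 6))
        values = np.hstack([meas, meas[:, [2]]])  # gene g6 == gene g2
        train = toy_matrix(values)
        split = GeneSplit(measured=train.gene_ids[:6],
                          unmeasured=[train.gene_ids[6]])
        models = gene_lasso_fit(train, split, LassoConfig(alpha=1e-3,
                                                          max_iter=50000))
        coefs = models.unstandardized_coefs()[0]
        assert abs(coefs[2] - 1.0) < 0.05
        others = np.delete(coefs, 2)
        assert np.abs(others).max() < 0.05

    def test_full_shrinkage_predicts_training_mean(self, train_and_split):
        train, split = train_and_split
        models = gene_lasso_fit(train, split, LassoConfig(alpha=1e6))
        target = make_matrix(3, 20, seed=5)
        res = gene_lasso_impute(models, target)
        train_means = train.gene_values(split.unmeasured).mean(axis=0)
        np.testing.assert_allclose(
            res.imputed, np.tile(train_means, (3, 1)), atol=1e-8
        )

    def test_linear_combination_recovered(self):
        """u = 2*g0 - g1 + noise: unstandardized coefficients near (2, -1)."""
        rng = np.random.default_rng(8)
        meas = rng.normal(10, 1, size=(200, 5))
        u = 2 * meas[:, 0] - meas[:, 1] + rng.normal(0, 0.05, 200)
        train = toy_matrix(np.hstack([meas, u[:, None]]))
        split = GeneSplit(measured=train.gene_ids[:5],
                          unmeasured=[train.gene_ids[5]])
        models = gene_lasso_fit(train, split, LassoConfig(alpha=1e-3,
                                                          max_iter=50000))
        coefs = models.unstandardized_coefs()[0]
        assert abs(coefs[0] - 2.0) < 0.1
        assert abs(coefs[1] + 1.0) < 0.1

    def test_batched_equals_single_target(self, train_and_split):
        train, split = train_and_split
        targets = make_matrix(5, 20, seed=6)
        models = gene_lasso_fit(train, split, LassoConfig(alpha=0.1))
        batched = gene_lasso_impute(models, targets)
        one = gene_lasso_impute(models, targets.subset_samples(
            [targets.sample_ids[2]]
        ))
        np.testing.assert_allclose(batched.imputed[2], one.imputed[0],
                                   atol=1e-12)

    def test_prediction_matches_matmul_oracle(self, train_and_split):
        train, split = train_and_split
        targets = make_matrix(4, 20, seed=14)
        models = gene_lasso_fit(train, split, LassoConfig(alpha=0.05))
        res = gene_lasso_impute(models, targets)
        X = targets.gene_values(split.measured)
        mean = train.gene_values(split.measured).mean(axis=0)
        sd = train.gene_values(split.measured).std(axis=0)
        Xs = (X - mean) / sd
        expected = Xs @ models.coefs.T + models.intercepts
        np.testing.assert_allclose(res.imputed, expected, atol=1e-10)


def brute_force_sample_knn(targets, train, split, k, standardize=True):
    """Literal O(n^2) transcription: all-pairs distances on (standardized)
    measured genes, inverse-distance-weighted average of unmeasured genes."""
    tm = train.gene_values(split.measured)
    um = train.gene_values(split.unmeasured)
    qm = targets.gene_values(split.measured)
    if standardize:
        mu, sd = tm.mean(0), tm.std(0)
        sd = np.where(sd == 0, 1.0, sd)
        tm, qm = (tm - mu) / sd, (qm - mu) / sd
    out = np.zeros((qm.shape[0], um.shape[1]))
    for i in range(qm.shape[0]):
        d = np.array([np.sqrt(((qm[i] - tm[j]) ** 2).sum())
                      for j in range(tm.shape[0])])
        order = sorted(range(len(d)), key=lambda j: (d[j], j))[:k]
        dk = d[order]
        if (dk == 0).any():
            w = np.where(dk == 0, 1.0, 0.0)
        else:
            w = 1.0 / dk
        w = w / w.sum()
        out[i] = sum(w[a] * um[order[a]] for a in range(k))
    return out


def brute_force_gene_knn(targets, train, split, k, standardize=True):
    """Literal transcription: per unmeasured gene, distances between its
    train column and every measured gene's train column, then an
    inverse-distance-weighted average of the target's own values there."""
    tm = train.gene_values(split.measured)
    um = train.gene_values(split.unmeasured)
    qm = targets.gene_values(split.measured)  # raw values are averaged
    if standardize:
        mu_m, sd_m = tm.mean(0), tm.std(0)
        sd_m = np.where(sd_m == 0, 1.0, sd_m)
        mu_u, sd_u = um.mean(0), um.std(0)
        sd_u = np.where(sd_u == 0, 1.0, sd_u)
        tm = (tm - mu_m) / sd_m
        um = (um - mu_u) / sd_u
    out = np.zeros((qm.shape[0], um.shape[1]))
    for u in range(um.shape[1]):
        d = np.array([np.sqrt(((um[:, u] - tm[:, m]) ** 2).sum())
                      for m in range(tm.shape[1])])
        order = sorted(range(len(d)), key=lambda m: (d[m], m))[:k]
        dk = d[order]
        if (dk == 0).any():
            w = np.where(dk == 0, 1.0, 0.0)
        else:
            w = 1.0 / dk
        w = w / w.sum()
        out[:, u] = qm[:, order] @ w
    return out


class TestSampleKnn:
    def test_identical_target_k1_copies_neighbor(self, train_and_split):
        train, split = train_and_split
        t = train.subset_samples([train.sample_ids[7]])
        target = ExpressionMatrix(
            values=t.gene_values(split.measured), sample_ids=["tgt"],
            gene_ids=split.measured, dataset_ids=["dt"],
        )
        res = sample_knn_impute(target, train, split, KnnConfig(k=1))
        np.testing.assert_array_equal(
            res.imputed[0], t.gene_values(split.unmeasured)[0]
        )

    def test_hand_weighted_mean(self):
        # neighbors at distances 1 and 2, gene values 10 and 40 -> 20
        train = toy_matrix([[1.0, 10.0], [2.0, 40.0], [100.0, 0.0]])
        split = GeneSplit(measured=["g0"], unmeasured=["g1"])
        target = ExpressionMatrix(values=[[0.0]], sample_ids=["t"],
                                  gene_ids=["g0"], dataset_ids=["d"])
        res = sample_knn_impute(target, train, split, KnnConfig(k=2),
                                standardize=False)
        assert res.imputed[0, 0] == pytest.approx(20.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        for trial in range(5):
            train = make_matrix(40, 15, seed=100 + trial)
            targets = make_matrix(6, 15, seed=200 + trial)
            split = GeneSplit(measured=train.gene_ids[:9],
                              unmeasured=train.gene_ids[9:])
            k = int(rng.integers(1, 8))
            res = sample_knn_impute(targets, train, split, KnnConfig(k=k))
            oracle = brute_force_sample_knn(targets, train, split, k)
            np.testing.assert_allclose(res.imputed, oracle, atol=1e-10)

    def test_k_exceeding_train_rejected(self, train_and_split):
        train, split = train_and_split
        target = make_matrix(1, 20, seed=0)
        with pytest.raises(DataError, match="exceeds"):
            sample_knn_impute(target, train, split, KnnConfig(k=31))


class TestGeneKnn:
    def test_duplicate_gene_k1_copies_target_value(self):
        rng = np.random.default_rng(4)
        meas = rng.normal(10, 1, size=(30, 4))
        train = toy_matrix(np.hstack([meas, meas[:, [1]]]))
        split = GeneSplit(measured=train.gene_ids[:4],
                          unmeasured=[train.gene_ids[4]])
        target = ExpressionMatrix(
            values=rng.normal(10, 1, size=(3, 4)),
            sample_ids=["a", "b", "c"], gene_ids=split.measured,
            dataset_ids=["d"] * 3,
        )
        res = gene_knn_impute(target, train, split, KnnConfig(k=1))
        np.testing.assert_allclose(res.imputed[:, 0], target.values[:, 1],
                                   atol=1e-10)

    def test_hand_weighted_mean(self):
        # neighbor genes at train-distances 1 and 3, target values 6 and 2
        # -> (6 + 2/3) / (4/3) = 5
        train = toy_matrix([[0.0, 0.0, 0.0], [1.0, 3.0, 0.0]])
        split = GeneSplit(measured=["g0", "g1"], unmeasured=["g2"])
        target = ExpressionMatrix(values=[[6.0, 2.0]], sample_ids=["t"],
                                  gene_ids=["g0", "g1"], dataset_ids=["d"])
        res = gene_knn_impute(target, train, split, KnnConfig(k=2),
                              standardize=False)
        assert res.imputed[0, 0] == pytest.approx(5.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(31)
        for trial in range(5):
            train = make_matrix(25, 18, seed=300 + trial)
            targets = make_matrix(5, 18, seed=400 + trial)
            split = GeneSplit(measured=train.gene_ids[:11],
                              unmeasured=train.gene_ids[11:])
            k = int(rng.integers(1, 9))
            res = gene_knn_impute(targets, train, split, KnnConfig(k=k))
            oracle = brute_force_gene_knn(targets, train, split, k)
            np.testing.assert_allclose(res.imputed, oracle, atol=1e-10)

    def test_k_exceeding_measured_rejected(self, train_and_split):
        train, split = train_and_split
        target = make_matrix(1, 20, seed=0)
        with pytest.raises(DataError, match="exceeds"):
            gene_knn_impute(target, train, split, KnnConfig(k=13))


class TestLassoSolverProperties:
    def test_alpha_zero_matches_ols(self):
        """With alpha=0 on a full-rank toy the L1 solution is OLS."""
        rng = np.random.default_rng(12)
        X = rng.normal(size=(40, 8))
        beta_true = rng.normal(size=8)
        y = X @ beta_true + rng.normal(0, 0.1, 40)
        train = toy_matrix(
            np.hstack([X, y[:, None], rng.normal(size=(40, 1))])
        )
        split = GeneSplit(measured=train.gene_ids[:8],
                          unmeasured=train.gene_ids[8:])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = gene_lasso_fit(
                train, split,
                LassoConfig(alpha=0.0, max_iter=100000, tol=1e-12),
                standardize=False,
            )
        Xi = np.hstack([np.ones((40, 1)), X])
        coef_ols = np.linalg.solve(Xi.T @ Xi, Xi.T @ y)
        assert abs(models.intercepts[0] - coef_ols[0]) < 1e-6
        np.testing.assert_allclose(models.coefs[0], coef_ols[1:], atol=1e-6)

    def test_l1_norm_non_increasing_in_alpha(self, train_and_split):
        train, split = train_and_split
        target = make_matrix(1, 20, seed=17)
        norms = []
        for alpha in np.logspace(-3, 2, 10):
            res = sample_lasso_impute(
                target, train, split, LassoConfig(alpha=alpha, max_iter=50000)
            )
            norms.append(np.abs(res.diagnostics["betas"].to_numpy()).sum())
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))
        assert norms[-1] == 0.0  # complete shrinkage at large alpha

    def test_permutation_equivariance(self, train_and_split):
        """Permuting training-sample order leaves imputations unchanged."""
        train, split = train_and_split
        target = make_matrix(3, 20, seed=19)
        rng = np.random.default_rng(0)
        perm = rng.permutation(train.n_samples)
        shuffled = train.subset_samples([train.sample_ids[i] for i in perm])
        # coordinate descent must run to tight convergence for the fitted
        # optimum (and thus the imputation) to be order-independent
        tight = LassoConfig(alpha=0.05, tol=1e-14, max_iter=1000000)
        for method, kw in [
            ("sample-lasso", {"lasso_config": tight}),
            ("gene-lasso", {"lasso_config": tight}),
            ("sample-knn", {"k": 4}),
            ("gene-knn", {"k": 4}),
        ]:
            a = impute(method, target, train, split, **kw)
            b = impute(method, target, shuffled, split, **kw)
            np.testing.assert_allclose(a.imputed, b.imputed, atol=1e-10,
                                       err_msg=method)


class TestCrossScaleProperty:
    @pytest.mark.parametrize("scale", [0.5, 0.8, 1.25, 2.0])
    def test_sample_lasso_beats_sample_knn_under_affine_targets(self, scale):
        """Targets that are a*combo+b of training samples on the measured
        genes: the per-sample regression absorbs the affine distortion,
        plain neighbour averaging cannot."""
        from transpute.evaluate import nrmse_per_gene

        rng = np.random.default_rng(int(scale * 100))
        train = make_matrix(40, 60, seed=23)
        split = GeneSplit(measured=train.gene_ids[:40],
                          unmeasured=train.gene_ids[40:])
        W = rng.dirichlet(np.ones(3), size=8)  # 8 targets, 3-sample combos
        picks = rng.integers(0, 40, size=(8, 3))
        combo = np.stack([
            W[i] @ train.values[picks[i]] for i in range(8)
        ])
        b = 1.0
        target_full = ExpressionMatrix(
            values=scale * combo + b,
            sample_ids=[f"t{i}" for i in range(8)],
            gene_ids=train.gene_ids, dataset_ids=["dt"] * 8,
        )
        target = target_full.subset_genes(split.measured)
        truth = target_full.subset_genes(split.unmeasured)
        lasso = sample_lasso_impute(target, train, split,
                                    LassoConfig(alpha=1e-3, max_iter=50000))
        knn = sample_knn_impute(target, train, split, KnnConfig(k=5))
        med_lasso = float(np.nanmedian(nrmse_per_gene(truth, lasso)))
        med_knn = float(np.nanmedian(nrmse_per_gene(truth, knn)))
        assert med_lasso < med_knn


class TestTuning:
    def test_single_point_grid_returned(self, train_and_split):
        train, split = train_and_split
        validation = make_matrix(6, 20, seed=25)
        best, table = tune_hyperparameter(
            "sample-knn", train, validation, split, grid=[3]
        )
        assert best == 3
        assert len(table) == 1

    def test_two_point_grid_argmin_matches_hand_scoring(self, train_and_split):
        from transpute.evaluate import nrmse_per_gene

        train, split = train_and_split
        validation = make_matrix(5, 20, seed=26)
        best, table = tune_hyperparameter(
            "sample-knn", train, validation, split, grid=[1, 10]
        )
        truth = validation.subset_genes(split.unmeasured)
        scores = {}
        for k in (1, 10):
            res = sample_knn_impute(validation, train, split, KnnConfig(k=k))
            scores[k] = float(np.nanmedian(nrmse_per_gene(truth, res)))
        assert best == min(scores, key=scores.get)
        np.testing.assert_allclose(
            table["score"].to_numpy(), [scores[1], scores[10]], atol=1e-12
        )

    def test_empty_validation_rejected(self, train_and_split):
        train, split = train_and_split
        empty = train.subset_samples([])
        with pytest.raises(DataError):
            tune_hyperparameter("sample-knn", train, empty, split, grid=[1])
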