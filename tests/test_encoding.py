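import numpy as np
import pytest

from audenc.encoding import (
    DEFAULT_LAMBDA_GRID,
    EncodingSample,
    VoxelEncodingModel,
    build_encoding_dataset,
    fit_sample,
    lasso_fit,
    normalize_voxels,
    select_lambda,
    standardize_columns,
)
from audenc.metrics import pearson_columns
from audenc.stimulus import StimulusSpec


def soft_threshold(z, lam):
    """Independent closed-form LASSO solution for orthonormal designs."""
    return np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)


def orthonormal_design(m, c, seed):
    """D with D'D = m I (the scaling of the 1/(2m) objective)."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((m, c)))
    return q * np.sqrt(m)


class TestNormalizeVoxels:
    def test_hand_arithmetic_population_sd(self):
        Xn, missing = normalize_voxels(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(
            Xn[:, 0], [-np.sqrt(1.5), 0.0, np.sqrt(1.5)], atol=1e-12
        )
        # population-SD convention: SD exactly 1
        assert Xn[:, 0].std() == pytest.approx(1.0, abs=1e-12)
        assert not missing[0]

    def test_idempotent(self):
        X = np.random.default_rng(0).standard_normal((20, 3))
        once, _ = normalize_voxels(X)
        twice, _ = normalize_voxels(once)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_constant_column_flagged(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        Xn, missing = normalize_voxels(X)
        assert missing[0] and not missing[1]
        np.testing.assert_array_equal(Xn[:, 0], 0.0)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError):
            normalize_voxels(np.ones((1, 3)))


class TestLassoFit:
    def test_dead_zone_gives_exact_zero(self):
        rng = np.random.default_rng(1)
        D = rng.standard_normal((30, 5))
        x = rng.standard_normal(30)
        lam_max = np.max(np.abs(D.T @ x)) / 30
        alpha = lasso_fit(D, x, lam_max * 1.001)
        np.testing.assert_array_equal(alpha, np.zeros(5))

    def test_orthonormal_matches_soft_threshold(self):
        m, c = 40, 6
        D = orthonormal_design(m, c, seed=2)
        x = np.random.default_rng(3).standard_normal(m)
        for lam in (0.05, 0.1, 0.15):
            alpha = lasso_fit(D, x, lam)
            expected = soft_threshold(D.T @ x / m, lam)
            np.testing.assert_allclose(alpha, expected, atol=1e-6)

    def test_zero_penalty_matches_normal_equations(self):
        rng = np.random.default_rng(4)
        D = rng.standard_normal((50, 4))
        x = rng.standard_normal(50)
        ols = np.linalg.solve(D.T @ D, D.T @ x)  # independent oracle
        np.testing.assert_allclose(lasso_fit(D, x, 0.0), ols, atol=1e-6)

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            lasso_fit(np.array([[np.nan]]), np.array([1.0]), 0.1)

    def test_objective_never_worse_than_zero_vector(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            D = rng.standard_normal((20, 8))
            x = rng.standard_normal(20)
            lam = rng.uniform(0.01, 0.3)
            a = lasso_fit(D, x, lam)
            obj = lambda v: np.sum((x - D @ v) ** 2) / 40 + lam * np.abs(v).sum()
            assert obj(a) <= obj(np.zeros(8)) + 1e-10

    def test_sparsity_nonincreasing_along_grid(self):
        rng = np.random.default_rng(6)
        D = rng.standard_normal((30, 10))
        x = rng.standard_normal(30)
        nnz = [
            np.count_nonzero(lasso_fit(D, x, lam))
            for lam in (0.01, 0.05, 0.10, 0.15, 0.3)
        ]
        assert np.all(np.diff(nnz) <= 0)

    def test_noiseless_recovery_at_vanishing_penalty(self):
        """Orthonormalized design, no noise: alpha -> ground truth."""
        m, c = 60, 8
        D = orthonormal_design(m, c, seed=7)
        truth = np.zeros(c)
        truth[[1, 4, 6]] = [1.2, -0.8, 0.5]
        x = D @ truth
        alpha = lasso_fit(D, x, 1e-9)
        np.testing.assert_allclose(alpha, truth, rtol=1e-4)


class TestVoxelEncodingModel:
    def test_noiseless_voxel_near_perfect_pcc(self):
        rng = np.random.default_rng(8)
        D = rng.standard_normal((60, 10))
        w = np.zeros(10)
        w[[0, 3, 7]] = [1.0, -1.5, 0.7]
        X = (D @ w)[:, None]
        model = VoxelEncodingModel(alpha=0.001).fit(D, X)
        assert model.pcc(D, X)[0] > 0.999

    def test_null_voxels_have_near_zero_mean_pcc(self):
        """Monte-Carlo null: coefficients fit on noise, scored on fresh
        noise from the same (non-responsive) voxels, average PCC ~ 0."""
        rng = np.random.default_rng(9)
        D = rng.standard_normal((60, 10))
        X_train = rng.standard_normal((60, 200))  # 200 pure-noise voxels
        X_test = rng.standard_normal((60, 200))
        model = VoxelEncodingModel(alpha=0.1).fit(D, X_train)
        r = model.pcc(D, X_test)
        assert abs(np.nanmean(np.nan_to_num(r))) < 0.05

    def test_support_recovery_beats_random_subsets(self):
        """Jaccard overlap of fitted vs true support, k=5, SNR 5."""
        rng = np.random.default_rng(10)
        m, c, k = 60, 20, 5
        jac_fit, jac_rand = [], []
        for _ in range(50):
            D = rng.standard_normal((m, c))
            w = np.zeros(c)
            sup = rng.choice(c, k, replace=False)
            w[sup] = rng.uniform(0.5, 1.5, k) * rng.choice([-1, 1], k)
            sig = D @ w
            x = sig + rng.normal(0, np.std(sig) / 5, m)
            a = lasso_fit(standardize_columns(D)[0], (x - x.mean()) / x.std(), 0.1)
            est = set(np.flatnonzero(a))
            true = set(sup)
            jac_fit.append(len(est & true) / max(1, len(est | true)))
            rnd = set(rng.choice(c, k, replace=False))
            jac_rand.append(len(rnd & true) / len(rnd | true))
        assert np.mean(jac_fit) > np.mean(jac_rand)

    def test_missing_voxels_propagate(self):
        D = np.random.default_rng(11).standard_normal((20, 4))
        X = np.column_stack([np.ones(20), D @ [1.0, 0, 0, 0]])
        sample = EncodingSample(
            design=D, bold=normalize_voxels(X)[0], subject=0, excerpt=0,
            category=0, layer=1, missing=normalize_voxels(X)[1],
        )
        res = fit_sample(sample, 0.01)
        assert np.isnan(res.pcc[0])
        assert res.pcc[1] > 0.99


class TestDatasetConstruction:
    def _bold(self, spec, m, v=3):
        rng = np.random.default_rng(0)
        return {
            (s, e): rng.standard_normal((m, v))
            for s in range(spec.n_subjects)
            for e in range(spec.n_excerpts)
        }

    @pytest.mark.parametrize(
        "cats,excs,subs,expected", [(3, 7, 6, 126), (1, 1, 1, 1), (2, 3, 4, 24)]
    )
    def test_sample_counts(self, cats, excs, subs, expected):
        spec = StimulusSpec(
            sample_rate=100, tr=1.0, n_categories=cats,
            excerpts_per_category=excs, excerpt_duration=5.0, n_subjects=subs,
        )
        designs = [np.random.default_rng(e).standard_normal((5, 4)) for e in range(spec.n_excerpts)]
        samples = build_encoding_dataset(designs, self._bold(spec, 5), spec, layer=1)
        assert len(samples) == expected

    def test_missing_pair_reported(self):
        spec = StimulusSpec(
            sample_rate=100, tr=1.0, n_categories=1,
            excerpts_per_category=2, excerpt_duration=5.0, n_subjects=2,
        )
        bold = self._bold(spec, 5)
        del bold[(1, 0)]
        designs = [np.zeros((5, 4))] * 2
        with pytest.raises(ValueError, match=r"\(1, 0\)"):
            build_encoding_dataset(designs, bold, spec, layer=1)


def _synthetic_samples(n_samples, m, c, noise, seed, v=6):
    rng = np.random.default_rng(seed)
    w = np.zeros((v, c))
    for i in range(v):
        w[i, rng.choice(c, 3, replace=False)] = rng.uniform(0.5, 1.5, 3)
    samples = []
    for s in range(n_samples):
        D = rng.standard_normal((m, c))
        X = D @ w.T + rng.normal(0, noise, (m, v))
        Xn, miss = normalize_voxels(X)
        samples.append(
            EncodingSample(D, Xn, subject=s, excerpt=0, category=0, layer=1, missing=miss)
        )
    return samples


class TestLambdaSelection:
    def test_default_grid_is_the_published_one(self):
        assert DEFAULT_LAMBDA_GRID == (0.05, 0.10, 0.15)

    def test_single_candidate_grid(self):
        samples = _synthetic_samples(3, 20, 8, noise=0.5, seed=0)
        lam, record = select_lambda(samples, grid=[0.1])
        assert lam == 0.1
        assert len(record) == 1

    def test_needs_two_samples(self):
        samples = _synthetic_samples(1, 20, 8, noise=0.5, seed=0)
        with pytest.raises(ValueError):
            select_lambda(samples)

    def test_ties_break_toward_sparser_model(self):
        # two identical noiseless samples: every penalty predicts equally badly/well
        samples = _synthetic_samples(2, 20, 4, noise=0.0, seed=1)
        samples[1] = EncodingSample(
            samples[0].design, samples[0].bold, 1, 0, 0, 1, samples[0].missing
        )
        lam, record = select_lambda(samples, grid=[0.05, 0.10])
        scores = record["mean_heldout_pcc"]
        if abs(scores[0] - scores[1]) < 1e-12:
            assert lam == 0.10

    def test_regularization_not_harmful_under_heavy_noise(self):
        """Across seeds, the best grid penalty's held-out PCC is not worse
        than the unpenalized fit's (trend, not per-seed)."""
        diffs = []
        for seed in range(20):
            samples = _synthetic_samples(4, 20, 10, noise=3.0, seed=seed)
            zs = [standardize_columns(s.design)[0] for s in samples]
            held_scores = {lam: [] for lam in (0.0, 0.05, 0.10, 0.15)}
            for i in range(len(samples)):
                Dtr = np.concatenate([z for j, z in enumerate(zs) if j != i])
                Xtr = np.concatenate(
                    [s.bold for j, s in enumerate(samples) if j != i]
                )
                for lam in held_scores:
                    coef = lasso_fit(Dtr, Xtr, lam) if lam > 0 else np.linalg.lstsq(Dtr, Xtr, rcond=None)[0].T
                    pred = zs[i] @ np.atleast_2d(coef).T
                    held_scores[lam].append(
                        np.nanmean(pearson_columns(pred, samples[i].bold))
                    )
            best_grid = max(
                np.mean(held_scores[lam]) for lam in (0.05, 0.10, 0.15)
            )
            diffs.append(best_grid - np.mean(held_scores[0.0]))
        assert np.mean(diffs) > -0.02
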