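import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from normsig.errors import DegenerateSampleError, DomainError, ShapeError
from normsig.expr_io import ExpressionMatrix, FactorTable, median_center
from normsig.normalization import (
    GFSParams,
    gfs_transform,
    log_transform,
    normalize,
    quantile_apply,
    quantile_fit,
    sva_apply,
    sva_fit,
)
from normsig.synthetic import SyntheticSpec, generate_dataset


def _matrix(values, space="log"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        tuple(f"G{i}" for i in range(values.shape[0])),
        tuple(f"S{j}" for j in range(values.shape[1])),
        space,
    )


class TestLogTransform:
    def test_definition(self):
        m = _matrix([[np.e], [1.0]], "raw")
        out = log_transform(m)
        np.testing.assert_allclose(out.values[:, 0], [1.0, 0.0], atol=1e-15)
        assert out.value_space == "log"

    def test_nonpositive_requires_offset(self):
        m = _matrix([[0.0], [2.0]], "raw")
        with pytest.raises(DomainError):
            log_transform(m)
        out = log_transform(m, offset=1.0)
        np.testing.assert_allclose(out.values[:, 0], [0.0, np.log(3.0)])


class TestQuantile:
    def test_reference_is_mean_of_sorted_columns(self):
        m = _matrix([[1, 2], [2, 4], [3, 6]])
        ref = quantile_fit(m)
        np.testing.assert_allclose(ref.reference_quantiles, [1.5, 3.0, 4.5])

    def test_fit_on_self_apply(self):
        m = _matrix([[1, 6], [2, 4], [3, 2]])
        out = quantile_apply(m, quantile_fit(m))
        np.testing.assert_allclose(out.values[:, 0], [1.5, 3.0, 4.5])
        np.testing.assert_allclose(out.values[:, 1], [4.5, 3.0, 1.5])

    def test_all_columns_identical_sorted_after_apply(self, rng):
        m = _matrix(rng.normal(size=(40, 6)))
        out = quantile_apply(m, quantile_fit(m))
        sorted_cols = np.sort(out.values, axis=0)
        for j in range(1, 6):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])

    def test_idempotent(self, rng):
        m = _matrix(rng.normal(size=(30, 5)))
        once = quantile_apply(m, quantile_fit(m))
        twice = quantile_apply(once, quantile_fit(once))
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_rank_invariance_of_frozen_apply(self, rng):
        train = _matrix(rng.normal(size=(30, 5)))
        ref = quantile_fit(train)
        held = _matrix(rng.normal(size=(30, 2)))
        distorted = held.with_values(np.exp(held.values * 0.5) + 3.0, "log")
        a = quantile_apply(held, ref)
        b = quantile_apply(distorted, ref)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_ties_get_mean_of_tied_reference_positions(self):
        m = _matrix([[1.0], [1.0], [5.0]])
        ref = quantile_fit(_matrix([[10.0], [20.0], [30.0]]))
        out = quantile_apply(m, ref)
        np.testing.assert_allclose(out.values[:, 0], [15.0, 15.0, 30.0])

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            quantile_apply(_matrix([[1], [2]]), quantile_fit(_matrix([[1], [2], [3]])))


class TestGFS:
    def test_top_fraction_scores_one_bottom_scores_zero(self, rng):
        values = rng.permutation(100).astype(float).reshape(-1, 1)
        m = _matrix(values)
        out = gfs_transform(m, GFSParams(0.05, 0.15))
        order = np.argsort(-values[:, 0])
        scores = out.values[order, 0]
        assert (scores[:5] == 1.0).all()  # top 5 = theta1 * 100
        assert (scores[-85:] == 0.0).all()  # ranks 16..100
        assert scores[0] == 1.0

    def test_midway_gene_scores_half(self):
        values = np.arange(100, 0, -1, dtype=float).reshape(-1, 1)  # rank = index+1
        out = gfs_transform(_matrix(values), GFSParams(0.05, 0.15))
        # gene with rank 10 is midway between cutoffs q1=5 and q2=15
        assert out.values[9, 0] == pytest.approx(0.5)

    def test_bounds_and_fractions(self, rng):
        m = _matrix(rng.normal(size=(400, 7)))
        out = gfs_transform(m, GFSParams(0.05, 0.15))
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0
        ones = (out.values == 1.0).sum(axis=0)
        zeros = (out.values == 0.0).sum(axis=0)
        assert np.all(np.abs(ones - 0.05 * 400) <= 1)
        assert np.all(zeros >= (1 - 0.15) * 400 - 1)

    @settings(deadline=None, max_examples=25)
    @given(
        scale=st.floats(0.1, 10.0, allow_nan=False),
        shift=st.floats(-5.0, 5.0, allow_nan=False),
    )
    def test_invariant_to_increasing_affine_transform(self, scale, shift):
        rng = np.random.default_rng(0)
        m = _matrix(rng.normal(size=(60, 3)))
        out = gfs_transform(m)
        distorted = gfs_transform(m.with_values(m.values * scale + shift, "log"))
        np.testing.assert_array_equal(out.values, distorted.values)

    def test_invariant_to_monotone_nonlinear_transform(self, rng):
        m = _matrix(rng.normal(size=(80, 4)))
        out = gfs_transform(m)
        distorted = gfs_transform(m.with_values(np.exp(m.values), "log"))
        np.testing.assert_array_equal(out.values, distorted.values)

    def test_constant_sample_rejected_by_name(self):
        values = np.column_stack([np.arange(10.0), np.full(10, 3.0)])
        with pytest.raises(DegenerateSampleError, match="S1"):
            gfs_transform(_matrix(values))

    def test_invalid_thetas(self):
        with pytest.raises(DomainError):
            GFSParams(theta1=0.2, theta2=0.1)


class TestSVA:
    @staticmethod
    def _batch_cohort(seed=0, strength=1.5):
        spec = SyntheticSpec(
            seed=seed,
            confounder_strength=strength,
            confounder_rho=0.0,
            n_minor_components=0,
            artifact_rate=0.0,
            scale_sd=0.0,
            noise_sd=1.0,
        )
        matrix, factors, truth = generate_dataset(spec)
        return median_center(log_transform(matrix)), factors, truth

    def test_no_structure_gives_k_zero_identity(self):
        spec = SyntheticSpec(
            seed=1,
            n_genes=300,
            confounder_strength=0.0,
            minor_strength=0.0,
            n_minor_components=0,
            artifact_rate=0.0,
            scale_sd=0.0,
            covariates=(),
        )
        matrix, factors, _ = generate_dataset(spec)
        # log only — per-sample median centering would itself inject a weak
        # rank-1 component (shared median-estimation error) at this gene count
        logged = log_transform(matrix)
        model = sva_fit(logged, factors, seed=3)
        assert model.k == 0
        out = sva_apply(logged, model)
        np.testing.assert_array_equal(out.values, logged.values)

    def test_surrogate_recovers_planted_batch(self):
        logged, factors, truth = self._batch_cohort(seed=2)
        model = sva_fit(logged, factors, seed=5)
        assert model.k >= 1
        corr = np.corrcoef(model.surrogate_vectors[:, 0], truth.confounder_scores)[0, 1]
        assert abs(corr) >= 0.9

    def test_surrogates_orthogonal(self):
        logged, factors, _ = self._batch_cohort(seed=3)
        model = sva_fit(logged, factors, k=3, seed=5)
        gram = model.surrogate_vectors.T @ model.surrogate_vectors
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-10)

    def test_class_effect_preserved_after_correction(self):
        logged, factors, truth = self._batch_cohort(seed=4)
        model = sva_fit(logged, factors, seed=5)
        corrected = sva_apply(logged, model)
        labels = np.array(factors.class_labels)
        rows = [logged.gene_ids.index(g) for g in truth.signal_genes]
        pre = (
            logged.values[rows][:, labels == "subject"].mean(axis=1)
            - logged.values[rows][:, labels == "control"].mean(axis=1)
        )
        post = (
            corrected.values[rows][:, labels == "subject"].mean(axis=1)
            - corrected.values[rows][:, labels == "control"].mean(axis=1)
        )
        assert np.abs(post - pre).max() / np.abs(pre).max() <= 0.15

    def test_frozen_apply_on_held_out_samples(self):
        logged, factors, _ = self._batch_cohort(seed=6)
        train = logged.subset_samples(logged.sample_ids[:60])
        held = logged.subset_samples(logged.sample_ids[60:])
        model = sva_fit(train, factors.align_to(train.sample_ids), seed=5)
        out = sva_apply(held, model)
        assert out.values.shape == held.values.shape
        # held-out correction does not depend on the rest of the batch
        single = sva_apply(held.subset_samples(held.sample_ids[:1]), model)
        np.testing.assert_allclose(single.values[:, 0], out.values[:, 0], atol=1e-12)


class TestNormalizeDispatch:
    def test_none_is_passthrough(self, rng):
        m = _matrix(rng.normal(size=(20, 6)))
        train, test = normalize(m, "none", test=m)
        assert train is m and test is m

    def test_sva_requires_factors(self, rng):
        m = _matrix(rng.normal(size=(20, 6)))
        with pytest.raises(DomainError):
            normalize(m, "sva")
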