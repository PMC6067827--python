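import numpy as np
import pytest

from normsig.errors import DesignError, DomainError
from normsig.expr_io import ExpressionMatrix
from normsig.validation import (
    _soft_threshold,
    _stratified_even_split,
    cluster_signature,
    cv_no_selection,
    cv_with_selection_and_null,
    predict_nsc,
    stability_index,
    train_nsc,
    CVReport,
)


def _matrix(values, space="log"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        tuple(f"G{i}" for i in range(values.shape[0])),
        tuple(f"S{j}" for j in range(values.shape[1])),
        space,
    )


def _blobs(rng, n_genes=12, n_per_class=10, sep=4.0, noise=0.5):
    a = rng.normal(0.0, noise, size=(n_genes, n_per_class))
    b = rng.normal(sep, noise, size=(n_genes, n_per_class))
    m = _matrix(np.hstack([a, b]))
    labels = ["a"] * n_per_class + ["b"] * n_per_class
    return m, labels


class TestNSC:
    def test_soft_threshold_arithmetic(self):
        assert _soft_threshold(np.array(2.5), 1.0) == pytest.approx(1.5)
        assert _soft_threshold(np.array(-2.5), 1.0) == pytest.approx(-1.5)
        assert _soft_threshold(np.array(0.5), 1.0) == 0.0

    def test_perfectly_separated_toy_data(self, rng):
        m, labels = _blobs(rng, n_genes=2)
        model = train_nsc(m, labels, delta=0.0)
        assert predict_nsc(model, m) == tuple(labels)

    def test_delta_zero_deviations_unshrunken(self, rng):
        m, labels = _blobs(rng)
        model = train_nsc(m, labels, delta=0.0)
        np.testing.assert_array_equal(model.shrunken_deviations, model.deviations)

    def test_full_shrinkage_falls_back_to_priors(self, rng):
        m, labels = _blobs(rng, n_per_class=6)
        big = float(np.abs(train_nsc(m, labels, delta=0.0).deviations).max()) + 1.0
        model = train_nsc(m, labels, delta=big)
        assert model.n_active_genes == 0
        # with all genes shrunk out, the priors decide every prediction
        pred = predict_nsc(model, m)
        assert len(set(pred)) == 1

    def test_tie_break_toward_first_declared_class(self):
        # sample exactly between both centroids
        values = np.array([[0.0, 0.0, 2.0, 2.0]])
        m = _matrix(values)
        model = train_nsc(m, ["x", "x", "y", "y"], delta=0.0, priors="uniform")
        midpoint = _matrix(np.array([[1.0]]))
        assert predict_nsc(model, midpoint) == ("x",)

    def test_single_class_rejected(self, rng):
        m, _ = _blobs(rng)
        with pytest.raises(DesignError):
            train_nsc(m, ["a"] * m.n_samples, delta=0.0)

    def test_training_accuracy_optimistic(self, rng):
        # train accuracy >= held-out accuracy on average over seeds
        gaps = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            m, labels = _blobs(r, n_genes=30, n_per_class=10, sep=1.0, noise=1.0)
            train = m.subset_samples(m.sample_ids[:5] + m.sample_ids[10:15])
            test = m.subset_samples(m.sample_ids[5:10] + m.sample_ids[15:20])
            lab_train = ["a"] * 5 + ["b"] * 5
            model = train_nsc(train, lab_train, delta=0.0)
            acc_train = np.mean(np.array(predict_nsc(model, train)) == lab_train)
            acc_test = np.mean(np.array(predict_nsc(model, test)) == lab_train)
            gaps.append(acc_train - acc_test)
        assert np.mean(gaps) >= 0.0


class TestSplitting:
    def test_stratified_even_split_counts(self):
        codes = np.array([0] * 56 + [1] * 28)
        rng = np.random.default_rng(0)
        for _ in range(20):
            train, val = _stratified_even_split(codes, rng)
            assert (codes[train] == 0).sum() == 28
            assert (codes[train] == 1).sum() == 14
            assert sorted(np.concatenate([train, val])) == list(range(84))


class TestCVNoSelection:
    def test_single_split_deterministic(self, default_logged):
        logged, factors, _ = default_logged
        a = cv_no_selection(logged, factors, method="gfs", n_splits=1, seed=3)
        b = cv_no_selection(logged, factors, method="gfs", n_splits=1, seed=3)
        assert a.accuracy_observed[0] == b.accuracy_observed[0]

    def test_strong_signal_gfs_accuracy(self, default_logged):
        logged, factors, _ = default_logged
        report = cv_no_selection(logged, factors, method="gfs", n_splits=25, seed=7)
        assert report.median_accuracy >= 0.85


class TestCVWithSelection:
    def test_report_structure_and_empirical_p(self, default_logged):
        logged, factors, _ = default_logged
        report = cv_with_selection_and_null(
            logged, factors, method="gfs", threshold=0.01, n_splits=15, seed=5
        )
        assert report.accuracy_random is not None
        assert 0.0 <= report.empirical_p <= 1.0
        valid = ~np.isnan(report.accuracy_observed)
        expected = np.mean(
            report.accuracy_random[valid] > report.accuracy_observed[valid]
        )
        assert report.empirical_p == pytest.approx(expected)

    def test_threshold_domain(self, default_logged):
        logged, factors, _ = default_logged
        with pytest.raises(DomainError):
            cv_with_selection_and_null(logged, factors, threshold=1.5, n_splits=2, seed=0)

    def test_random_arm_indistinguishable_on_null_data(self):
        from conftest import pure_null_spec
        from normsig.expr_io import median_center
        from normsig.normalization import log_transform
        from normsig.synthetic import generate_dataset
        from scipy.stats import mannwhitneyu

        matrix, factors, _ = generate_dataset(pure_null_spec(3, n_genes=500))
        logged = median_center(log_transform(matrix))
        report = cv_with_selection_and_null(
            logged, factors, method="none", threshold=0.2, n_splits=40, seed=8
        )
        valid = ~np.isnan(report.accuracy_observed)
        if valid.sum() >= 10:
            p = mannwhitneyu(
                report.accuracy_observed[valid], report.accuracy_random[valid]
            ).pvalue
            assert p > 0.05


class TestStabilityIndex:
    def _report(self, sigs):
        n = len(sigs)
        return CVReport(
            method="gfs",
            accuracy_observed=np.ones(n),
            accuracy_random=np.ones(n),
            signature_sizes=np.array([len(s) for s in sigs]),
            split_signatures=tuple(tuple(s) for s in sigs),
            n_empty_signatures=0,
            empirical_p=0.0,
            seed=0,
        )

    def test_identical_signatures_index_one(self):
        freq, index = stability_index(self._report([("A", "B")] * 5))
        assert index == 1.0
        assert freq == {"A": 1.0, "B": 1.0}

    def test_disjoint_signatures_index_zero(self):
        freq, index = stability_index(
            self._report([("A",), ("B",), ("C",)])
        )
        assert index == 0.0

    def test_signal_genes_selected_more_often(self, default_logged):
        logged, factors, truth = default_logged
        report = cv_with_selection_and_null(
            logged, factors, method="gfs", threshold=0.05, n_splits=20, seed=2
        )
        freq, _ = stability_index(report)
        signal_freq = [freq.get(g, 0.0) for g in truth.signal_genes]
        other = [f for g, f in freq.items() if g not in truth.signal_genes]
        assert np.mean(signal_freq) > (np.median(other) if other else 0.0)


class TestClusterSignature:
    def test_two_blobs_recovered(self, rng):
        m, labels = _blobs(rng, n_genes=12, n_per_class=10, sep=5.0)
        result = cluster_signature(m, m.gene_ids, linkage="ward", true_labels=labels)
        assert result["cut_accuracy"] >= 0.95

    def test_ward_and_average_agree_on_separated_blobs(self, rng):
        m, labels = _blobs(rng, n_genes=12, n_per_class=10, sep=5.0)
        for linkage in ("ward", "average"):
            result = cluster_signature(m, m.gene_ids, linkage=linkage, true_labels=labels)
            assert result["cut_accuracy"] >= 0.95

    def test_duplicate_samples_merge_at_zero_height(self):
        values = np.column_stack([[1.0, 2.0], [1.0, 2.0], [5.0, 6.0]])
        m = _matrix(values)
        result = cluster_signature(m, m.gene_ids)
        assert result["linkage_matrix"][0, 2] == 0.0

    def test_newick_export(self, rng):
        from normsig.validation import linkage_to_newick

        m, _ = _blobs(rng, n_genes=5, n_per_class=3)
        result = cluster_signature(m, m.gene_ids)
        nwk = linkage_to_newick(result["linkage_matrix"], list(result["sample_ids"]))
        assert nwk.endswith(";")
        for sid in result["sample_ids"]:
            assert sid in nwk
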