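"""Shrunken-centroid classification and signature validation by repeated splitting.

The classifier is the nearest shrunken centroid (PAM-style): per-class
centroid deviations from the overall centroid, standardized by the pooled
within-class standard deviation (stabilized by ``s0`` = median pooled sd),
are soft-thresholded by a shrinkage amount ``delta``; prediction minimizes
the standardized distance to the shrunken centroids minus ``2 log`` prior.

Two cross-validation experiments repeat stratified 50/50 sample splits:

* ``cv_no_selection`` trains on all genes — a direct read-out of how much
  noise a normalization regime leaves in the data.
* ``cv_with_selection_and_null`` selects a signature on the training half
  only (F-test/BH at a threshold), evaluates it, and in the same split
  evaluates a size-matched uniformly random gene set.  The empirical p-value
  is the fraction of splits where the random signature strictly beats the
  observed one — a signature that fails this test is not demonstrably better
  than noise, however accurate its classifier looks.

Quantile and SVA normalization are refitted inside every split on the
training half only and applied frozen to the validation half.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from normsig.errors import (
    AlignmentError,
    DesignError,
    DomainError,
    EmptyResultError,
)
from normsig.expr_io import ExpressionMatrix, FactorTable
from normsig.normalization import GFSParams, Method, normalize
from normsig.selection import f_test_per_gene, select_signature, Signature

Delta = float | Literal["auto"]


# ---------------------------------------------------------------------------
# Nearest shrunken centroid


@dataclass(frozen=True)
class NSCModel:
    """Fitted shrunken-centroid classifier.

    ``deviations`` are the raw standardized centroid deviations d_ik; the
    shrunken deviations after soft-thresholding by ``delta`` are in
    ``shrunken_deviations``.  At ``delta=0`` the two coincide.  ``priors``
    follow the declared class order.
    """

    class_levels: tuple[str, ...]
    overall_centroid: np.ndarray  # genes
    class_centroids: np.ndarray  # genes x K
    pooled_sd: np.ndarray  # genes
    s0: float
    delta: float
    deviations: np.ndarray  # genes x K
    shrunken_deviations: np.ndarray  # genes x K
    priors: np.ndarray  # K
    gene_ids: tuple[str, ...]

    @property
    def n_active_genes(self) -> int:
        """Genes with a non-zero shrunken deviation in at least one class."""
        return int(np.any(self.shrunken_deviations != 0.0, axis=1).sum())


def _soft_threshold(d: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)


def _nsc_components(values: np.ndarray, codes: np.ndarray, n_classes: int):
    """Centroids, pooled within-class sd (+s0), standardized deviations."""
    n_genes, n_total = values.shape
    counts = np.bincount(codes, minlength=n_classes)
    overall = values.mean(axis=1)
    centroids = np.empty((n_genes, n_classes))
    within_ss = np.zeros(n_genes)
    for k in range(n_classes):
        cols = codes == k
        grp = values[:, cols]
        centroids[:, k] = grp.mean(axis=1)
        within_ss += ((grp - centroids[:, [k]]) ** 2).sum(axis=1)
    pooled_sd = np.sqrt(within_ss / max(n_total - n_classes, 1))
    s0 = float(np.median(pooled_sd))
    if s0 == 0.0:
        # More than half the genes are constant within class (possible after
        # heavy top-coding); fall back to the mean positive sd so the
        # standardization stays finite.
        positive = pooled_sd[pooled_sd > 0]
        s0 = float(positive.mean()) if positive.size else 1.0
    m_k = np.sqrt(1.0 / counts - 1.0 / n_total)
    denom = np.outer(pooled_sd + s0, m_k)
    with np.errstate(divide="ignore", invalid="ignore"):
        deviations = np.where(denom > 0, (centroids - overall[:, None]) / denom, 0.0)
    return overall, centroids, pooled_sd, s0, m_k, deviations, counts


def _discriminant_scores(
    values: np.ndarray,
    overall: np.ndarray,
    pooled_sd: np.ndarray,
    s0: float,
    m_k: np.ndarray,
    deviations: np.ndarray,
    priors: np.ndarray,
    deltas: np.ndarray,
) -> np.ndarray:
    """Discriminant scores for a batch of deltas at once.

    Returns an array (n_deltas, n_samples, K); lower is better.
    """
    scale = pooled_sd + s0
    z = values / scale[:, None]  # genes x samples
    # Shrunken standardized centroids for every delta: (D, genes, K)
    shrunk = _soft_threshold(deviations[None, :, :], deltas[:, None, None])
    cent = (overall[:, None] / scale[:, None])[None, :, :] + shrunk * m_k[None, None, :]
    z_sq = (z**2).sum(axis=0)  # samples
    cross = np.einsum("gs,dgk->dsk", z, cent)
    cent_sq = (cent**2).sum(axis=1)  # D x K
    dist = z_sq[None, :, None] - 2.0 * cross + cent_sq[:, None, :]
    return dist - 2.0 * np.log(priors)[None, None, :]


def train_nsc(
    train: ExpressionMatrix,
    labels: Sequence[str],
    delta: Delta = "auto",
    priors: Literal["empirical", "uniform"] = "empirical",
    n_inner_folds: int = 5,
    n_grid: int = 30,
    seed: int = 0,
) -> NSCModel:
    """Fit a shrunken-centroid classifier.

    ``delta='auto'`` picks the shrinkage by stratified inner cross-validation
    over an ``n_grid``-point grid from 0 to the largest absolute deviation,
    preferring the largest delta among ties (most parsimonious model).
    """
    labels = np.asarray([str(x) for x in labels])
    if labels.size != train.n_samples:
        raise DesignError("one label per training sample required")
    levels = tuple(dict.fromkeys(labels))  # declared order = first appearance
    if len(levels) < 2:
        raise DesignError("training data contain a single class")
    codes = np.array([levels.index(x) for x in labels])
    counts = np.bincount(codes, minlength=len(levels))
    if (counts < 2).any():
        raise DesignError("each class needs at least 2 training samples")

    if delta == "auto":
        delta_value = _select_delta_inner_cv(
            train.values, codes, len(levels), priors, n_inner_folds, n_grid, seed
        )
    else:
        delta_value = float(delta)
        if delta_value < 0:
            raise DomainError("delta must be non-negative")

    overall, centroids, pooled_sd, s0, m_k, deviations, counts = _nsc_components(
        train.values, codes, len(levels)
    )
    prior_vec = (
        counts / counts.sum() if priors == "empirical" else np.full(len(levels), 1.0 / len(levels))
    )
    return NSCModel(
        class_levels=levels,
        overall_centroid=overall,
        class_centroids=centroids,
        pooled_sd=pooled_sd,
        s0=s0,
        delta=delta_value,
        deviations=deviations,
        shrunken_deviations=_soft_threshold(deviations, delta_value),
        priors=prior_vec,
        gene_ids=train.gene_ids,
    )


def _stratified_folds(
    codes: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Index sets of stratified folds (each class spread across folds)."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for k in np.unique(codes):
        idx = rng.permutation(np.flatnonzero(codes == k))
        for i, j in enumerate(idx):
            folds[i % n_folds].append(int(j))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _select_delta_inner_cv(
    values: np.ndarray,
    codes: np.ndarray,
    n_classes: int,
    priors: str,
    n_folds: int,
    n_grid: int,
    seed: int,
) -> float:
    *_, deviations, _ = _nsc_components(values, codes, n_classes)
    grid = np.linspace(0.0, float(np.abs(deviations).max()), n_grid)
    rng = np.random.default_rng(seed)
    n_folds = min(n_folds, int(np.bincount(codes).min()))
    if n_folds < 2:
        return 0.0
    folds = _stratified_folds(codes, n_folds, rng)
    correct = np.zeros(n_grid)
    total = 0
    for held in folds:
        mask = np.ones(values.shape[1], dtype=bool)
        mask[held] = False
        if np.unique(codes[mask]).size < n_classes:
            continue
        overall, _, pooled_sd, s0, m_k, dev, counts = _nsc_components(
            values[:, mask], codes[mask], n_classes
        )
        prior_vec = (
            counts / counts.sum()
            if priors == "empirical"
            else np.full(n_classes, 1.0 / n_classes)
        )
        scores = _discriminant_scores(
            values[:, held], overall, pooled_sd, s0, m_k, dev, prior_vec, grid
        )
        pred = np.argmin(scores, axis=2)  # D x n_held
        correct += (pred == codes[held][None, :]).sum(axis=1)
        total += held.size
    if total == 0:
        return 0.0
    best_acc = correct.max()
    # Largest delta among ties: the most shrunken model that is as accurate.
    return float(grid[np.flatnonzero(correct == best_acc)[-1]])


def predict_nsc(model: NSCModel, m: ExpressionMatrix) -> tuple[str, ...]:
    """Minimal-discriminant-score class per sample.

    Ties are broken toward the first class level in declared order.
    """
    if m.gene_ids != model.gene_ids:
        raise AlignmentError("gene set differs from the training gene set")
    m_k = _model_mk(model)
    scores = _discriminant_scores(
        m.values,
        model.overall_centroid,
        model.pooled_sd,
        model.s0,
        m_k,
        model.shrunken_deviations,
        model.priors,
        np.array([0.0]),  # deviations already shrunken; no further threshold
    )[0]
    pred = np.argmin(scores, axis=1)  # argmin takes the first index on ties
    return tuple(model.class_levels[k] for k in pred)


def _model_mk(model: NSCModel) -> np.ndarray:
    # Recover m_k from the stored deviations-to-centroid relation:
    # centroid_k - overall = m_k * (sd + s0) * d_k; solve on any gene with d != 0.
    K = len(model.class_levels)
    m_k = np.empty(K)
    scale = model.pooled_sd + model.s0
    diff = model.class_centroids - model.overall_centroid[:, None]
    for k in range(K):
        nz = np.flatnonzero(model.deviations[:, k] != 0)
        if nz.size:
            g = nz[0]
            m_k[k] = diff[g, k] / (scale[g] * model.deviations[g, k])
        else:
            m_k[k] = 1.0
    return m_k


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass(frozen=True)
class CVReport:
    """Per-split accuracies and aggregates for one normalization regime.

    ``accuracy_observed`` is NaN for splits whose training-half selection
    produced an empty signature (those splits are excluded from medians and
    from the empirical p, and counted in ``n_empty_signatures``).
    """

    method: str
    accuracy_observed: np.ndarray
    accuracy_random: np.ndarray | None
    signature_sizes: np.ndarray | None
    split_signatures: tuple[tuple[str, ...], ...] | None
    n_empty_signatures: int
    empirical_p: float | None
    seed: int

    @property
    def n_splits(self) -> int:
        return self.accuracy_observed.size

    @property
    def median_accuracy(self) -> float:
        valid = self.accuracy_observed[~np.isnan(self.accuracy_observed)]
        return float(np.median(valid)) if valid.size else float("nan")

    @property
    def iqr_accuracy(self) -> tuple[float, float]:
        valid = self.accuracy_observed[~np.isnan(self.accuracy_observed)]
        if not valid.size:
            return (float("nan"), float("nan"))
        lo, hi = np.quantile(valid, [0.25, 0.75])
        return (float(lo), float(hi))

    @property
    def median_accuracy_random(self) -> float | None:
        if self.accuracy_random is None:
            return None
        valid = self.accuracy_random[~np.isnan(self.accuracy_random)]
        return float(np.median(valid)) if valid.size else float("nan")


def _stratified_even_split(
    codes: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split sample indices 50/50 within each class (round(n_c/2) to training)."""
    train_idx: list[int] = []
    val_idx: list[int] = []
    for k in np.unique(codes):
        idx = rng.permutation(np.flatnonzero(codes == k))
        n_train = int(round(idx.size / 2))
        train_idx.extend(idx[:n_train].tolist())
        val_idx.extend(idx[n_train:].tolist())
    return np.sort(np.array(train_idx)), np.sort(np.array(val_idx))


def _split_and_normalize(
    m: ExpressionMatrix,
    factors: FactorTable,
    method: Method,
    rng_split: np.random.Generator,
    sva_seed: int,
    gfs_params: GFSParams | None,
    k,
):
    levels = factors.class_levels
    codes = np.array([levels.index(c) for c in factors.class_labels])
    train_idx, val_idx = _stratified_even_split(codes, rng_split)
    train_ids = [m.sample_ids[i] for i in train_idx]
    val_ids = [m.sample_ids[i] for i in val_idx]
    train = m.subset_samples(train_ids)
    val = m.subset_samples(val_ids)
    train_norm, val_norm = normalize(
        train,
        method,
        factors=factors.align_to(train_ids),
        test=val,
        gfs_params=gfs_params,
        k=k,
        seed=sva_seed,
    )
    train_labels = [factors.class_labels[i] for i in train_idx]
    val_labels = [factors.class_labels[i] for i in val_idx]
    return train_norm, val_norm, train_labels, val_labels


def _check_cv_inputs(m: ExpressionMatrix, factors: FactorTable, n_splits: int) -> FactorTable:
    if n_splits < 1:
        raise DomainError("n_splits must be >= 1")
    factors = factors.align_to(m.sample_ids)
    counts = np.bincount(
        [factors.class_levels.index(c) for c in factors.class_labels], minlength=2
    )
    if (counts < 4).any():
        raise DesignError("need >= 4 samples per class for 50/50 stratified splitting")
    return factors


def cv_no_selection(
    m: ExpressionMatrix,
    factors: FactorTable,
    method: Method = "none",
    n_splits: int = 1000,
    seed: int = 0,
    delta: Delta = "auto",
    gfs_params: GFSParams | None = None,
    sva_k="auto",
) -> CVReport:
    """Repeated stratified 50/50 splits, all genes used as features.

    ``m`` should be the log-scale (median-centered) matrix; for quantile and
    SVA the normalization is refitted inside every split on the training half
    and applied frozen to the validation half.
    """
    factors = _check_cv_inputs(m, factors, n_splits)
    ss = np.random.SeedSequence(seed).spawn(3)
    rng_split = np.random.default_rng(ss[0])
    rng_delta = np.random.default_rng(ss[1])
    sva_seeds = np.random.default_rng(ss[2]).integers(0, 2**31 - 1, size=n_splits)

    acc = np.empty(n_splits)
    for i in range(n_splits):
        train, val, train_labels, val_labels = _split_and_normalize(
            m, factors, method, rng_split, int(sva_seeds[i]), gfs_params, sva_k
        )
        model = train_nsc(
            train, train_labels, delta=delta, seed=int(rng_delta.integers(2**31 - 1))
        )
        pred = predict_nsc(model, val)
        acc[i] = float(np.mean([p == t for p, t in zip(pred, val_labels)]))
    return CVReport(
        method=method,
        accuracy_observed=acc,
        accuracy_random=None,
        signature_sizes=None,
        split_signatures=None,
        n_empty_signatures=0,
        empirical_p=None,
        seed=seed,
    )


def cv_with_selection_and_null(
    m: ExpressionMatrix,
    factors: FactorTable,
    method: Method = "none",
    threshold: float = 0.01,
    n_splits: int = 1000,
    seed: int = 0,
    delta: Delta = "auto",
    gfs_params: GFSParams | None = None,
    sva_k="auto",
) -> CVReport:
    """Splits with training-half feature selection plus a size-matched random arm.

    Per split: select a signature on the training half (F-test/BH at
    ``threshold``), train/evaluate the observed classifier on the signature;
    draw a uniformly random gene set of equal size from the full gene
    universe and train/evaluate it identically.  The empirical p-value is the
    fraction of non-empty splits where the random accuracy strictly exceeds
    the observed one (ties favour the observed arm).
    """
    if not 0.0 < threshold < 1.0:
        raise DomainError(f"threshold must be in (0,1), got {threshold}")
    factors = _check_cv_inputs(m, factors, n_splits)
    ss = np.random.SeedSequence(seed).spawn(4)
    rng_split = np.random.default_rng(ss[0])
    rng_delta = np.random.default_rng(ss[1])
    rng_random = np.random.default_rng(ss[2])  # independent random-signature stream
    sva_seeds = np.random.default_rng(ss[3]).integers(0, 2**31 - 1, size=n_splits)

    acc_obs = np.full(n_splits, np.nan)
    acc_rand = np.full(n_splits, np.nan)
    sizes = np.zeros(n_splits, dtype=int)
    split_sigs: list[tuple[str, ...]] = []
    gene_array = np.array(m.gene_ids)
    for i in range(n_splits):
        train, val, train_labels, val_labels = _split_and_normalize(
            m, factors, method, rng_split, int(sva_seeds[i]), gfs_params, sva_k
        )
        stats_ = f_test_per_gene(train, train_labels)
        sig = select_signature(stats_, threshold, normalization=method)
        sizes[i] = sig.size
        split_sigs.append(sig.gene_ids)
        # Keep the random stream aligned across splits regardless of emptiness.
        random_genes = tuple(
            gene_array[rng_random.choice(len(gene_array), size=max(sig.size, 1), replace=False)]
        )
        delta_seed = int(rng_delta.integers(2**31 - 1))
        if sig.is_empty:
            continue
        obs_model = train_nsc(
            train.subset_genes(sig.gene_ids), train_labels, delta=delta, seed=delta_seed
        )
        pred = predict_nsc(obs_model, val.subset_genes(sig.gene_ids))
        acc_obs[i] = float(np.mean([p == t for p, t in zip(pred, val_labels)]))
        rand_model = train_nsc(
            train.subset_genes(random_genes), train_labels, delta=delta, seed=delta_seed
        )
        pred_r = predict_nsc(rand_model, val.subset_genes(random_genes))
        acc_rand[i] = float(np.mean([p == t for p, t in zip(pred_r, val_labels)]))

    valid = ~np.isnan(acc_obs)
    # All splits empty: there is no evidence the selection beats random, so
    # the empirical p is reported at its least favourable value.
    empirical_p = (
        float(np.mean(acc_rand[valid] > acc_obs[valid])) if valid.any() else 1.0
    )
    return CVReport(
        method=method,
        accuracy_observed=acc_obs,
        accuracy_random=acc_rand,
        signature_sizes=sizes,
        split_signatures=tuple(split_sigs),
        n_empty_signatures=int((~valid).sum()),
        empirical_p=empirical_p,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Selection stability


def stability_index(report: CVReport) -> tuple[dict[str, float], float]:
    """Per-gene selection frequency and the mean pairwise Jaccard of split signatures.

    The aggregate index is 1 when every split selects the same signature and
    0 when split signatures are pairwise disjoint.
    """
    if report.split_signatures is None:
        raise DomainError("report has no selection traces (run cv_with_selection)")
    sigs = [frozenset(s) for s in report.split_signatures]
    non_empty = [s for s in sigs if s]
    if not non_empty:
        raise EmptyResultError("every split produced an empty signature")
    freq: dict[str, float] = {}
    for s in sigs:
        for g in s:
            freq[g] = freq.get(g, 0.0) + 1.0
    n = len(sigs)
    freq = {g: c / n for g, c in freq.items()}
    if len(non_empty) < 2:
        return freq, 1.0
    jaccards = [
        len(a & b) / len(a | b) for a, b in combinations(non_empty, 2)
    ]
    return freq, float(np.mean(jaccards))


# ---------------------------------------------------------------------------
# Hierarchical clustering of a signature


def cluster_signature(
    m: ExpressionMatrix,
    sig: Signature | Sequence[str],
    linkage: Literal["ward", "average"] = "ward",
    true_labels: Sequence[str] | None = None,
) -> dict:
    """Agglomerative clustering of samples on the signature genes (Euclidean).

    Returns the scipy linkage matrix, the 2-group cut labels and — when true
    class labels are given — the 2-cut accuracy under the best of the two
    possible cluster-to-class assignments.
    """
    gene_ids = sig.gene_ids if isinstance(sig, Signature) else tuple(sig)
    if len(gene_ids) < 2:
        raise DomainError("need a signature of at least 2 genes to cluster")
    sub = m.subset_genes(gene_ids)
    if linkage not in ("ward", "average"):
        raise DomainError(f"unsupported linkage {linkage!r}")
    dist = pdist(sub.values.T, metric="euclidean")
    z = hierarchy.linkage(dist, method=linkage)
    cut = hierarchy.fcluster(z, t=2, criterion="maxclust")
    out = {
        "linkage_matrix": z,
        "cluster_labels": cut,
        "sample_ids": sub.sample_ids,
        "linkage": linkage,
    }
    if true_labels is not None:
        truth = np.asarray(true_labels)
        levels = list(dict.fromkeys(truth))
        if len(levels) != 2:
            raise DesignError("best-matching accuracy needs exactly 2 true classes")
        binary = truth == levels[0]
        cut_binary = cut == 1
        acc = max(
            float(np.mean(cut_binary == binary)),
            float(np.mean(cut_binary == ~binary)),
        )
        out["cut_accuracy"] = acc
    return out


def linkage_to_newick(z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Render a scipy linkage matrix as Newick (branch lengths from merge heights)."""
    tree = hierarchy.to_tree(z)

    def render(node, parent_height: float) -> str:
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{parent_height:.6g}"
        children = f"({render(node.left, node.dist)},{render(node.right, node.dist)})"
        return f"{children}:{parent_height - node.dist:.6g}"

    if tree.is_leaf():
        return f"{leaf_names[tree.id]}:0;"
    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"
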