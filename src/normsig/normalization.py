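"""The four normalization regimes: log-only, quantile, gene fuzzy scoring, SVA-lite.

Log conversion and gene fuzzy scoring (GFS) are within-sample transforms and
need no fitting.  Quantile normalization and the simplified surrogate-variable
correction are fitted on training samples and applied frozen to held-out
samples, so that a held-out sample's processed values never depend on the
other samples in its batch (the "test-set bias" problem).

GFS is a rank-based soft top-coding: per sample, the top ``theta1`` fraction
of genes scores 1, genes between the ``theta1`` and ``theta2`` rank cutoffs
score a linear interpolant, and everything below scores 0.  It is invariant
to any strictly increasing per-sample transform of the input.

SVA-lite estimates latent heterogeneity directions from class-adjusted
residuals by SVD and removes them by regression, protecting the class effect
by including it in the removal design.  The number of surrogate vectors is
chosen by permutation parallel analysis unless given.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.stats import rankdata

from normsig.errors import (
    AlignmentError,
    DegenerateSampleError,
    DomainError,
    RankError,
    ShapeError,
)
from normsig.expr_io import ExpressionMatrix, FactorTable

Method = Literal["none", "quantile", "gfs", "sva"]
METHODS: tuple[Method, ...] = ("none", "quantile", "gfs", "sva")


# ---------------------------------------------------------------------------
# Log conversion


def log_transform(m: ExpressionMatrix, offset: float | None = None) -> ExpressionMatrix:
    """Entrywise natural log of a raw intensity matrix.

    Non-positive entries raise :class:`DomainError` unless ``offset`` is
    given, in which case ``log(x + offset)`` is computed (offset must make
    every entry positive).
    """
    if m.value_space != "raw":
        raise DomainError(f"log_transform expects raw intensities, got {m.value_space!r}")
    values = m.values if offset is None else m.values + offset
    if (values <= 0).any():
        i, j = np.argwhere(values <= 0)[0]
        raise DomainError(
            f"non-positive entry at gene {m.gene_ids[i]!r}, sample "
            f"{m.sample_ids[j]!r}; pass an offset to log_transform"
        )
    return m.with_values(np.log(values), "log")


# ---------------------------------------------------------------------------
# Quantile normalization


@dataclass(frozen=True)
class QuantileReference:
    """Target distribution: rank-wise mean of the sorted training columns."""

    reference_quantiles: np.ndarray

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference_quantiles, dtype=float)
        object.__setattr__(self, "reference_quantiles", ref)
        if ref.ndim != 1:
            raise ShapeError("reference must be a vector")
        if np.any(np.diff(ref) < 0):
            raise DomainError("reference quantiles must be non-decreasing")

    @property
    def n_genes(self) -> int:
        return self.reference_quantiles.size


def quantile_fit(train: ExpressionMatrix) -> QuantileReference:
    """Mean across training samples of within-sample sorted values."""
    ref = np.sort(train.values, axis=0).mean(axis=1)
    return QuantileReference(ref)


def quantile_apply(m: ExpressionMatrix, ref: QuantileReference) -> ExpressionMatrix:
    """Replace each sample's values by reference values at their within-sample ranks.

    Tied values receive the mean of the reference values at the tied rank
    positions, so the transform is well defined and rank-invariant.
    """
    if m.n_genes != ref.n_genes:
        raise ShapeError(
            f"matrix has {m.n_genes} genes but reference has {ref.n_genes}"
        )
    refq = ref.reference_quantiles
    out = np.empty_like(m.values)
    for j in range(m.n_samples):
        col = m.values[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        # Mean reference value over each run of equal input values.
        boundaries = np.flatnonzero(np.r_[True, sorted_col[1:] != sorted_col[:-1]])
        sums = np.add.reduceat(refq, boundaries)
        counts = np.diff(np.r_[boundaries, refq.size])
        group_means = sums / counts
        group_of_pos = np.cumsum(np.r_[True, sorted_col[1:] != sorted_col[:-1]]) - 1
        out[order, j] = group_means[group_of_pos]
    return m.with_values(out, "quantile")


# ---------------------------------------------------------------------------
# Gene fuzzy scoring


@dataclass(frozen=True)
class GFSParams:
    """GFS thresholds as rank-percentile fractions, 0 < theta1 < theta2 < 1.

    ``theta1=0.05, theta2=0.15`` are the method's defaults; varying theta1 in
    [0.05, 0.10] and theta2 in [0.15, 0.20] is reported to give similar
    results, so both are exposed.  Ranks are descending (rank 1 = highest
    expression); ties share the average rank by default.
    """

    theta1: float = 0.05
    theta2: float = 0.15
    tie_rule: Literal["average", "min"] = "average"

    def __post_init__(self) -> None:
        if not 0.0 < self.theta1 < self.theta2 < 1.0:
            raise DomainError(
                f"need 0 < theta1 < theta2 < 1, got ({self.theta1}, {self.theta2})"
            )
        if self.tie_rule not in ("average", "min"):
            raise DomainError(f"unknown tie_rule {self.tie_rule!r}")


def gfs_transform(
    m: ExpressionMatrix, params: GFSParams | None = None
) -> ExpressionMatrix:
    """Per-sample fuzzy rank scores in [0, 1].

    With descending rank ``r`` (rank 1 = highest expression) and rank cutoffs
    ``q1 = theta1 * n`` and ``q2 = theta2 * n``::

        s = 1                      if r <= q1
        s = (r - q2) / (q1 - q2)   if q1 < r < q2
        s = 0                      if r >= q2

    which is ``clip((r - q2) / (q1 - q2), 0, 1)``.  A constant sample has no
    meaningful ranks and raises :class:`DegenerateSampleError`.
    """
    params = params or GFSParams()
    n = m.n_genes
    q1 = params.theta1 * n
    q2 = params.theta2 * n
    ptp = m.values.max(axis=0) - m.values.min(axis=0)
    if (ptp == 0).any():
        j = int(np.argmax(ptp == 0))
        raise DegenerateSampleError(
            f"sample {m.sample_ids[j]!r} is constant; GFS ranks are undefined"
        )
    ranks = rankdata(-m.values, method=params.tie_rule, axis=0)
    scores = np.clip((ranks - q2) / (q1 - q2), 0.0, 1.0)
    return m.with_values(scores, "gfs")


# ---------------------------------------------------------------------------
# SVA-lite


@dataclass(frozen=True)
class SVAModel:
    """Frozen surrogate-variable correction fitted on training samples.

    ``surrogate_vectors`` (n_train x k) are the orthonormal right-singular
    vectors of the class-adjusted residual matrix; ``surrogate_coefficients``
    (genes x k) come from regressing expression on class + surrogates, so the
    class-attributable part of each gene is protected from removal.  New
    samples get scores by projecting their residuals onto the stored
    gene-space directions (``gene_directions`` / ``singular_values``) — the
    correction is frozen, never refitted.
    """

    k: int
    surrogate_vectors: np.ndarray  # n_train x k
    surrogate_coefficients: np.ndarray  # genes x k
    gene_directions: np.ndarray  # genes x k (left singular vectors)
    singular_values: np.ndarray  # k
    gene_means: np.ndarray  # genes, overall training mean
    train_sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]


def _class_residuals(values: np.ndarray, class_codes: np.ndarray) -> np.ndarray:
    """Subtract per-gene class means (the class-adjusted residual matrix)."""
    residuals = values.copy()
    for code in np.unique(class_codes):
        cols = class_codes == code
        residuals[:, cols] -= residuals[:, cols].mean(axis=1, keepdims=True)
    return residuals


def _parallel_analysis_k(
    residuals: np.ndarray,
    singular_values: np.ndarray,
    n_permutations: int,
    quantile: float,
    rng: np.random.Generator,
    margin: float = 0.02,
) -> int:
    """Leading singular values exceeding their row-permutation null quantile.

    Each permutation shuffles every gene's residuals independently across
    samples, destroying inter-gene correlation while preserving per-gene
    marginals; the observed spectrum is compared component-wise to the null
    spectrum's upper quantile and k is the length of the leading run of
    exceedances.  Under pure noise the observed and permuted spectra are
    exchangeable and differ by well under 1%, so a genuine factor must clear
    the threshold by ``margin`` (a real planted factor of >= 1 sd exceeds it
    severalfold); this keeps k = 0 on structureless residuals.
    """
    n_genes, n_samples = residuals.shape
    n_keep = singular_values.size
    null_spectra = np.empty((n_permutations, n_keep))
    for b in range(n_permutations):
        permuted = residuals[
            np.arange(n_genes)[:, None],
            rng.permuted(np.tile(np.arange(n_samples), (n_genes, 1)), axis=1),
        ]
        null_spectra[b] = np.linalg.svd(permuted, compute_uv=False)[:n_keep]
    thresholds = np.quantile(null_spectra, quantile, axis=0)
    exceeds = singular_values > thresholds * (1.0 + margin)
    k = 0
    while k < exceeds.size and exceeds[k]:
        k += 1
    return k


def sva_fit(
    train: ExpressionMatrix,
    factors: FactorTable,
    k: int | Literal["auto"] = "auto",
    n_permutations: int = 20,
    pa_quantile: float = 0.95,
    seed: int = 0,
) -> SVAModel:
    """Estimate heterogeneity directions from class-adjusted residuals.

    Fits per-gene class means, takes the SVD of the residual matrix, keeps
    ``k`` right-singular vectors (permutation parallel analysis when
    ``k='auto'``), and stores the gene-wise surrogate coefficients from a
    joint regression of expression on class + surrogates.
    """
    if train.n_samples <= 2:
        raise RankError("SVA needs more than 2 training samples")
    factors = factors.align_to(train.sample_ids)
    levels = factors.class_levels
    class_codes = np.array([levels.index(c) for c in factors.class_labels])
    max_k = train.n_samples - 2
    if k != "auto" and (int(k) < 0 or int(k) > max_k):
        raise RankError(f"k={k} outside [0, n_samples-2]={max_k}")

    residuals = _class_residuals(train.values, class_codes)
    u, s, vt = np.linalg.svd(residuals, full_matrices=False)
    # One singular value per class-mean constraint is identically ~0.
    usable = min(max_k, s.size)
    u, s, vt = u[:, :usable], s[:usable], vt[:usable]

    if k == "auto":
        rng = np.random.default_rng(seed)
        k_sel = _parallel_analysis_k(residuals, s, n_permutations, pa_quantile, rng)
    else:
        k_sel = int(k)

    surrogates = vt[:k_sel].T  # n_train x k
    if k_sel > 0:
        class_dummy = (class_codes == 1).astype(float)
        design = np.column_stack(
            [np.ones(train.n_samples), class_dummy, surrogates]
        )
        coef, *_ = np.linalg.lstsq(design, train.values.T, rcond=None)
        sur_coef = coef[2:].T  # genes x k
    else:
        sur_coef = np.zeros((train.n_genes, 0))
    return SVAModel(
        k=k_sel,
        surrogate_vectors=surrogates,
        surrogate_coefficients=sur_coef,
        gene_directions=u[:, :k_sel],
        singular_values=s[:k_sel],
        gene_means=train.values.mean(axis=1),
        train_sample_ids=train.sample_ids,
        gene_ids=train.gene_ids,
    )


def sva_apply(m: ExpressionMatrix, model: SVAModel) -> ExpressionMatrix:
    """Subtract the fitted surrogate contribution from each sample.

    Every sample — training or new — is scored by projecting its residual
    from the stored training gene means onto the frozen gene-space directions
    (score_i = u_i . residual / s_i), then the per-gene surrogate
    contribution is subtracted.  Using the same projection for training and
    held-out samples keeps the two populations exchangeable: a correction
    that used exact in-sample scores for training data but projections for
    new data would treat the two systematically differently and bias any
    train/validate comparison.  The correction is frozen — no refitting, and
    no dependence on the other samples in the new batch.  ``k=0`` models
    return the input unchanged.
    """
    if m.gene_ids != model.gene_ids:
        raise AlignmentError("gene set differs from the one the SVA model was fitted on")
    if model.k == 0:
        return m.with_values(m.values.copy(), "sva")
    resid = m.values - model.gene_means[:, None]
    scores = (model.gene_directions / model.singular_values).T @ resid  # k x n
    corrected = m.values - model.surrogate_coefficients @ scores
    return m.with_values(corrected, "sva")


# ---------------------------------------------------------------------------
# Unified train/apply entry point


def normalize(
    train: ExpressionMatrix,
    method: Method,
    factors: FactorTable | None = None,
    test: ExpressionMatrix | None = None,
    gfs_params: GFSParams | None = None,
    k: int | Literal["auto"] = "auto",
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix | None]:
    """Normalize a (log-space) training matrix and optionally a held-out one.

    ``none`` and ``gfs`` are within-sample; ``quantile`` and ``sva`` fit on
    the training samples and apply the frozen transform to the held-out set.
    ``factors`` is required for ``sva`` (class labels protect the class
    effect).
    """
    if method == "none":
        return train, test
    if method == "gfs":
        params = gfs_params or GFSParams()
        return gfs_transform(train, params), (
            gfs_transform(test, params) if test is not None else None
        )
    if method == "quantile":
        ref = quantile_fit(train)
        return quantile_apply(train, ref), (
            quantile_apply(test, ref) if test is not None else None
        )
    if method == "sva":
        if factors is None:
            raise DomainError("SVA normalization requires a factor table")
        model = sva_fit(train, factors, k=k, seed=seed)
        return sva_apply(train, model), (
            sva_apply(test, model) if test is not None else None
        )
    raise DomainError(f"unknown normalization method {method!r}")
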