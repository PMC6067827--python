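"""Synthetic bulk-expression generator with planted structure and ground truth.

The generator emulates a two-class bead-array cohort: 56 cases and 28
controls, log-normal-scale intensities, a small set of truly class-affected
genes, covariate-linked effects (gender, ethnicity at 75/25 ratios),
pervasive sample heterogeneity, and i.i.d. noise.  The heterogeneity has
three layers, mirroring what plagues real array cohorts:

* a *leading latent factor* loading on a large fraction of genes, whose
  per-sample score is mildly correlated with class (``confounder_rho``) —
  the component a surrogate-variable correction is designed to find;
* several *minor latent factors* of smaller strength on the same confounded
  genes — diffuse correlated variation that low-rank corrections recover
  only partially;
* *sample-specific artifacts*: sparse heavy-tailed spikes (hybridization
  blemishes) and a per-sample dynamic-range scale factor (array-to-array
  intensity spread), neither of which is low-rank.

The additive model lives on the natural-log scale and is exponentiated to
raw intensity space:

    log x[g, s] = baseline[g]
                + class_effect * 1[g signal, s case]
                + sum_c effect_c * 1[g in c's gene set, s in c's minor level]
                + sum_r strength_r * loading[g, r] * score[s, r]
                + spike[g, s] + Normal(0, noise_sd)

followed by the per-sample scale distortion
``x[., s] <- median(x[., s]) + a[s] * (x[., s] - median(x[., s]))``.

Signal genes are placed high in the expression distribution (around the
``signal_baseline_percentile`` of per-gene baselines) so that the planted
shift moves them through the top ranks of each sample — the regime in which
differential expression is detectable on arrays at all.

All randomness flows from one master seed through named independent
substreams; ground truth (which genes carry which effect, each sample's
heterogeneity score) is returned alongside the data for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from normsig.errors import SpecError
from normsig.expr_io import ExpressionMatrix, FactorTable


@dataclass(frozen=True)
class CovariateSpec:
    """A categorical nuisance covariate with its own affected gene set.

    ``proportions`` are the level proportions in sample-assignment order
    (e.g. ``(0.75, 0.25)`` for a 3:1 split); ``n_affected`` genes receive an
    additive shift of ``effect`` (log scale) in the minor level.
    """

    name: str
    levels: tuple[str, ...]
    proportions: tuple[float, ...]
    n_affected: int
    effect: float


def _default_covariates() -> tuple[CovariateSpec, ...]:
    return (
        CovariateSpec("gender", ("male", "female"), (0.75, 0.25), 30, 0.8),
        CovariateSpec("ethnicity", ("chinese", "other"), (0.75, 0.25), 30, 0.8),
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic cohort.

    Defaults mirror the study design this generator emulates: 56 cases vs 28
    controls, covariates at 75/25 ratios, 20 class-affected genes shifted by
    1 log-sd, and heterogeneity touching 40% of genes.  ``n_genes`` defaults
    to 2,000 — a scaled stand-in for a filtered bead-array panel of ~18k
    probes.  Setting ``class_effect=0`` together with zero heterogeneity
    (``confounder_strength=0, minor_strength=0, artifact_rate=0,
    scale_sd=0``) yields a pure-null cohort for calibration checks.
    """

    n_subject: int = 56
    n_control: int = 28
    n_genes: int = 2000
    n_signal: int = 20
    class_effect: float = 1.0
    covariates: tuple[CovariateSpec, ...] = field(default_factory=_default_covariates)
    confounded_fraction: float = 0.4
    confounder_strength: float = 1.2
    confounder_rho: float = 0.3
    n_minor_components: int = 8
    minor_strength: float = 0.5
    artifact_rate: float = 0.03
    artifact_sd: float = 3.0
    scale_sd: float = 0.6
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    signal_baseline_percentile: float = 0.93
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subject < 2 or self.n_control < 2:
            raise SpecError("need at least 2 samples per class")
        if self.n_genes < 1 or self.n_signal < 0:
            raise SpecError("gene counts must be positive")
        n_affected = self.n_signal + sum(c.n_affected for c in self.covariates)
        if n_affected > self.n_genes:
            raise SpecError(
                f"signal + covariate gene counts ({n_affected}) exceed n_genes ({self.n_genes})"
            )
        if not 0.0 <= self.confounded_fraction <= 1.0:
            raise SpecError("confounded_fraction must be in [0,1]")
        if not -1.0 <= self.confounder_rho <= 1.0:
            raise SpecError("confounder_rho must be in [-1,1]")
        if not 0.0 <= self.artifact_rate < 1.0:
            raise SpecError("artifact_rate must be in [0,1)")
        if not 0.0 < self.signal_baseline_percentile < 1.0:
            raise SpecError("signal_baseline_percentile must be in (0,1)")
        for cov in self.covariates:
            if len(cov.levels) != len(cov.proportions) or len(cov.levels) < 2:
                raise SpecError(f"covariate {cov.name!r} levels/proportions mismatch")
            if not np.isclose(sum(cov.proportions), 1.0):
                raise SpecError(f"covariate {cov.name!r} proportions must sum to 1")
            if any(not 0.0 < p < 1.0 for p in cov.proportions):
                raise SpecError(f"covariate {cov.name!r} proportions must be in (0,1)")
        for name in (
            "noise_sd",
            "baseline_sd",
            "confounder_strength",
            "minor_strength",
            "artifact_sd",
            "scale_sd",
        ):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be non-negative")
        if self.n_minor_components < 0:
            raise SpecError("n_minor_components must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.n_subject + self.n_control


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one generated dataset, for recovery oracles.

    ``confounder_scores`` and ``confounder_loadings`` describe the leading
    heterogeneity factor (the one optionally correlated with class).
    """

    signal_genes: frozenset[str]
    covariate_genes: Mapping[str, frozenset[str]]
    confounded_genes: frozenset[str]
    confounder_scores: np.ndarray
    confounder_loadings: np.ndarray


_SUBSTREAMS = ("baseline", "assignments", "confounder", "noise")


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    """Independent named generators derived from one master seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_SUBSTREAMS, children)}


def _proportional_counts(n: int, proportions: Sequence[float]) -> list[int]:
    """Split n into integer level counts matching proportions (largest remainder)."""
    raw = np.asarray(proportions) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in order[:remainder]:
        counts[i] += 1
    return counts.tolist()


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, FactorTable, SyntheticTruth]:
    """Generate one cohort: raw-intensity matrix, factor table and ground truth.

    Deterministic given ``spec.seed``; the returned matrix is strictly
    positive (raw intensity space).
    """
    rngs = _substreams(spec.seed)
    n_genes, n_samples = spec.n_genes, spec.n_samples

    gene_ids = tuple(f"G{i:05d}" for i in range(n_genes))
    sample_ids = tuple(f"S{i:03d}" for i in range(n_samples))
    class_labels = ("subject",) * spec.n_subject + ("control",) * spec.n_control
    is_subject = np.array([c == "subject" for c in class_labels])

    rng_assign = rngs["assignments"]
    # Disjoint planted gene sets: signal first, then each covariate.
    perm = rng_assign.permutation(n_genes)
    cursor = 0
    signal_idx = perm[cursor : cursor + spec.n_signal]
    cursor += spec.n_signal
    covariate_idx: dict[str, np.ndarray] = {}
    for cov in spec.covariates:
        covariate_idx[cov.name] = perm[cursor : cursor + cov.n_affected]
        cursor += cov.n_affected

    # Covariate level assignment, balanced within each class so covariates
    # are not accidentally confounded with the class factor.
    factors: dict[str, tuple[str, ...]] = {"class": class_labels}
    cov_minor_mask: dict[str, np.ndarray] = {}
    for cov in spec.covariates:
        labels = np.empty(n_samples, dtype=object)
        for mask in (is_subject, ~is_subject):
            n_grp = int(mask.sum())
            counts = _proportional_counts(n_grp, cov.proportions)
            pool = np.repeat(np.asarray(cov.levels, dtype=object), counts)
            labels[mask] = rng_assign.permutation(pool)
        factors[cov.name] = tuple(labels)
        minor_level = cov.levels[int(np.argmin(cov.proportions))]
        cov_minor_mask[cov.name] = labels == minor_level

    rng_base = rngs["baseline"]
    baseline = rng_base.normal(spec.baseline_mean, spec.baseline_sd, size=n_genes)
    if spec.n_signal:
        # Signal genes sit high in the expression distribution (jittered), so
        # the planted shift moves them through the top ranks of each sample.
        baseline[signal_idx] = (
            spec.baseline_mean
            + spec.baseline_sd * norm.ppf(spec.signal_baseline_percentile)
            + rng_base.normal(0.0, 0.25, size=spec.n_signal)
        )

    rng_conf = rngs["confounder"]
    n_confounded = int(round(spec.confounded_fraction * n_genes))
    confounded_idx = rng_conf.permutation(n_genes)[:n_confounded]
    # Standardized class indicator for the rho-correlated leading factor.
    z_class = (is_subject.astype(float) - is_subject.mean()) / max(is_subject.std(), 1e-12)

    log_values = np.tile(baseline[:, None], (1, n_samples))
    log_values[np.ix_(signal_idx, np.where(is_subject)[0])] += spec.class_effect
    for cov in spec.covariates:
        idx = covariate_idx[cov.name]
        cols = np.where(cov_minor_mask[cov.name])[0]
        if idx.size and cols.size:
            log_values[np.ix_(idx, cols)] += cov.effect

    lead_loadings = np.zeros(n_genes)
    lead_scores = np.zeros(n_samples)
    strengths = [spec.confounder_strength] + [spec.minor_strength] * spec.n_minor_components
    for r, strength in enumerate(strengths):
        loadings = np.zeros(n_genes)
        loadings[confounded_idx] = rng_conf.normal(0.0, 1.0, size=n_confounded)
        scores = rng_conf.normal(0.0, 1.0, size=n_samples)
        if r == 0:
            scores = spec.confounder_rho * z_class + np.sqrt(
                1.0 - spec.confounder_rho**2
            ) * scores
            lead_loadings, lead_scores = loadings, scores
        if strength > 0:
            log_values += strength * np.outer(loadings, scores)

    if spec.artifact_rate > 0:
        spikes = rng_conf.random((n_genes, n_samples)) < spec.artifact_rate
        log_values += spikes * rng_conf.normal(
            0.0, spec.artifact_sd, size=(n_genes, n_samples)
        )

    log_values += rngs["noise"].normal(0.0, spec.noise_sd, size=(n_genes, n_samples))

    if spec.scale_sd > 0:
        scale = np.exp(rng_conf.normal(0.0, spec.scale_sd, size=n_samples))
        medians = np.median(log_values, axis=0)
        log_values = medians[None, :] + scale[None, :] * (log_values - medians[None, :])

    matrix = ExpressionMatrix(np.exp(log_values), gene_ids, sample_ids, "raw")
    table = FactorTable(sample_ids, factors, "class")
    truth = SyntheticTruth(
        signal_genes=frozenset(gene_ids[i] for i in signal_idx),
        covariate_genes={
            name: frozenset(gene_ids[i] for i in idx)
            for name, idx in covariate_idx.items()
        },
        confounded_genes=frozenset(gene_ids[i] for i in confounded_idx),
        confounder_scores=lead_scores,
        confounder_loadings=lead_loadings,
    )
    return matrix, table, truth
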