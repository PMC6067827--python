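"""Per-gene F-test differential expression, BH correction, and signature overlap.

The per-gene statistic is the classical one-way ANOVA F — between-group mean
square over within-group mean square with (K - 1, N - K) degrees of freedom —
followed by Benjamini-Hochberg step-up adjustment across genes.  A signature
is the ordered set of genes whose adjusted p-value passes a threshold
(defaults 0.01 strict / 0.05 relaxed).  ``compare_selections`` quantifies how
differently the normalization regimes select: all pairwise and higher-order
intersection counts, plus a contrast of the reference p-values of genes
selected by several regimes versus genes selected by only one.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from normsig.errors import AlignmentError, DesignError, DomainError
from normsig.expr_io import ExpressionMatrix


@dataclass(frozen=True)
class GeneStats:
    """Per-gene F statistics with raw and BH-adjusted p-values."""

    gene_ids: tuple[str, ...]
    f: np.ndarray
    p: np.ndarray
    p_adj: np.ndarray
    df: tuple[int, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"F": self.f, "p": self.p, "p_adj": self.p_adj},
            index=list(self.gene_ids),
        )


@dataclass(frozen=True)
class Signature:
    """Ordered gene set passing an adjusted-p threshold under one normalization.

    Genes are ordered by raw p, ties broken lexicographically by gene id.
    An empty signature is legal (nothing passed the cutoff).
    """

    gene_ids: tuple[str, ...]
    threshold: float
    normalization: str = ""

    @property
    def size(self) -> int:
        return len(self.gene_ids)

    @property
    def is_empty(self) -> bool:
        return not self.gene_ids


def f_test_per_gene(m: ExpressionMatrix, class_labels: Sequence[str]) -> GeneStats:
    """One-way ANOVA F per gene across the groups defined by ``class_labels``.

    Degenerate genes are handled explicitly: zero within-group variance with
    non-zero between-group variance gives F = inf, p = 0; a completely
    constant gene gives F = 0, p = 1.
    """
    labels = np.asarray(class_labels)
    if labels.size != m.n_samples:
        raise DesignError("one class label per sample required")
    levels, codes = np.unique(labels, return_inverse=True)
    n_groups = levels.size
    if n_groups < 2:
        raise DesignError("need at least 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        small = levels[counts < 2]
        raise DesignError(f"groups with fewer than 2 samples: {list(small)}")

    values = m.values
    n_total = labels.size
    grand_mean = values.mean(axis=1)
    between_ss = np.zeros(m.n_genes)
    within_ss = np.zeros(m.n_genes)
    for g in range(n_groups):
        cols = codes == g
        group = values[:, cols]
        group_mean = group.mean(axis=1)
        between_ss += counts[g] * (group_mean - grand_mean) ** 2
        within_ss += ((group - group_mean[:, None]) ** 2).sum(axis=1)
    df1, df2 = n_groups - 1, n_total - n_groups

    with np.errstate(divide="ignore", invalid="ignore"):
        f = (between_ss / df1) / (within_ss / df2)
    zero_within = np.isclose(within_ss, 0.0)
    f = np.where(zero_within & ~np.isclose(between_ss, 0.0), np.inf, f)
    f = np.where(zero_within & np.isclose(between_ss, 0.0), 0.0, f)
    p = np.where(np.isinf(f), 0.0, stats.f.sf(np.where(np.isinf(f), 0.0, f), df1, df2))
    p = np.where(f == 0.0, 1.0, p)
    return GeneStats(m.gene_ids, f, p, bh_adjust(p), (df1, df2))


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_signature(
    stats_: GeneStats, threshold: float = 0.01, normalization: str = ""
) -> Signature:
    """Genes with adjusted p <= threshold, ordered by raw p then gene id."""
    if not 0.0 < threshold <= 1.0:
        raise DomainError(f"threshold must be in (0, 1], got {threshold}")
    hits = np.flatnonzero(stats_.p_adj <= threshold)
    order = sorted(hits, key=lambda i: (stats_.p[i], stats_.gene_ids[i]))
    return Signature(tuple(stats_.gene_ids[i] for i in order), threshold, normalization)


def compare_selections(
    signatures: Mapping[str, Signature],
    stats_reference: GeneStats | None = None,
) -> dict:
    """Intersection structure of signatures from different normalizations.

    Reports every pairwise and higher-order intersection count plus the union
    size.  If ``stats_reference`` is given (typically the adjusted p-values
    under one chosen regime), genes selected under >= ``majority`` regimes
    are contrasted against singly-selected genes: summary quantiles of the
    reference p-values in each group and a two-sided rank-sum p-value.
    """
    if len(signatures) < 2:
        raise DesignError("need at least 2 signatures to compare")
    sets = {name: set(sig.gene_ids) for name, sig in signatures.items()}
    names = sorted(sets)

    report: dict = {
        "sizes": {name: len(sets[name]) for name in names},
        "union": len(set().union(*sets.values())),
        "intersections": {},
    }
    for r in range(2, len(names) + 1):
        for combo in combinations(names, r):
            common = set.intersection(*(sets[n] for n in combo))
            report["intersections"]["&".join(combo)] = len(common)

    if stats_reference is not None:
        ref_index = {g: i for i, g in enumerate(stats_reference.gene_ids)}
        all_selected = set().union(*sets.values())
        missing = [g for g in all_selected if g not in ref_index]
        if missing:
            raise AlignmentError(
                f"selected genes absent from reference stats: {missing[:5]}"
            )
        counts = {g: sum(g in s for s in sets.values()) for g in all_selected}
        majority = max(2, len(names) - 1)
        shared = [g for g, c in counts.items() if c >= majority]
        single = [g for g, c in counts.items() if c == 1]
        report["significance_contrast"] = _p_value_contrast(
            shared, single, stats_reference, ref_index, majority
        )
    return report


def _p_value_contrast(shared, single, reference, ref_index, majority) -> dict:
    out = {
        "min_regimes_for_shared": majority,
        "n_shared": len(shared),
        "n_single": len(single),
    }
    for key, genes in (("shared", shared), ("single", single)):
        if genes:
            ps = np.array([reference.p[ref_index[g]] for g in genes])
            out[f"{key}_p_quartiles"] = [float(q) for q in np.quantile(ps, [0.25, 0.5, 0.75])]
        else:
            out[f"{key}_p_quartiles"] = None
    if shared and single:
        ps_shared = [reference.p[ref_index[g]] for g in shared]
        ps_single = [reference.p[ref_index[g]] for g in single]
        out["ranksum_p"] = float(
            stats.mannwhitneyu(ps_shared, ps_single, alternative="two-sided").pvalue
        )
    else:
        out["ranksum_p"] = None
    return out
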