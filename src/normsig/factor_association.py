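"""PCA of the sample cloud and PC-by-factor Kruskal-Wallis association.

Samples are the observations and genes the variables.  Variables are centered
(not scaled — unit-variance scaling would distort the [0, 1] structure of
fuzzy-scored data) and the principal components come from the SVD of the
centered matrix.  Each of the leading PCs' score vectors is then tested for
association with every categorical factor using the Kruskal-Wallis rank test,
giving a PC x factor p-value grid; the row index of the first significant PC
per factor is a compact diagnostic of how prominently that factor's signal
sits in the data under a given normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from normsig.errors import DegenerateInputError, DesignError, DomainError
from normsig.expr_io import ExpressionMatrix, FactorTable


@dataclass(frozen=True)
class PCModel:
    """PCA of samples: scores (samples x PCs), loadings (genes x PCs), variance fractions.

    Signs are fixed by making the largest-magnitude entry of each loading
    vector positive, so results are deterministic across SVD backends.
    The loading matrix lets a user inspect which genes drive a
    heterogeneity-dominated component; the package does not act on it
    further.
    """

    scores: np.ndarray
    loadings: np.ndarray
    variance_fraction: np.ndarray
    sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass(frozen=True)
class AssociationTable:
    """PC x factor grid of Kruskal-Wallis p-values with a significance mask."""

    p_values: pd.DataFrame  # rows PC1..PCn, columns factor names
    alpha: float = 0.05

    @property
    def mask(self) -> pd.DataFrame:
        return self.p_values <= self.alpha

    def first_significant_pc(self) -> dict[str, int | None]:
        """Per factor, the 1-based rank of the first significant PC (None if none)."""
        out: dict[str, int | None] = {}
        for factor in self.p_values.columns:
            hits = np.flatnonzero(self.mask[factor].to_numpy())
            out[factor] = int(hits[0]) + 1 if hits.size else None
        return out

    def to_display(self) -> pd.DataFrame:
        """Two-decimal display form (full precision stays in ``p_values``)."""
        return self.p_values.round(2)


def run_pca(m: ExpressionMatrix, center: bool = True) -> PCModel:
    """PCA of the sample cloud via SVD of the (gene-centered) matrix."""
    if m.n_samples < 2 or m.n_genes < 2:
        raise DesignError("PCA needs at least 2 samples and 2 genes")
    x = m.values.T.astype(float)  # samples x genes
    if center:
        x = x - x.mean(axis=0, keepdims=True)
    total_var = np.sum(x**2)
    if total_var == 0:
        raise DegenerateInputError("constant matrix: PCA undefined")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # Drop the component that centering makes identically zero.
    keep = min(x.shape) - 1 if center else min(x.shape)
    keep = max(keep, 1)
    u, s, vt = u[:, :keep], s[:keep], vt[:keep]
    # Deterministic sign: largest-|.| loading entry positive per component.
    flip = np.sign(vt[np.arange(keep), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    scores = u * s
    return PCModel(
        scores=scores,
        loadings=vt.T,
        variance_fraction=s**2 / np.sum(s**2),
        sample_ids=m.sample_ids,
        gene_ids=m.gene_ids,
    )


def kw_association(scores_for_pc: np.ndarray, factor_labels: Sequence[str]) -> float:
    """Kruskal-Wallis p-value for association of one PC's scores with a factor.

    Tie-corrected H statistic referred to a chi-square with (levels - 1)
    degrees of freedom; identical values everywhere give H = 0, p = 1.
    """
    scores_for_pc = np.asarray(scores_for_pc, dtype=float)
    labels = np.asarray(factor_labels)
    if scores_for_pc.size != labels.size:
        raise DesignError("scores and labels must have equal length")
    groups = [scores_for_pc[labels == lev] for lev in np.unique(labels)]
    if len(groups) < 2:
        raise DesignError("factor needs at least 2 levels")
    if np.all(scores_for_pc == scores_for_pc[0]):
        return 1.0
    h, p = stats.kruskal(*groups)
    return float(p)


def build_association_table(
    pc: PCModel,
    factors: FactorTable,
    n_pcs: int = 10,
    alpha: float = 0.05,
) -> AssociationTable:
    """KW p-values of the top ``n_pcs`` components against every factor.

    Raw p-values are reported without multiple-testing correction across the
    grid, matching the raw-threshold convention of the diagnostic; treat
    borderline cells accordingly.
    """
    if n_pcs > pc.n_components:
        raise DomainError(
            f"requested {n_pcs} PCs but model has {pc.n_components}"
        )
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must be in (0,1), got {alpha}")
    factors = factors.align_to(pc.sample_ids)
    table = {
        name: [
            kw_association(pc.scores[:, i], factors.factors[name])
            for i in range(n_pcs)
        ]
        for name in factors.factor_names
    }
    frame = pd.DataFrame(table, index=[f"PC{i + 1}" for i in range(n_pcs)])
    return AssociationTable(frame, alpha)
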