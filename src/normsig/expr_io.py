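"""Expression-matrix and factor-table containers, TSV I/O, and matrix-level preprocessing.

The on-disk convention is plain tab-separated text: genes in rows, samples in
columns, a header row of sample identifiers and a first column of gene
identifiers.  Factor tables are one row per sample with a header.  Every
destructive preprocessing step (detection filtering, centering) can record its
parameters in a JSON provenance sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from normsig.errors import (
    AlignmentError,
    DesignError,
    DomainError,
    EmptyResultError,
    FormatError,
    IdentifierError,
    ShapeError,
)

ValueSpace = Literal["raw", "log", "quantile", "gfs", "sva"]

_VALUE_SPACES = ("raw", "log", "quantile", "gfs", "sva")


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples numeric matrix with identifier lists.

    ``value_space`` tags which transformation the values currently live in:
    ``raw`` (non-negative intensities), ``log`` (natural log), ``quantile``,
    ``gfs`` (fuzzy scores in [0, 1]) or ``sva`` (surrogate-corrected log).
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    value_space: ValueSpace = "raw"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if self.value_space not in _VALUE_SPACES:
            raise DomainError(f"unknown value_space {self.value_space!r}")
        if values.ndim != 2:
            raise ShapeError(f"expression values must be 2-D, got shape {values.shape}")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ShapeError(
                f"values shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise IdentifierError(f"duplicate gene ids: {dupes}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise IdentifierError(f"duplicate sample ids: {dupes}")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if self.value_space == "raw" and (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise DomainError(
                f"negative raw intensity at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def with_values(self, values: np.ndarray, value_space: ValueSpace) -> "ExpressionMatrix":
        """Return a copy with new values in a (possibly different) value space."""
        return ExpressionMatrix(values, self.gene_ids, self.sample_ids, value_space)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise AlignmentError(f"genes absent from matrix: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            self.values[rows, :], tuple(gene_ids), self.sample_ids, self.value_space
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise AlignmentError(f"samples absent from matrix: {missing[:5]}")
        cols = [index[s] for s in sample_ids]
        return ExpressionMatrix(
            self.values[:, cols], self.gene_ids, tuple(sample_ids), self.value_space
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class FactorTable:
    """Per-sample categorical annotations.

    ``class_factor`` names the two-level case/control factor; any other
    factor (gender, ethnicity, batch, ...) must have at least two levels and
    cover every sample.
    """

    sample_ids: tuple[str, ...]
    factors: Mapping[str, tuple[str, ...]]
    class_factor: str = "class"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        factors = {
            str(name): tuple(str(v) for v in levels)
            for name, levels in dict(self.factors).items()
        }
        object.__setattr__(self, "factors", factors)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise IdentifierError(f"duplicate sample ids: {_duplicates(self.sample_ids)}")
        if self.class_factor not in factors:
            raise DesignError(f"class factor {self.class_factor!r} not present")
        n = len(self.sample_ids)
        for name, labels in factors.items():
            if len(labels) != n:
                raise DesignError(
                    f"factor {name!r} covers {len(labels)} samples, expected {n}"
                )
            # Only the class factor's level count is a structural invariant;
            # other factors may collapse to one level in a training-half
            # subset (tests that need >= 2 levels check at point of use).
            if name == self.class_factor and len(set(labels)) != 2:
                raise DesignError(
                    f"class factor {name!r} has {len(set(labels))} levels, expected 2"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(self.factors)

    @property
    def class_labels(self) -> tuple[str, ...]:
        return self.factors[self.class_factor]

    @property
    def class_levels(self) -> tuple[str, ...]:
        """The two class levels in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.class_labels:
            seen.setdefault(lab, None)
        return tuple(seen)

    def align_to(self, sample_ids: Sequence[str]) -> "FactorTable":
        """Reorder (or subset) rows to match ``sample_ids``."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise AlignmentError(f"samples missing from factor table: {missing[:5]}")
        rows = [index[s] for s in sample_ids]
        return FactorTable(
            tuple(sample_ids),
            {name: tuple(labels[i] for i in rows) for name, labels in self.factors.items()},
            self.class_factor,
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({name: list(v) for name, v in self.factors.items()})
        frame.insert(0, "sample_id", list(self.sample_ids))
        return frame


def _duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in ids:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out


# ---------------------------------------------------------------------------
# I/O


def read_expression_matrix(
    path: str | Path, dialect: str = "genes_in_rows", value_space: ValueSpace = "raw"
) -> ExpressionMatrix:
    """Read a TSV expression matrix (first row sample ids, first column gene ids).

    Parsing is locale-independent (dot decimal separator).  Duplicate
    identifiers raise :class:`IdentifierError`; non-numeric or missing cells
    raise :class:`FormatError` naming the offending row and column.
    """
    if dialect != "genes_in_rows":
        raise DomainError(f"unsupported dialect {dialect!r}")
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    gene_ids = [str(g) for g in frame.index]
    sample_ids = [str(s) for s in frame.columns]
    if len(set(gene_ids)) != len(gene_ids):
        raise IdentifierError(f"duplicate gene ids in {path}: {_duplicates(gene_ids)}")
    if len(set(sample_ids)) != len(sample_ids):
        raise IdentifierError(f"duplicate sample ids in {path}: {_duplicates(sample_ids)}")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        try:
            values[:, j] = pd.to_numeric(frame[col], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError):
            bad = pd.to_numeric(frame[col], errors="coerce")
            row = bad.index[bad.isna().to_numpy()][0]
            raise FormatError(
                f"non-numeric cell at gene {row!r}, sample {col!r} in {path}"
            ) from None
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise FormatError(
            f"missing value at gene {gene_ids[i]!r}, sample {sample_ids[j]!r} in {path}"
        )
    return ExpressionMatrix(values, tuple(gene_ids), tuple(sample_ids), value_space)


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, float_format: str = "%.12g"
) -> None:
    """Write a matrix as TSV with 12 significant digits (read/write round-trips)."""
    m.to_frame().to_csv(path, sep="\t", float_format=float_format)


def read_factor_table(
    path: str | Path, class_factor: str = "class"
) -> FactorTable:
    """Read a per-sample factor table (TSV, first column sample ids)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise FormatError(f"factor table {path} needs a sample column and >=1 factor")
    sample_col = frame.columns[0]
    if frame[sample_col].isna().any() or frame.drop(columns=sample_col).isna().any().any():
        raise FormatError(f"missing value in factor table {path}")
    sample_ids = tuple(frame[sample_col].astype(str))
    factors = {
        str(c): tuple(frame[c].astype(str)) for c in frame.columns if c != sample_col
    }
    if class_factor not in factors:
        raise DesignError(f"class factor {class_factor!r} not found in {path}")
    for name, labels in factors.items():
        if name != class_factor and len(set(labels)) < 2:
            raise DesignError(f"factor {name!r} in {path} has fewer than 2 levels")
    return FactorTable(sample_ids, factors, class_factor)


def write_factor_table(t: FactorTable, path: str | Path) -> None:
    t.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Matrix-level preprocessing


@dataclass
class Provenance:
    """Accumulates the parameters of each preprocessing step for a JSON sidecar."""

    steps: list[dict] = field(default_factory=list)

    def record(self, step: str, **params) -> None:
        self.steps.append({"step": step, **params})

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"steps": self.steps}, indent=2) + "\n")


def apply_detection_filter(
    m: ExpressionMatrix,
    det_p: np.ndarray,
    alpha: float = 0.05,
    direction: Literal["discard_above", "discard_below"] = "discard_above",
    min_fraction: float = 1.0,
    provenance: Provenance | None = None,
) -> tuple[ExpressionMatrix, tuple[str, ...]]:
    """Drop undetected genes based on per-probe detection p-values.

    A gene is *detected* in a sample when its detection p-value is on the
    favourable side of ``alpha``.  With ``direction='discard_above'`` (the
    standard bead-array convention) detection p-values above ``alpha`` mark a
    probe as undetected; ``'discard_below'`` inverts this for compatibility
    with analyses that use the opposite convention.  A gene is kept when it is
    detected in at least ``min_fraction`` of samples.  Returns the filtered
    matrix and the retained gene ids.
    """
    det_p = np.asarray(det_p, dtype=float)
    if det_p.shape != m.values.shape:
        raise ShapeError(
            f"detection p-value shape {det_p.shape} != matrix shape {m.values.shape}"
        )
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"alpha must be in (0,1), got {alpha}")
    if direction == "discard_above":
        detected = det_p <= alpha
    elif direction == "discard_below":
        detected = det_p >= alpha
    else:
        raise DomainError(f"unknown direction {direction!r}")
    keep = detected.mean(axis=1) >= min_fraction
    if not keep.any():
        raise EmptyResultError("detection filter discarded every gene")
    retained = tuple(g for g, k in zip(m.gene_ids, keep) if k)
    if provenance is not None:
        provenance.record(
            "detection_filter",
            alpha=alpha,
            direction=direction,
            min_fraction=min_fraction,
            n_in=m.n_genes,
            n_retained=len(retained),
        )
    out = ExpressionMatrix(m.values[keep, :], retained, m.sample_ids, m.value_space)
    return out, retained


def median_center(
    m: ExpressionMatrix,
    axis: Literal["per_sample", "per_gene"] = "per_sample",
    provenance: Provenance | None = None,
) -> ExpressionMatrix:
    """Subtract the median of each sample (default) or each gene.

    Per-sample centering keeps every sample's processed values independent of
    the rest of the cohort, avoiding the cross-sample dependence that makes
    results change when cohort composition changes.
    """
    if m.value_space not in ("raw", "log"):
        raise DomainError(f"median centering not defined for value_space={m.value_space!r}")
    if axis == "per_sample":
        centered = m.values - np.median(m.values, axis=0, keepdims=True)
    elif axis == "per_gene":
        centered = m.values - np.median(m.values, axis=1, keepdims=True)
    else:
        raise DomainError(f"unknown axis {axis!r}")
    if provenance is not None:
        provenance.record("median_center", axis=axis)
    # Centering can produce negatives, so the result is never tagged raw.
    return ExpressionMatrix(centered, m.gene_ids, m.sample_ids, "log")
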