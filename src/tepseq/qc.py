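"""Cohort-level quality control for platelet spliced-RNA count matrices.

Three filters are applied, in this order, before any modeling:

1. low-abundance genes (fewer than 30 intron-spanning reads in more than
   90% of the cohort) are dropped;
2. samples with fewer than 750 detected spliced genes are dropped;
3. samples whose counts-per-million profile correlates poorly (Pearson
   r < 0.5) with the leave-one-sample-out median profile of the rest of
   the cohort are dropped.

All three are deliberately label-agnostic: they run before normalization
or any training-cohort choice, so the leave-one-out correlation uses plain
counts-per-million on raw counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CountMatrix


class QCError(ValueError):
    pass


@dataclass
class QCReport:
    """Audit record of what each filter removed."""

    genes_before: int = 0
    genes_after: int = 0
    removed_genes: list[str] = field(default_factory=list)
    samples_removed_detected: list[str] = field(default_factory=list)
    samples_removed_loso: list[str] = field(default_factory=list)
    loso_r: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "genes_before": self.genes_before,
            "genes_after": self.genes_after,
            "n_removed_genes": len(self.removed_genes),
            "samples_removed_detected": self.samples_removed_detected,
            "samples_removed_loso": self.samples_removed_loso,
            "loso_r": self.loso_r,
        }


def filter_low_abundance_genes(
    m: CountMatrix, min_count: int = 30, frac: float = 0.9
) -> tuple[CountMatrix, list[str]]:
    """Drop genes with < ``min_count`` reads in more than ``frac`` of samples.

    A gene survives as long as at least ``(1 - frac)`` of the cohort shows
    ``min_count`` or more intron-spanning reads for it.  Surviving gene
    order is preserved.
    """
    if m.n_genes == 0 or m.n_samples == 0:
        raise QCError("cannot gene-filter an empty count matrix")
    if not (0 < frac < 1):
        raise QCError(f"frac must be in (0, 1), got {frac}")
    if min_count < 0:
        raise QCError(f"min_count must be >= 0, got {min_count}")
    below = (m.counts.to_numpy() < min_count).sum(axis=1)
    keep = below <= frac * m.n_samples
    removed = list(m.gene_ids[~keep])
    return CountMatrix(m.counts.loc[keep]), removed


def count_detected_genes(m: CountMatrix, sample: str) -> int:
    """Number of genes with at least one intron-spanning read in ``sample``."""
    if sample not in m.sample_ids:
        raise QCError(f"unknown sample: {sample!r}")
    return int((m.counts[sample] >= 1).sum())


def filter_samples_by_detected_genes(
    m: CountMatrix, min_genes: int = 750
) -> tuple[CountMatrix, list[str]]:
    """Drop samples detecting fewer than ``min_genes`` spliced genes (strict <)."""
    if min_genes < 0:
        raise QCError(f"min_genes must be >= 0, got {min_genes}")
    detected = (m.counts >= 1).sum(axis=0)
    keep = detected >= min_genes
    removed = list(m.sample_ids[~keep])
    if not keep.any():
        raise QCError("detected-genes filter removed every sample")
    return CountMatrix(m.counts.loc[:, keep]), removed


def loso_cross_correlation(m: CountMatrix) -> pd.Series:
    """Leave-one-sample-out cross-correlation of CPM profiles.

    For each sample the reference is the per-gene median CPM over all other
    samples; the statistic is the Pearson correlation of the sample's own
    CPM vector with that reference.  Zero-variance vectors yield NaN.
    """
    if m.n_samples < 3:
        raise QCError("leave-one-sample-out correlation needs >= 3 samples")
    cpm = m.cpm().to_numpy()
    n = m.n_samples
    r = np.full(n, np.nan)
    for j in range(n):
        others = np.delete(cpm, j, axis=1)
        ref = np.median(others, axis=1)
        x, y = cpm[:, j], ref
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            warnings.warn(
                f"zero-variance profile for sample {m.sample_ids[j]!r}; "
                "leave-one-out correlation undefined"
            )
            continue
        r[j] = np.corrcoef(x, y)[0, 1]
    return pd.Series(r, index=m.sample_ids)


def loso_cross_correlation_filter(
    m: CountMatrix, threshold: float = 0.5
) -> tuple[CountMatrix, pd.Series, list[str]]:
    """Single-pass removal of samples with leave-one-out r below threshold.

    References are not recomputed after removals; an undefined (NaN)
    correlation counts as failing the filter.
    """
    r = loso_cross_correlation(m)
    fail = r.isna() | (r < threshold)
    removed = list(r.index[fail])
    if fail.all():
        raise QCError("cross-correlation filter removed every sample")
    return CountMatrix(m.counts.loc[:, ~fail.to_numpy()]), r, removed


def run_qc(
    m: CountMatrix,
    min_count: int = 30,
    frac: float = 0.9,
    min_genes: int = 750,
    loso_threshold: float = 0.5,
) -> tuple[CountMatrix, QCReport]:
    """Gene filter, then detected-genes filter, then leave-one-out filter."""
    report = QCReport(genes_before=m.n_genes)
    m, report.removed_genes = filter_low_abundance_genes(m, min_count, frac)
    report.genes_after = m.n_genes
    m, report.samples_removed_detected = filter_samples_by_detected_genes(
        m, min_genes
    )
    m, r, report.samples_removed_loso = loso_cross_correlation_filter(
        m, loso_threshold
    )
    report.loso_r = {k: float(v) for k, v in r.items()}
    return m, report
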