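"""Isoform-level differential analysis, exon-skipping PSI statistics, and
the P-selectin co-expression signature.

Isoform and percent-spliced-in (PSI) matrices come from an upstream
Bayesian isoform quantifier and are consumed here as inputs: an
isoform-by-sample table of assigned read counts with a parent-gene map,
and an event-by-sample table of PSI values in [0, 1] with the
inclusion/exclusion read counts supporting each value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import diff_splicing
from .core_io import CountMatrix
from .normalize import tmm_factors


@dataclass
class IsoformCounts:
    """Isoform-by-sample assigned read counts plus a parent-gene map."""

    counts: pd.DataFrame  # isoforms x samples
    parent_gene: pd.Series  # isoform -> gene id

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.parent_gene.index):
            self.parent_gene = self.parent_gene.loc[self.counts.index]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("isoform counts must be non-negative")


@dataclass
class PSIMatrix:
    """Skipped-exon events: PSI in [0, 1] plus supporting read counts."""

    psi: pd.DataFrame  # events x samples, may contain NaN
    inclusion: pd.DataFrame
    exclusion: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.psi.to_numpy()
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
        if not ok.all():
            raise ValueError("PSI values must lie in [0, 1] where present")


def filter_isoforms(
    ic: IsoformCounts, min_reads: int = 10, frac: float = 0.9
) -> IsoformCounts:
    """Drop isoforms with < ``min_reads`` in more than ``frac`` of samples."""
    below = (ic.counts.to_numpy() < min_reads).sum(axis=1)
    keep = below <= frac * ic.counts.shape[1]
    return IsoformCounts(ic.counts.loc[keep], ic.parent_gene.loc[keep])


def diff_isoforms(
    ic: IsoformCounts,
    group: pd.Series,
    min_logcpm: float = 1.0,
    max_fdr: float = 0.01,
    prior_weight: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB LRT per isoform with TMM+CPM normalization, then FDR/logCPM cut.

    Returns the full result table and the selected subset (FDR < 0.01 and
    logCPM > 1 by default) with up/down counts in ``attrs``.
    """
    cm = CountMatrix(ic.counts.astype(np.int64))
    ref_idx = int(np.argmin(np.abs(
        cm.lib_size - cm.lib_size.median()
    )))
    factors, _ = tmm_factors(ic.counts.astype(float), str(cm.sample_ids[ref_idx]))
    eff_lib = cm.lib_size.astype(float) * factors
    table, _, _ = diff_splicing.differential_splicing(
        ic.counts, group, eff_lib, min_logcpm=-np.inf, max_fdr=1.1,
        prior_weight=prior_weight,
    )
    selected = table[(table["FDR"] < max_fdr) & (table["logCPM"] > min_logcpm)]
    selected.attrs["n_up"] = int((selected["logFC"] > 0).sum())
    selected.attrs["n_down"] = int((selected["logFC"] < 0).sum())
    return table, selected


def classify_locus_patterns(
    ic: IsoformCounts,
    selected_isoforms: list[str],
    group: pd.Series,
) -> pd.Series:
    """Label each parent locus concordant_up / concordant_down / alternative.

    Per selected isoform the sign of the group-median difference is taken;
    a locus whose selected isoforms all move the same way is concordant,
    mixed signs mark potential alternative isoform usage.  A zero median
    difference is treated as concordant with either direction.
    """
    group = group.loc[ic.counts.columns]
    levels = sorted(pd.unique(group.dropna()))
    sub = ic.counts.loc[selected_isoforms]
    med1 = sub.loc[:, (group == levels[0]).to_numpy()].median(axis=1)
    med2 = sub.loc[:, (group == levels[1]).to_numpy()].median(axis=1)
    sign = np.sign(med2 - med1)
    labels = {}
    for gene, iso_signs in sign.groupby(ic.parent_gene.loc[selected_isoforms]):
        nonzero = iso_signs[iso_signs != 0]
        if len(nonzero) == 0:
            labels[gene] = "concordant_up"  # all flat: tie rule
        elif (nonzero > 0).all():
            labels[gene] = "concordant_up"
        elif (nonzero < 0).all():
            labels[gene] = "concordant_down"
        else:
            labels[gene] = "alternative"
    return pd.Series(labels, name="pattern")


def exon_coverage_filter(
    psi: PSIMatrix, min_reads: int = 10, frac: float = 0.6
) -> PSIMatrix:
    """Keep events well covered with evidence for both inclusion and exclusion.

    A sample supports an event when its total assigned reads exceed
    ``min_reads`` AND both inclusion and exclusion reads are nonzero; the
    event survives when strictly more than ``frac`` of samples support it.
    """
    inc = psi.inclusion.to_numpy(dtype=float)
    exc = psi.exclusion.to_numpy(dtype=float)
    supports = ((inc + exc) > min_reads) & (inc > 0) & (exc > 0)
    keep = supports.sum(axis=1) > frac * psi.psi.shape[1]
    return PSIMatrix(
        psi.psi.loc[keep], psi.inclusion.loc[keep], psi.exclusion.loc[keep]
    )


def exon_skipping_test(
    psi: PSIMatrix, group: pd.Series, max_fdr: float = 0.01, ref_level=None
) -> pd.DataFrame:
    """Per-event Welch t-test on PSI between groups with BH-FDR and delta-PSI.

    ``delta_psi`` is the group-2 median PSI minus the group-1 median
    (positive favors inclusion in group 2).  Events missing in a whole
    group are skipped with a warning.
    """
    group = group.loc[psi.psi.columns]
    levels = sorted(pd.unique(group.dropna()))
    if ref_level is not None:
        levels = [ref_level] + [l for l in levels if l != ref_level]
    g1 = (group == levels[0]).to_numpy()
    g2 = (group == levels[1]).to_numpy()
    rows = []
    skipped = 0
    for event, vals in psi.psi.iterrows():
        a = vals.to_numpy()[g1]
        b = vals.to_numpy()[g2]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size < 2 or b.size < 2:
            skipped += 1
            continue
        t, p = stats.ttest_ind(b, a, equal_var=False)
        rows.append((event, float(t), float(p),
                     float(np.median(b) - np.median(a))))
    if skipped:
        warnings.warn(f"{skipped} events lacked >= 2 PSI values per group")
    out = pd.DataFrame(
        rows, columns=["event_id", "t", "p", "delta_psi"]
    ).set_index("event_id")
    out["FDR"] = diff_splicing.bh_adjust(out["p"].to_numpy())
    sig = out[out["FDR"] < max_fdr]
    out.attrs["n_inclusion"] = int((sig["delta_psi"] > 0).sum())
    out.attrs["n_exclusion"] = int((sig["delta_psi"] < 0).sum())
    out.attrs["levels"] = levels
    return out


def target_gene_signature(
    log_mat: pd.DataFrame,
    target_gene: str,
    up_set: list[str] | None = None,
    max_fdr: float = 0.01,
) -> tuple[pd.DataFrame, list[str], dict]:
    """Co-expression signature of a target gene (e.g. P-selectin / SELP).

    Every gene's logCPM profile is Pearson-correlated with the target's;
    the signature keeps positively (r > 0) and significantly (BH-FDR <
    0.01) correlated genes.  When an up-regulated differential set is
    supplied, the overlap (Venn counts) is reported alongside.
    """
    if target_gene not in log_mat.index:
        raise ValueError(f"target gene {target_gene!r} not in the matrix")
    y = log_mat.loc[target_gene].to_numpy()
    if y.std() == 0:
        raise ValueError("target gene has zero variance")
    X = log_mat.to_numpy()
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=1) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = Xc @ yc / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, np.where(np.isfinite(t), p, 0.0))
    table = pd.DataFrame({"r": r, "p": p}, index=log_mat.index)
    ok = table["p"].notna()
    table["FDR"] = np.nan
    table.loc[ok, "FDR"] = diff_splicing.bh_adjust(table.loc[ok, "p"].to_numpy())
    signature = list(table.index[(table["r"] > 0) & (table["FDR"] < max_fdr)])
    overlap: dict = {"signature_size": len(signature)}
    if up_set is not None:
        inter = set(signature) & set(up_set)
        overlap |= {
            "up_set_size": len(up_set),
            "overlap": len(inter),
            "up_only": len(set(up_set) - inter),
            "signature_only": len(set(signature) - inter),
        }
    return table, signature, overlap
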