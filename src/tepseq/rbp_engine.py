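"""RBP motif search in UTRs and binding-site / fold-change correlation.

RNA-binding proteins (RBPs) are characterized by short degenerate
(IUPAC-coded) sequence motifs.  The engine (i) extracts 5' and 3' UTR
sequences of the genes detected in platelets from a reference genome and
gene annotation, (ii) deconvolutes each RBP's IUPAC motifs into
non-redundant A/C/G/T strings, (iii) counts motif occurrences in every
UTR, (iv) discards UTRs with insufficient read coverage (>= 3 reads for
5' UTRs, >= 5 for 3' UTRs), (v) sums hits per gene and side, and finally
correlates the per-gene number of binding sites with the differential-
splicing log fold-change of that gene, per RBP and UTR side.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diff_splicing import bh_adjust

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MotifError(ValueError):
    pass


@dataclass
class RBPMotifSet:
    rbp_id: str
    iupac_motifs: list[str]
    expanded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.expanded:
            self.expanded = expand_motif_set(self.iupac_motifs)


@dataclass
class UTRRecord:
    gene_id: str
    transcript_id: str
    side: str  # five_prime | three_prime
    sequence: str
    read_count: int = 0

    def __post_init__(self) -> None:
        if self.side not in ("five_prime", "three_prime"):
            raise ValueError(f"invalid UTR side: {self.side!r}")
        if not self.sequence:
            raise ValueError("empty UTR sequence")


def iupac_expand(motif: str) -> list[str]:
    """All A/C/G/T strings matching one IUPAC motif (Cartesian expansion).

    The number of expansions equals the product of per-symbol degeneracies.
    """
    motif = motif.upper()
    pools = []
    for i, sym in enumerate(motif):
        if sym not in IUPAC:
            raise MotifError(f"invalid IUPAC symbol {sym!r} at position {i}")
        pools.append(IUPAC[sym])
    return ["".join(p) for p in itertools.product(*pools)]


def expand_motif_set(motifs: list[str]) -> list[str]:
    """Expand a motif list and deduplicate across the set, order-preserving."""
    seen: dict[str, None] = {}
    for m in motifs:
        for s in iupac_expand(m):
            seen.setdefault(s)
    return list(seen)


def parse_motif_table(path) -> list[RBPMotifSet]:
    """Read a motif compendium TSV (species, rbp_id, motif) -> human RBP sets.

    Rows are filtered to Homo sapiens, grouped by RBP, motifs uppercased
    and U converted to T.  A motif with a symbol outside the IUPAC
    alphabet raises an error naming the row.
    """
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if tab.empty:
        return []
    cols = {c.lower(): c for c in tab.columns}
    species_c = cols.get("species")
    rbp_c = cols.get("rbp_id") or cols.get("rbp")
    motif_c = cols.get("motif")
    if not (species_c and rbp_c and motif_c):
        raise MotifError(
            "motif table needs species, rbp_id and motif columns; "
            f"found {list(tab.columns)}"
        )
    human = tab[
        tab[species_c].str.contains("sapiens", case=False, na=False)
    ]
    sets = []
    for rbp, grp in human.groupby(rbp_c, sort=False):
        motifs = [str(m).upper().replace("U", "T") for m in grp[motif_c]]
        for row, m in zip(grp.index, motifs):
            bad = [c for c in m if c not in IUPAC]
            if bad:
                raise MotifError(
                    f"row {row}: motif {m!r} has non-IUPAC symbol {bad[0]!r}"
                )
        sets.append(RBPMotifSet(rbp_id=str(rbp), iupac_motifs=motifs))
    return sets


def count_motif_hits(sequence: str, expanded: list[str]) -> int:
    """Total non-overlapping, left-to-right occurrences of a motif set.

    Counts each expanded A/C/G/T string separately and sums; N in the
    sequence never matches (motif strings contain no N).
    """
    seq = sequence.upper()
    return sum(seq.count(m) for m in expanded)


# ---------------------------------------------------------------------------
# UTR extraction
# ---------------------------------------------------------------------------


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_utrs(
    genome_fasta, gtf_path, gene_set: set[str] | None = None
) -> list[UTRRecord]:
    """UTR sequences per transcript and side from a genome FASTA + GTF.

    UTR features are taken from the annotation where present, otherwise
    derived as the exonic sequence outside the CDS span.  Per transcript
    and side the genomic pieces are concatenated in transcript orientation
    (minus-strand transcripts reverse-complemented); coordinates are
    handled half-open 0-based internally.  Transcripts without a CDS are
    skipped with a warning.
    """
    import gffutils
    from pyfaidx import Fasta

    db = gffutils.create_db(
        str(gtf_path), ":memory:", merge_strategy="create_unique",
        keep_order=True, disable_infer_genes=True, disable_infer_transcripts=True,
    )
    fasta = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    records: list[UTRRecord] = []
    skipped = 0
    for tx in db.features_of_type("transcript"):
        gene_id = tx.attributes.get("gene_id", ["?"])[0]
        if gene_set is not None and gene_id not in gene_set:
            continue
        tx_id = tx.attributes.get("transcript_id", [tx.id])[0]
        exons = sorted(
            db.children(tx, featuretype="exon"), key=lambda f: f.start
        )
        cds = sorted(db.children(tx, featuretype="CDS"), key=lambda f: f.start)
        if not exons:
            continue
        if not cds:
            skipped += 1
            continue
        cds_lo = min(c.start for c in cds) - 1  # to 0-based
        cds_hi = max(c.end for c in cds)
        left_parts, right_parts = [], []
        for ex in exons:
            lo, hi = ex.start - 1, ex.end
            seq = fasta[ex.seqid][lo:hi]
            if hi <= cds_lo:
                left_parts.append(seq)
            elif lo >= cds_hi:
                right_parts.append(seq)
            else:
                if lo < cds_lo:
                    left_parts.append(seq[: cds_lo - lo])
                if hi > cds_hi:
                    right_parts.append(seq[cds_hi - lo:])
        left = "".join(left_parts)
        right = "".join(right_parts)
        if tx.strand == "-":
            five, three = _revcomp(right), _revcomp(left)
        else:
            five, three = left, right
        if five:
            records.append(UTRRecord(gene_id, tx_id, "five_prime", five))
        if three:
            records.append(UTRRecord(gene_id, tx_id, "three_prime", three))
    if skipped:
        warnings.warn(f"{skipped} transcripts without CDS skipped")
    return records


# ---------------------------------------------------------------------------
# Coverage gating + aggregation
# ---------------------------------------------------------------------------


def utr_coverage_filter(
    records: list[UTRRecord], min_5p: int = 3, min_3p: int = 5
) -> list[UTRRecord]:
    """Keep UTRs confidently present in platelets (read_count >= threshold).

    5' UTRs need >= 3 reads and 3' UTRs >= 5 (the 3' bar is higher to
    offset the oligo-dT amplification bias toward transcript 3' ends).
    """
    out = []
    for rec in records:
        bar = min_5p if rec.side == "five_prime" else min_3p
        if rec.read_count >= bar:
            out.append(rec)
    return out


def aggregate_gene_level(
    records: list[UTRRecord], motif_sets: list[RBPMotifSet]
) -> pd.DataFrame:
    """Sum motif hits over transcripts: long table (gene, side, rbp, hits)."""
    rows = []
    for rec in records:
        for ms in motif_sets:
            hits = count_motif_hits(rec.sequence, ms.expanded)
            rows.append((rec.gene_id, rec.side, ms.rbp_id, hits))
    long = pd.DataFrame(rows, columns=["gene_id", "side", "rbp_id", "hits"])
    return (
        long.groupby(["gene_id", "side", "rbp_id"], sort=False)["hits"]
        .sum()
        .reset_index()
    )


def rbp_expression_filter(
    motif_sets: list[RBPMotifSet],
    gene_universe: set[str],
    rbp_to_gene: dict[str, str] | None = None,
) -> list[RBPMotifSet]:
    """Keep RBPs whose own transcript passes the cohort abundance filter.

    ``rbp_to_gene`` maps RBP identifiers to count-matrix gene ids; by
    default the RBP id itself is looked up.  Unmappable ids are dropped
    with a warning.
    """
    kept = []
    unmapped = []
    for ms in motif_sets:
        gid = (rbp_to_gene or {}).get(ms.rbp_id, ms.rbp_id)
        if gid is None:
            unmapped.append(ms.rbp_id)
            continue
        if gid in gene_universe:
            kept.append(ms)
    if unmapped:
        warnings.warn(f"unmappable RBP ids dropped: {unmapped}")
    return kept


def tropism_summary(gene_hits: pd.DataFrame) -> pd.DataFrame:
    """Per-RBP mean binding sites in 5' vs 3' UTRs (UTR tropism)."""
    means = (
        gene_hits.groupby(["rbp_id", "side"])["hits"].mean().unstack(fill_value=0.0)
    )
    for side in ("five_prime", "three_prime"):
        if side not in means.columns:
            means[side] = 0.0
    return means[["five_prime", "three_prime"]]


def correlate_sites_logfc(
    gene_hits: pd.DataFrame, logfc: pd.Series, method: str = "pearson"
) -> pd.DataFrame:
    """Correlate per-gene binding-site counts with differential log fold-change.

    Per (RBP, side) the site counts of all genes shared with the
    fold-change table are correlated (Pearson by default, Spearman
    optional); p-values are BH-adjusted within each UTR side.
    Zero-variance site vectors are excluded with a warning.
    """
    rows = []
    for (rbp, side), grp in gene_hits.groupby(["rbp_id", "side"]):
        merged = grp.set_index("gene_id")["hits"].to_frame().join(
            logfc.rename("logFC"), how="inner"
        ).dropna()
        if len(merged) < 3:
            continue
        x = merged["hits"].to_numpy(dtype=float)
        y = merged["logFC"].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            warnings.warn(f"zero-variance site counts for {rbp}/{side}; skipped")
            continue
        if method == "pearson":
            r, p = stats.pearsonr(x, y)
        elif method == "spearman":
            r, p = stats.spearmanr(x, y)
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        rows.append((rbp, side, float(r), float(p), len(merged)))
    out = pd.DataFrame(rows, columns=["rbp_id", "side", "r", "p", "n_genes"])
    out["FDR"] = np.nan
    for side in out["side"].unique():
        mask = out["side"] == side
        out.loc[mask, "FDR"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    return out
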