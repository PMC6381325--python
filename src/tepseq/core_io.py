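"""Data model and I/O for platelet spliced-RNA count tables and annotations.

The central container is :class:`CountMatrix`: a genes-by-samples table of
intron-spanning read counts.  Only reads that span an exon-exon junction are
counted upstream, so a "count" here is direct evidence of a spliced
transcript.  Per-sample library sizes are the column sums of this table and
are kept consistent with the counts at all times.

Sample metadata travels alongside as :class:`SampleAnnotation`, one row per
sample with the clinical covariates the pipeline consumes (group, age,
blood-storage stratum, smoking, gender, cohort role).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SERIAL_FORMAT_VERSION = 1

ANNOTATION_COLUMNS = [
    "sample_id",
    "group",
    "age",
    "storage",
    "gender",
    "smoking",
    "cohort_role",
    "site",
]


class DataFormatError(ValueError):
    """Raised when an input table violates the count/annotation contract."""


@dataclass
class CountMatrix:
    """Genes-by-samples integer count matrix with per-sample library sizes.

    Counts are stored genes-as-rows; every per-sample statistic is a column
    reduction.  Gene and sample order is preserved from the source file --
    downstream tie-breaking depends on it, so no implicit sorting happens
    anywhere.
    """

    counts: pd.DataFrame  # genes x samples, integer dtype

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()][0]
            raise DataFormatError(f"duplicate gene id: {dup!r}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()][0]
            raise DataFormatError(f"duplicate sample id: {dup!r}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values), atol=0, rtol=0):
                g, s = np.argwhere(values != np.round(values))[0]
                raise DataFormatError(
                    f"non-integer count at gene {counts.index[g]!r}, "
                    f"sample {counts.columns[s]!r}"
                )
            counts = counts.astype(np.int64)
            object.__setattr__(self, "counts", counts)
            values = counts.to_numpy()
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise DataFormatError(
                f"negative count at gene {counts.index[g]!r}, "
                f"sample {counts.columns[s]!r}"
            )
        # canonical memory layout: downstream linear algebra must give
        # bit-identical results regardless of how the frame was assembled
        if not values.flags["C_CONTIGUOUS"]:
            object.__setattr__(
                self,
                "counts",
                pd.DataFrame(
                    np.ascontiguousarray(values),
                    index=counts.index,
                    columns=counts.columns,
                ),
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def lib_size(self) -> pd.Series:
        """Per-sample total intron-spanning reads (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "CountMatrix":
        genes = list(genes)
        return CountMatrix(self.counts.loc[genes])

    def subset_samples(self, samples: Iterable[str]) -> "CountMatrix":
        samples = list(samples)
        return CountMatrix(self.counts[samples])

    def cpm(self) -> pd.DataFrame:
        """Plain counts-per-million on raw counts (no TMM, no correction)."""
        lib = self.lib_size.to_numpy(dtype=float)
        lib = np.where(lib == 0, 1.0, lib)
        return self.counts / lib * 1e6

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts)


@dataclass
class SampleAnnotation:
    """One clinical record per sample.

    ``cohort_role`` partitions samples into training / evaluation /
    validation; the roles are disjoint by construction (one row per sample).
    Missing ages are NaN and every consumer states how it treats them.
    """

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise DataFormatError(f"duplicate annotation for sample {dup!r}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def group(self, samples: Iterable[str] | None = None) -> pd.Series:
        g = self.table["group"]
        return g if samples is None else g.loc[list(samples)]

    def age(self, samples: Iterable[str] | None = None) -> pd.Series:
        a = pd.to_numeric(self.table["age"], errors="coerce")
        return a if samples is None else a.loc[list(samples)]

    def role_samples(self, role: str) -> list[str]:
        return list(self.table.index[self.table["cohort_role"] == role])

    def subset(self, samples: Iterable[str]) -> "SampleAnnotation":
        return SampleAnnotation(self.table.loc[list(samples)])


def load_counts(
    counts_path: str | Path, annotation_path: str | Path
) -> tuple[CountMatrix, SampleAnnotation]:
    """Read a genes-by-samples TSV plus its sample-annotation CSV.

    The count table header row holds sample ids and the first column holds
    gene ids.  Every sample in the count table must be annotated; samples
    without an annotation record are rejected rather than silently kept.
    """
    raw = pd.read_csv(counts_path, sep="\t", index_col=0)
    # validate cell contents before the integer cast so the error names
    # the offending cell
    for col in raw.columns:
        vals = pd.to_numeric(raw[col], errors="coerce")
        if vals.isna().any():
            gene = raw.index[vals.isna().to_numpy().argmax()]
            raise DataFormatError(
                f"non-numeric count at gene {gene!r}, sample {col!r}"
            )
    matrix = CountMatrix(raw)
    ann_raw = pd.read_csv(annotation_path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann_raw.columns]
    if missing:
        raise DataFormatError(f"annotation is missing columns: {missing}")
    ann = SampleAnnotation(ann_raw.set_index("sample_id"))
    unannotated = matrix.sample_ids.difference(ann.sample_ids)
    if len(unannotated):
        raise DataFormatError(
            f"samples without annotation: {sorted(unannotated)}"
        )
    return matrix, ann.subset(matrix.sample_ids)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t")


def write_annotation(ann: SampleAnnotation, path: str | Path) -> None:
    ann.table.reset_index(names="sample_id").to_csv(path, index=False)


def merge_technical_replicates(a: pd.Series, b: pd.Series) -> pd.Series:
    """Sum two count columns for the same sample (re-sequencing merge).

    Samples with a shallow first run are re-sequenced and the two per-gene
    count vectors added after summarization; merging happens before any
    gene or sample filtering.  The gene universes must match exactly.
    """
    if len(a.index) != len(b.index) or not a.index.equals(b.index):
        if set(a.index) == set(b.index):
            b = b.reindex(a.index)
        else:
            raise DataFormatError(
                "technical replicates have mismatched gene sets"
            )
    return a + b


# ---------------------------------------------------------------------------
# Model serialization: JSON archives with a format-version field.
# Floats go through repr round-tripping, so reals survive within 1e-12
# (in fact exactly); integer payloads are bit-exact.
# ---------------------------------------------------------------------------


def _encode(obj):
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist(), "dtype": str(obj.dtype)}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.Series):
        return {
            "__series__": obj.to_numpy().tolist(),
            "index": list(map(str, obj.index)),
            "dtype": str(obj.dtype),
        }
    if isinstance(obj, pd.DataFrame):
        return {
            "__frame__": obj.to_numpy().tolist(),
            "index": list(map(str, obj.index)),
            "columns": list(map(str, obj.columns)),
            "dtype": str(obj.to_numpy().dtype),
        }
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            "__dataclass__": type(obj).__name__,
            "fields": {
                f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)
            },
        }
    raise TypeError(f"cannot serialize {type(obj)!r}")


def _decode(d: dict):
    if "__ndarray__" in d:
        return np.asarray(d["__ndarray__"], dtype=d["dtype"])
    if "__series__" in d:
        return pd.Series(
            np.asarray(d["__series__"], dtype=d["dtype"]), index=d["index"]
        )
    if "__frame__" in d:
        return pd.DataFrame(
            np.asarray(d["__frame__"], dtype=d["dtype"]),
            index=d["index"],
            columns=d["columns"],
        )
    return d


def save_model(payload: Mapping, path: str | Path, kind: str) -> None:
    """Write a model archive (JSON, single file) with a version stamp."""
    archive = {
        "format_version": SERIAL_FORMAT_VERSION,
        "kind": kind,
        "payload": payload,
    }
    Path(path).write_text(json.dumps(archive, default=_encode))


def load_model(path: str | Path, kind: str | None = None) -> dict:
    archive = json.loads(Path(path).read_text(), object_hook=_decode)
    if archive.get("format_version") != SERIAL_FORMAT_VERSION:
        raise DataFormatError(
            f"unsupported model format version: {archive.get('format_version')}"
        )
    if kind is not None and archive.get("kind") != kind:
        raise DataFormatError(
            f"expected a {kind!r} archive, found {archive.get('kind')!r}"
        )
    return archive["payload"]
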