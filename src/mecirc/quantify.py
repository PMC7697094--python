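"""Multi-sample count matrices, CPM normalization and abundance filters.

Two filters mirror standard practice for lowly expressed circRNAs: a CPM
floor (>= 0.01 counts-per-million in at least three samples) and a raw-count
floor (>= 2 unique backsplice reads in at least three samples). Both keep a
junction row iff enough samples individually clear the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .chimera import CircRNACall

logger = logging.getLogger(__name__)

CIRCEXPLORER_COLS = [
    "chrom",
    "start",
    "end",
    "strand",
    "gene_id",
    "read_count",
    "exon_list",
    "kind",
    "insert_seq",
]


def junction_row_id(call: CircRNACall) -> str:
    return f"{call.gene_id}|{call.exon_list[0]}|{call.exon_list[-1]}|{call.insert_seq}"


@dataclass
class CountMatrix:
    """Junction-by-sample read counts plus per-sample library sizes."""

    counts: pd.DataFrame  # rows: junction ids; columns: sample ids; int
    library_sizes: pd.Series  # per sample, total reads

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        colsum = self.counts.sum(axis=0)
        bad = self.library_sizes[self.library_sizes < colsum]
        if len(bad):
            raise ValueError(f"library size below column sum for {list(bad.index)}")

    @property
    def n_junctions(self) -> int:
        return len(self.counts)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def build_matrix(
    per_sample_calls: dict[str, list[CircRNACall]],
    library_sizes: dict[str, int] | None = None,
) -> CountMatrix:
    """Assemble the union-of-junctions count matrix over samples.

    Junctions absent from a sample get a structural zero. Library size is the
    user-supplied total read count per sample, defaulting to the column sum
    (logged) when not provided.
    """
    if not per_sample_calls:
        raise ValueError("at least one sample required")
    samples = list(per_sample_calls)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample id")
    data: dict[str, dict[str, int]] = {}
    for sample, calls in per_sample_calls.items():
        col: dict[str, int] = {}
        for c in calls:
            rid = junction_row_id(c)
            if rid in col:
                raise ValueError(f"duplicate junction {rid} in sample {sample}")
            col[rid] = c.read_count
        data[sample] = col
    counts = pd.DataFrame(data).fillna(0).astype(int)
    counts = counts.sort_index()
    if library_sizes is None:
        libs = counts.sum(axis=0)
        logger.info("library sizes not supplied; using per-sample column sums")
    else:
        libs = pd.Series({s: int(library_sizes[s]) for s in samples})
    return CountMatrix(counts=counts, library_sizes=libs.loc[counts.columns])


def cpm(matrix: CountMatrix) -> pd.DataFrame:
    """Counts per million: count / library_size * 1e6."""
    if (matrix.library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return matrix.counts / matrix.library_sizes * 1e6


def filter_low(
    matrix: CountMatrix, cpm_min: float = 0.01, min_samples: int = 3
) -> CountMatrix:
    """Keep junctions with CPM >= cpm_min in at least min_samples samples."""
    if cpm_min <= 0 or min_samples <= 0:
        raise ValueError("thresholds must be positive")
    if min_samples > len(matrix.samples):
        logger.warning(
            "min_samples=%d exceeds n_samples=%d; nothing kept",
            min_samples,
            len(matrix.samples),
        )
    keep = (cpm(matrix) >= cpm_min).sum(axis=1) >= min_samples
    logger.info("filter_low: kept %d/%d junctions", int(keep.sum()), len(keep))
    return CountMatrix(matrix.counts.loc[keep], matrix.library_sizes)


def filter_min_reads(
    matrix: CountMatrix, min_reads: int = 2, min_samples: int = 3
) -> CountMatrix:
    """Keep junctions with >= min_reads unique reads in >= min_samples samples."""
    if min_reads <= 0 or min_samples <= 0:
        raise ValueError("thresholds must be positive")
    if min_samples > len(matrix.samples):
        logger.warning(
            "min_samples=%d exceeds n_samples=%d; nothing kept",
            min_samples,
            len(matrix.samples),
        )
    keep = (matrix.counts >= min_reads).sum(axis=1) >= min_samples
    logger.info("filter_min_reads: kept %d/%d junctions", int(keep.sum()), len(keep))
    return CountMatrix(matrix.counts.loc[keep], matrix.library_sizes)


def write_circexplorer_like(calls: list[CircRNACall], path) -> None:
    """Write calls as a TSV whose first six columns are BED6-compatible.

    Columns: chrom, start, end, strand, gene_id, read_count, exon_list
    (comma-joined), kind, insert_seq.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(CIRCEXPLORER_COLS) + "\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.strand}\t{c.gene_id}\t"
                f"{c.read_count}\t{','.join(map(str, c.exon_list))}\t{c.kind}\t"
                f"{c.insert_seq}\n"
            )


def read_circexplorer_like(path) -> list[CircRNACall]:
    df = pd.read_csv(path, sep="\t", dtype={"insert_seq": str}, keep_default_na=False)
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            CircRNACall(
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                gene_id=str(row.gene_id),
                exon_list=tuple(int(x) for x in str(row.exon_list).split(",")),
                kind=str(row.kind),
                insert_seq=str(row.insert_seq),
                read_count=int(row.read_count),
            )
        )
    return calls


def write_matrix(matrix: CountMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("# library_sizes\t")
        fh.write("\t".join(f"{s}={int(v)}" for s, v in matrix.library_sizes.items()))
        fh.write("\n")
        matrix.counts.to_csv(fh, sep="\t", index_label="junction")


def read_matrix(path) -> CountMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        libs = {}
        for tok in header.split("\t")[1:]:
            s, v = tok.split("=")
            libs[s] = int(v)
        counts = pd.read_csv(fh, sep="\t", index_col="junction")
    counts.index.name = None
    return CountMatrix(counts=counts.astype(int), library_sizes=pd.Series(libs))
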