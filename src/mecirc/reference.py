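"""Strand-aware exon/intron reference built from genome FASTA + GTF gene models.

All coordinates are 0-based half-open internally. GTF input is 1-based
inclusive and converted on load; BED input is taken as-is. Exon sequences are
stored in transcript orientation (reverse-complemented for minus-strand
genes), and ``exon_index`` counts 1-based from the transcript 5' end, so that
"downstream" always means a larger index regardless of genomic strand.

Multi-transcript genes are collapsed to the exons of the longest annotated
transcript (by summed exon length), which fixes a single canonical exon
numbering per gene.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pyfaidx

from ._seq import fetch, revcomp

logger = logging.getLogger(__name__)

MIN_ME_LEN = 3
MAX_ME_LEN = 30


@dataclass(frozen=True)
class ExonRecord:
    """One exon of a gene model, with its transcript-oriented sequence."""

    gene_id: str
    exon_index: int  # 1-based, transcript 5' -> 3'
    chrom: str
    start: int  # genomic, 0-based half-open
    end: int
    strand: str
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"exon {self.gene_id}:{self.exon_index} has end <= start")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"exon {self.gene_id}:{self.exon_index} sequence length mismatch"
            )
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class GeneModel:
    """Ordered exons of one gene plus derived intron intervals."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[ExonRecord]

    def __post_init__(self) -> None:
        idx = [e.exon_index for e in self.exons]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError(f"{self.gene_id}: exon_index not strictly increasing")
        starts = [e.start for e in self.exons]
        if self.strand == "+":
            if starts != sorted(starts):
                raise ValueError(f"{self.gene_id}: + strand exon starts not ascending")
        else:
            if starts != sorted(starts, reverse=True):
                raise ValueError(f"{self.gene_id}: - strand exon starts not descending")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon(self, exon_index: int) -> ExonRecord:
        e = self.exons[exon_index - 1]
        assert e.exon_index == exon_index
        return e

    @property
    def span(self) -> tuple[int, int]:
        return (min(e.start for e in self.exons), max(e.end for e in self.exons))

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic intervals between consecutive exons, in transcript order.

        Intron i (1-based) separates exon i from exon i+1.
        """
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((a.end, b.start))
            else:
                out.append((b.end, a.start))
        return out

    def intron_sequence(self, intron_index: int, genome) -> str:
        """Transcript-oriented sequence of intron ``intron_index`` (1-based)."""
        s, e = self.introns[intron_index - 1]
        seq = fetch(genome, self.chrom, s, e)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass(frozen=True)
class KnownME:
    """A catalogued microexon from linear mRNA annotation (BED6 record)."""

    chrom: str
    start: int
    end: int
    strand: str
    me_id: str
    gene_id: str = ""
    nonstandard_length: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ExonIndex:
    """Exact k-mer index over transcript-oriented exon sequences."""

    k: int
    postings: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    @property
    def n_postings(self) -> int:
        return sum(len(v) for v in self.postings.values())

    def lookup(self, kmer: str) -> list[tuple[str, int, int]]:
        return self.postings.get(kmer, [])


def load_gene_models(gtf_path, fasta_path) -> dict[str, GeneModel]:
    """Load gene models from a GTF (exon features) and an indexed FASTA.

    Returns a dict gene_id -> GeneModel. Multi-transcript genes collapse to
    the longest transcript's exons (logged). A chrom present in the GTF but
    absent from the FASTA is a hard error naming the chrom.
    """
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    genome = pyfaidx.Fasta(str(fasta_path), sequence_always_upper=True)

    # group exon features by (gene_id, transcript_id)
    by_tx: dict[tuple[str, str], list] = {}
    for ex in db.features_of_type("exon"):
        gid = ex.attributes.get("gene_id", [ex.id])[0]
        tid = ex.attributes.get("transcript_id", [gid])[0]
        by_tx.setdefault((gid, tid), []).append(ex)

    # pick the longest transcript per gene
    best: dict[str, list] = {}
    for (gid, tid), exons in by_tx.items():
        total = sum(ex.end - ex.start + 1 for ex in exons)
        if gid not in best or total > best[gid][0]:
            best[gid] = [total, tid, exons]
    models: dict[str, GeneModel] = {}
    for gid, (_, tid, exons) in sorted(best.items()):
        n_tx = sum(1 for (g, _t) in by_tx if g == gid)
        if n_tx > 1:
            logger.info("gene %s: %d transcripts, collapsed to longest (%s)", gid, n_tx, tid)
        chrom = exons[0].seqid
        strand = exons[0].strand
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom!r} (gene {gid}) missing from FASTA")
        ivals = sorted((ex.start - 1, ex.end) for ex in exons)  # GTF 1-based incl.
        if strand == "-":
            ivals = ivals[::-1]
        recs = []
        for i, (s, e) in enumerate(ivals, start=1):
            seq = str(genome[chrom][s:e])
            if strand == "-":
                seq = revcomp(seq)
            recs.append(ExonRecord(gid, i, chrom, s, e, strand, seq))
        models[gid] = GeneModel(gid, chrom, strand, recs)
    return models


def build_exon_index(models: dict[str, GeneModel], k: int = 12) -> ExonIndex:
    """Index every full k-mer of every exon sequence (transcript orientation)."""
    if k < 8:
        raise ValueError("k must be >= 8")
    postings: dict[str, list[tuple[str, int, int]]] = {}
    for gid in sorted(models):
        for ex in models[gid].exons:
            seq = ex.sequence
            for off in range(len(seq) - k + 1):
                postings.setdefault(seq[off : off + k], []).append(
                    (gid, ex.exon_index, off)
                )
    return ExonIndex(k=k, postings=postings)


def load_known_mes(bed_path) -> list[KnownME]:
    """Load a known-microexon catalogue from BED6 (name column = me_id).

    Records outside the 3-30 nt microexon band are kept but flagged
    ``nonstandard_length`` with a warning; the band governs de novo calls,
    not external catalogues. Output is sorted by (chrom, start).
    """
    out: list[KnownME] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{bed_path}: line {lineno}: expected BED6, got {len(parts)} fields")
            try:
                chrom, start, end, name, _score, strand = parts[:6]
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{bed_path}: line {lineno}: {exc}") from exc
            if end_i <= start_i:
                raise ValueError(f"{bed_path}: line {lineno}: end <= start")
            if strand not in "+-":
                raise ValueError(f"{bed_path}: line {lineno}: bad strand {strand!r}")
            length = end_i - start_i
            nonstd = not (MIN_ME_LEN <= length <= MAX_ME_LEN)
            if nonstd:
                warnings.warn(
                    f"known ME {name} has nonstandard length {length} nt (kept, flagged)",
                    stacklevel=2,
                )
            gene_id = parts[6] if len(parts) > 6 else ""
            out.append(KnownME(chrom, start_i, end_i, strand, name, gene_id, nonstd))
    out.sort(key=lambda m: (m.chrom, m.start))
    return out


# ---------------------------------------------------------------------------
# flat-file reference bundle: exon table TSV + meta JSON (index rebuilt on load)

_EXON_COLS = ["gene_id", "exon_index", "chrom", "start", "end", "strand", "sequence"]


def save_reference(models: dict[str, GeneModel], k: int, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "exons.tsv", "w") as fh:
        fh.write("\t".join(_EXON_COLS) + "\n")
        for gid in sorted(models):
            for ex in models[gid].exons:
                fh.write(
                    f"{ex.gene_id}\t{ex.exon_index}\t{ex.chrom}\t{ex.start}\t"
                    f"{ex.end}\t{ex.strand}\t{ex.sequence}\n"
                )
    (out / "meta.json").write_text(json.dumps({"k": k, "format": "mecirc-ref-v1"}))


def load_reference(ref_dir) -> tuple[dict[str, GeneModel], ExonIndex]:
    ref = Path(ref_dir)
    meta = json.loads((ref / "meta.json").read_text())
    by_gene: dict[str, list[ExonRecord]] = {}
    with open(ref / "exons.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _EXON_COLS:
            raise ValueError(f"{ref}: unexpected exon table header")
        for line in fh:
            gid, idx, chrom, s, e, strand, seq = line.rstrip("\n").split("\t")
            by_gene.setdefault(gid, []).append(
                ExonRecord(gid, int(idx), chrom, int(s), int(e), strand, seq)
            )
    models = {
        gid: GeneModel(gid, recs[0].chrom, recs[0].strand, sorted(recs, key=lambda r: r.exon_index))
        for gid, recs in by_gene.items()
    }
    return models, build_exon_index(models, k=meta["k"])


def write_gtf(models: dict[str, GeneModel], path) -> None:
    """Write gene models back out as GTF exon features (1-based inclusive)."""
    with open(path, "w") as fh:
        for gid in sorted(models):
            m = models[gid]
            for ex in m.exons:
                attrs = (
                    f'gene_id "{gid}"; transcript_id "{gid}.t1"; '
                    f'exon_number "{ex.exon_index}";'
                )
                fh.write(
                    f"{m.chrom}\tmecirc\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )
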