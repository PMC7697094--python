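"""Backsplice chimera detection from single reads.

A backsplice-spanning read decomposes as

    [suffix of a downstream ("donor") exon] + [0 or 3-30 nt insert]
    + [prefix of the same or an upstream ("acceptor") exon]

with both fragments from the same gene and strand. The donor fragment must
reach the donor exon's 3' end and the acceptor fragment must start at the
acceptor exon's 5' start — that colinearity violation (donor index >=
acceptor index) is what distinguishes a backsplice from a forward splice.
Gaps of 1-2 nt fall below the microexon definition (3-30 nt) and yield no
hit; gaps above 30 nt likewise.

Detection is seed-and-extend: every exact k-mer of the read is looked up in
the exon index; each posting proposes either a donor alignment (fragment ends
at the exon 3' end) or an acceptor alignment (fragment starts at the exon 5'
start), candidates are verified allowing up to ``max_mismatch`` mismatches
per fragment, and verified donor/acceptor pairs of the same gene with an
admissible gap become hits. A fragment is only found if it contains at least
one error-free k-mer, which is guaranteed for error-free reads when
min_anchor >= k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from ._seq import hamming
from .reference import ExonIndex, GeneModel

logger = logging.getLogger(__name__)

MIN_INSERT = 3
MAX_INSERT = 30


@dataclass
class ScanParams:
    min_anchor: int = 18
    max_mismatch: int = 1
    min_insert: int = MIN_INSERT
    max_insert: int = MAX_INSERT
    scan_revcomp: bool = False  # set for unstranded libraries


@dataclass(frozen=True)
class ChimericHit:
    """One read decomposed across a backsplice junction."""

    read_id: str
    gene_id: str
    strand: str
    donor_exon_index: int
    acceptor_exon_index: int
    donor_read_span: tuple[int, int]
    acceptor_read_span: tuple[int, int]
    donor_exon_span: tuple[int, int]
    acceptor_exon_span: tuple[int, int]
    insert_seq: str
    mismatches: tuple[int, int]  # (donor fragment, acceptor fragment)
    read_seq: str = ""
    ambiguous: bool = False

    @property
    def junction_key(self) -> tuple[str, int, int, str]:
        return (
            self.gene_id,
            self.acceptor_exon_index,
            self.donor_exon_index,
            self.insert_seq,
        )

    @property
    def anchored_length(self) -> int:
        d = self.donor_read_span
        a = self.acceptor_read_span
        return (d[1] - d[0]) + (a[1] - a[0])


@dataclass(frozen=True)
class BackspliceJunction:
    """A merged junction located on the genome."""

    gene_id: str
    chrom: str
    strand: str
    acceptor_exon_index: int
    donor_exon_index: int
    genomic_start: int
    genomic_end: int
    insert_seq: str


@dataclass(frozen=True)
class CircRNACall:
    """A circRNA supported by one or more unique backsplice reads."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    exon_list: tuple[int, ...]
    kind: str  # "canonical" | "me_junction"
    insert_seq: str
    read_count: int

    @property
    def junction_key(self) -> tuple[str, int, int, str]:
        return (self.gene_id, self.exon_list[0], self.exon_list[-1], self.insert_seq)


@dataclass
class ScanStats:
    """Per-run bookkeeping of why reads did or did not yield hits."""

    n_reads: int = 0
    n_chimeric: int = 0
    n_ambiguous: int = 0
    n_gap_rejected: int = field(default=0)  # 1-2 nt or >30 nt or negative gaps seen


def _admissible_gap(gap: int, params: ScanParams) -> bool:
    return gap == 0 or params.min_insert <= gap <= params.max_insert


def scan_read(
    read_id: str,
    read_seq: str,
    index: ExonIndex,
    models: dict[str, GeneModel],
    params: ScanParams | None = None,
    keep: str = "best",
) -> list[ChimericHit]:
    """Decompose one read into backsplice chimeric hits.

    ``keep="best"`` returns the single preferred decomposition (fewest total
    mismatches, then longest anchored length, then smallest insert, then
    (acceptor, donor, gene) order; ties on the first three flag the hit
    ``ambiguous``). ``keep="all"`` returns every valid decomposition.
    """
    params = params or ScanParams()
    read_seq = read_seq.upper()
    L = len(read_seq)
    k = index.k
    if params.min_anchor < k:
        raise ValueError("min_anchor must be >= index k")
    if L < 2 * params.min_anchor:
        return []

    # candidate fragment alignments implied by exact seed matches
    donor_cand: set[tuple[str, int, int]] = set()  # (gene, exon_idx, p)
    accept_cand: set[tuple[str, int, int]] = set()  # (gene, exon_idx, q)
    for i in range(L - k + 1):
        for gid, eidx, off in index.lookup(read_seq[i : i + k]):
            elen = models[gid].exon(eidx).length
            # donor hypothesis: read[0:p] aligns to exon suffix ending at 3' end
            if i <= off:
                p = i + (elen - off)
                if params.min_anchor <= p <= L - params.min_anchor:
                    donor_cand.add((gid, eidx, p))
            # acceptor hypothesis: read[q:] aligns to exon prefix from 5' start
            q = i - off
            if q >= params.min_anchor and L - q >= params.min_anchor and L - q <= elen:
                accept_cand.add((gid, eidx, q))

    # verify fragments against exon sequences
    donors: dict[str, list[tuple[int, int, int]]] = {}  # gene -> (eidx, p, mm)
    for gid, eidx, p in donor_cand:
        eseq = models[gid].exon(eidx).sequence
        mm = hamming(read_seq[:p], eseq[len(eseq) - p :], params.max_mismatch)
        if mm <= params.max_mismatch:
            donors.setdefault(gid, []).append((eidx, p, mm))
    acceptors: dict[str, list[tuple[int, int, int]]] = {}
    for gid, eidx, q in accept_cand:
        eseq = models[gid].exon(eidx).sequence
        mm = hamming(read_seq[q:], eseq[: L - q], params.max_mismatch)
        if mm <= params.max_mismatch:
            acceptors.setdefault(gid, []).append((eidx, q, mm))

    hits: list[ChimericHit] = []
    for gid, dlist in donors.items():
        alist = acceptors.get(gid)
        if not alist:
            continue
        strand = models[gid].strand
        for d_idx, p, mm_d in dlist:
            d_len = models[gid].exon(d_idx).length
            for a_idx, q, mm_a in alist:
                if d_idx < a_idx:
                    continue  # forward splice, not a backsplice
                gap = q - p
                if not _admissible_gap(gap, params):
                    continue
                a_len_frag = L - q
                hits.append(
                    ChimericHit(
                        read_id=read_id,
                        gene_id=gid,
                        strand=strand,
                        donor_exon_index=d_idx,
                        acceptor_exon_index=a_idx,
                        donor_read_span=(0, p),
                        acceptor_read_span=(q, L),
                        donor_exon_span=(d_len - p, d_len),
                        acceptor_exon_span=(0, a_len_frag),
                        insert_seq=read_seq[p:q],
                        mismatches=(mm_d, mm_a),
                        read_seq=read_seq,
                    )
                )

    if params.scan_revcomp and not hits:
        from ._seq import revcomp

        rc_params = replace(params, scan_revcomp=False)
        hits = scan_read(read_id, revcomp(read_seq), index, models, rc_params, keep="all")

    if keep == "all" or not hits:
        return hits
    return [_select_best(hits)]


def _rank(h: ChimericHit) -> tuple:
    return (
        h.mismatches[0] + h.mismatches[1],
        -h.anchored_length,
        len(h.insert_seq),
        h.acceptor_exon_index,
        h.donor_exon_index,
        h.gene_id,
    )


def _select_best(hits: list[ChimericHit]) -> ChimericHit:
    ordered = sorted(hits, key=_rank)
    best = ordered[0]
    if len(ordered) > 1 and _rank(ordered[1])[:3] == _rank(best)[:3]:
        best = replace(best, ambiguous=True)
    return best


def scan_reads(
    reads,
    index: ExonIndex,
    models: dict[str, GeneModel],
    params: ScanParams | None = None,
) -> tuple[list[ChimericHit], ScanStats]:
    """Scan an iterable of (read_id, sequence) pairs; best hit per read."""
    stats = ScanStats()
    hits: list[ChimericHit] = []
    for rid, seq in reads:
        stats.n_reads += 1
        found = scan_read(rid, seq, index, models, params, keep="best")
        if found:
            stats.n_chimeric += 1
            if found[0].ambiguous:
                stats.n_ambiguous += 1
            hits.append(found[0])
    logger.info(
        "scanned %d reads: %d chimeric (%d ambiguous)",
        stats.n_reads,
        stats.n_chimeric,
        stats.n_ambiguous,
    )
    return hits, stats


def call_junction(hit: ChimericHit, models: dict[str, GeneModel]) -> BackspliceJunction:
    """Locate a chimeric hit's junction on the genome.

    The circRNA span runs from the acceptor exon's genomic-leftmost to the
    donor exon's genomic-rightmost coordinate (strand-symmetric).
    """
    model = models.get(hit.gene_id)
    if model is None:
        raise KeyError(f"gene {hit.gene_id} not in models")
    try:
        acc = model.exon(hit.acceptor_exon_index)
        don = model.exon(hit.donor_exon_index)
    except (IndexError, AssertionError) as exc:
        raise KeyError(
            f"exon index missing from gene {hit.gene_id}: "
            f"{hit.acceptor_exon_index}/{hit.donor_exon_index}"
        ) from exc
    start = min(acc.start, don.start)
    end = max(acc.end, don.end)
    return BackspliceJunction(
        gene_id=hit.gene_id,
        chrom=model.chrom,
        strand=model.strand,
        acceptor_exon_index=hit.acceptor_exon_index,
        donor_exon_index=hit.donor_exon_index,
        genomic_start=start,
        genomic_end=end,
        insert_seq=hit.insert_seq,
    )


def merge_junctions(
    hits: list[ChimericHit], models: dict[str, GeneModel]
) -> list[CircRNACall]:
    """Merge per-read hits of one sample into circRNA calls.

    Reads are counted once per unique read sequence (PCR/optical duplicates
    collapse); hits lacking a stored sequence fall back to read_id identity.
    Canonical and insert-bearing junctions over the same exon pair stay
    separate records.
    """
    groups: dict[tuple, dict] = {}
    for h in hits:
        key = h.junction_key
        g = groups.setdefault(key, {"uniq": set(), "hit": h})
        g["uniq"].add(h.read_seq if h.read_seq else h.read_id)
    calls: list[CircRNACall] = []
    for key in sorted(groups):
        g = groups[key]
        j = call_junction(g["hit"], models)
        calls.append(
            CircRNACall(
                chrom=j.chrom,
                start=j.genomic_start,
                end=j.genomic_end,
                strand=j.strand,
                gene_id=j.gene_id,
                exon_list=tuple(
                    range(j.acceptor_exon_index, j.donor_exon_index + 1)
                ),
                kind="me_junction" if j.insert_seq else "canonical",
                insert_seq=j.insert_seq,
                read_count=len(g["uniq"]),
            )
        )
    return calls
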