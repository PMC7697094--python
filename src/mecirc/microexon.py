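"""Microexon classification, expression filtering, genomic placement and
splice-site motif scoring.

Position classes follow the terminal-vs-body rule: a microexon that coincides
with the circRNA's transcript-5' or -3' terminus is a junction microexon
(junction_5p / junction_3p); a microexon fully inside the span but at neither
terminus sits in the body. De novo inserts discovered at the backsplice are
junction microexons by construction.

Placement of de novo inserts searches the host gene's intronic sequence, on
the gene strand, for an exact match of the insert; introns between and
immediately flanking the two backsplice exons are searched first, then all
introns. Among hits the one closest to the nearer backsplice exon wins
(ties break toward the transcript-5' exon and are flagged). Inserts shorter
than 6 nt are left UNPLACED — short queries match promiscuously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import fetch, revcomp
from .chimera import CircRNACall
from .reference import GeneModel, KnownME

logger = logging.getLogger(__name__)

MIN_PLACEABLE = 6  # placement restricted to microexons >= 6 nt

UNPLACED = None


@dataclass(frozen=True)
class LocatedME:
    """Genomic placement of a microexon insert."""

    chrom: str
    start: int
    end: int
    strand: str
    distance: int  # genomic nt to the nearer backsplice exon
    tie: bool = False


@dataclass(frozen=True)
class MicroexonCall:
    """A microexon associated with a circRNA."""

    source: str  # "de_novo" | "known"
    me_id: str
    insert_seq: str
    circ_key: tuple
    position: str  # "junction_5p" | "junction_3p" | "body"
    located: LocatedME | None
    acceptor_dinuc: str = ""
    donor_dinuc: str = ""
    gtag: bool = False
    flank_acceptor: str = ""  # 5 nt intron + 5 nt ME at the ME 5' boundary
    flank_donor: str = ""  # 5 nt ME + 5 nt intron at the ME 3' boundary
    unplaced_reason: str = ""


@dataclass
class MotifMatrix:
    """Position-frequency matrices around the two microexon boundaries.

    Each matrix covers 10 positions - 5 nt of intron and 5 nt of microexon
    (acceptor side: intron then ME; donor side: ME then intron) - by the four
    bases, in transcript orientation.
    """

    acceptor: pd.DataFrame  # 4 bases x 10 positions, counts
    donor: pd.DataFrame
    n_sequences: int

    def normalized(self) -> "MotifMatrix":
        return MotifMatrix(
            self.acceptor / self.n_sequences,
            self.donor / self.n_sequences,
            self.n_sequences,
        )


# ---------------------------------------------------------------------------
# expression filter for catalogued microexons


def _me_junction_strings(
    me: KnownME, model: GeneModel, genome, anchor: int
) -> tuple[str | None, str | None, str]:
    """Transcript-oriented (upstream-exon+ME, ME+downstream-exon, ME) strings."""
    me_seq = fetch(genome, me.chrom, me.start, me.end)
    if model.strand == "-":
        me_seq = revcomp(me_seq)
    # flanking exons by genomic position
    left = [e for e in model.exons if e.end <= me.start]
    right = [e for e in model.exons if e.start >= me.end]
    left_exon = max(left, key=lambda e: e.end) if left else None
    right_exon = min(right, key=lambda e: e.start) if right else None
    if model.strand == "+":
        up, down = left_exon, right_exon
    else:
        up, down = right_exon, left_exon
    up_str = up.sequence[-anchor:] + me_seq if up and up.length >= anchor else None
    down_str = me_seq + down.sequence[:anchor] if down and down.length >= anchor else None
    return up_str, down_str, me_seq


def filter_expressed_known_mes(
    reads,
    known_mes: list[KnownME],
    models: dict[str, GeneModel],
    genome,
    min_anchor: int = 10,
    require_both: bool = False,
) -> list[KnownME]:
    """Keep catalogued microexons with read support across a flanking exon.

    A microexon is expressed when at least one read contains its sequence
    contiguously joined to >= ``min_anchor`` nt of an adjacent exon of the
    same gene. With ``require_both`` a single read must cross the microexon
    and both flanking exons. Microexons falling in no annotated gene are
    flagged orphan and excluded.
    """
    text = "\n".join(seq.upper() for _rid, seq in reads)
    kept: list[KnownME] = []
    n_orphan = 0
    for me in known_mes:
        model = _host_gene(me, models)
        if model is None:
            n_orphan += 1
            logger.warning("known ME %s is orphan (no host gene); excluded", me.me_id)
            continue
        up_str, down_str, me_seq = _me_junction_strings(me, model, genome, min_anchor)
        if require_both:
            if up_str and down_str and (up_str + down_str[len(me_seq):]) in text:
                kept.append(me)
        else:
            if (up_str and up_str in text) or (down_str and down_str in text):
                kept.append(me)
    logger.info(
        "expression filter: kept %d/%d known MEs (%d orphans)",
        len(kept),
        len(known_mes),
        n_orphan,
    )
    return kept


def _host_gene(me: KnownME, models: dict[str, GeneModel]) -> GeneModel | None:
    if me.gene_id and me.gene_id in models:
        m = models[me.gene_id]
        s, e = m.span
        if m.chrom == me.chrom and m.strand == me.strand and s <= me.start and me.end <= e:
            return m
        return None
    for gid in sorted(models):
        m = models[gid]
        s, e = m.span
        if m.chrom == me.chrom and m.strand == me.strand and s <= me.start and me.end <= e:
            return m
    return None


# ---------------------------------------------------------------------------
# overlap + position classification


def classify_position(
    me_start: int, me_end: int, circ: CircRNACall
) -> str | None:
    """Terminal-vs-body class of a microexon interval against a circRNA span.

    Returns "junction_5p", "junction_3p", "body", or None (no call: the ME
    does not overlap, or crosses a span boundary without being contained).
    """
    if me_end <= circ.start or me_start >= circ.end:
        return None
    contained = circ.start <= me_start and me_end <= circ.end
    if not contained:
        return None
    at_left = me_start == circ.start
    at_right = me_end == circ.end
    if circ.strand == "+":
        if at_left:
            return "junction_5p"
        if at_right:
            return "junction_3p"
    else:
        if at_right:
            return "junction_5p"
        if at_left:
            return "junction_3p"
    return "body"


def overlap_known_mes(
    circ_calls: list[CircRNACall],
    expressed_mes: list[KnownME],
    genome=None,
) -> list[MicroexonCall]:
    """Annotate circRNAs whose span contains an expressed known microexon.

    Same-strand, same-chromosome comparison only. ``genome`` (optional) lets
    the call carry the microexon sequence.
    """
    calls: list[MicroexonCall] = []
    by_cs: dict[tuple[str, str], list[KnownME]] = {}
    for me in expressed_mes:
        by_cs.setdefault((me.chrom, me.strand), []).append(me)
    for circ in circ_calls:
        for me in by_cs.get((circ.chrom, circ.strand), []):
            pos = classify_position(me.start, me.end, circ)
            if pos is None:
                continue
            seq = fetch(genome, me.chrom, me.start, me.end) if genome is not None else ""
            if seq and circ.strand == "-":
                seq = revcomp(seq)
            calls.append(
                MicroexonCall(
                    source="known",
                    me_id=me.me_id,
                    insert_seq=seq,
                    circ_key=circ.junction_key,
                    position=pos,
                    located=LocatedME(me.chrom, me.start, me.end, me.strand, 0),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# de novo insert placement


def _interval_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    if a[1] <= b[0]:
        return b[0] - a[1]
    if b[1] <= a[0]:
        return a[0] - b[1]
    return 0


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def locate_me(
    insert_seq: str,
    circ: CircRNACall,
    models: dict[str, GeneModel],
    genome,
) -> tuple[LocatedME | None, str]:
    """Place a de novo insert in the host gene's introns.

    Returns (LocatedME, "") on success or (None, reason) when unplaced.
    """
    if len(insert_seq) < MIN_PLACEABLE:
        return None, "too_short_to_place"
    model = models[circ.gene_id]
    acc_idx, don_idx = circ.exon_list[0], circ.exon_list[-1]
    acc_iv = (model.exon(acc_idx).start, model.exon(acc_idx).end)
    don_iv = (model.exon(don_idx).start, model.exon(don_idx).end)

    n_introns = model.n_exons - 1
    tier1 = [i for i in range(max(1, acc_idx - 1), min(n_introns, don_idx) + 1)]
    tier2 = [i for i in range(1, n_introns + 1) if i not in tier1]

    for tier in (tier1, tier2):
        # (distance to nearer backsplice exon, distance to 5' exon, start)
        hits: list[tuple[int, int, int, int]] = []
        for intron_idx in tier:
            gs, _ge = model.introns[intron_idx - 1]
            iseq = model.intron_sequence(intron_idx, genome)
            for off in _find_all(iseq, insert_seq):
                if model.strand == "+":
                    s = gs + off
                else:
                    s = gs + (len(iseq) - off - len(insert_seq))
                e = s + len(insert_seq)
                d_acc = _interval_distance((s, e), acc_iv)
                d_don = _interval_distance((s, e), don_iv)
                hits.append((min(d_acc, d_don), d_acc, s, e))
        if hits:
            hits.sort()
            dist, _dacc, s, e = hits[0]
            tie = len(hits) > 1 and hits[1][0] == dist
            return LocatedME(model.chrom, s, e, model.strand, dist, tie=tie), ""
    return None, "no_intronic_match"


def splice_dinucs(
    located: LocatedME, genome
) -> tuple[str, str, bool, str, str]:
    """Intronic dinucleotides and 10-nt boundary contexts around a placed ME.

    Returns (acceptor_dinuc, donor_dinuc, gtag, flank_acceptor, flank_donor)
    in transcript orientation: the acceptor dinucleotide is the last 2 nt of
    the intron upstream of the microexon (canonically AG) and the donor
    dinucleotide is the first 2 nt of the intron downstream (canonically GT).
    """
    chrom, s, e, strand = located.chrom, located.start, located.end, located.strand
    if strand == "+":
        up5 = fetch(genome, chrom, max(0, s - 5), s)
        down5 = fetch(genome, chrom, e, e + 5)
        me = fetch(genome, chrom, s, e)
    else:
        up5 = revcomp(fetch(genome, chrom, e, e + 5))
        down5 = revcomp(fetch(genome, chrom, max(0, s - 5), s))
        me = revcomp(fetch(genome, chrom, s, e))
    if len(up5) < 2 or len(down5) < 2:
        return "", "", False, "", ""
    acceptor = up5[-2:]
    donor = down5[:2]
    gtag = acceptor == "AG" and donor == "GT"
    flank_acceptor = up5[-5:] + me[:5]
    flank_donor = me[-5:] + down5[:5]
    return acceptor, donor, gtag, flank_acceptor, flank_donor


def annotate_de_novo(
    circ_calls: list[CircRNACall],
    models: dict[str, GeneModel],
    genome,
) -> list[MicroexonCall]:
    """Place and motif-annotate every insert-bearing circRNA call.

    De novo inserts sit at the backsplice by construction; the position class
    reflects which side of the junction the insert extends (reported as
    junction_5p: the insert precedes the acceptor exon in the circle).
    """
    out: list[MicroexonCall] = []
    for circ in circ_calls:
        if circ.kind != "me_junction":
            continue
        located, reason = locate_me(circ.insert_seq, circ, models, genome)
        if located is None:
            out.append(
                MicroexonCall(
                    source="de_novo",
                    me_id=f"{circ.gene_id}_me",
                    insert_seq=circ.insert_seq,
                    circ_key=circ.junction_key,
                    position="junction_5p",
                    located=None,
                    unplaced_reason=reason,
                )
            )
            continue
        acc, don, gtag, fa, fd = splice_dinucs(located, genome)
        out.append(
            MicroexonCall(
                source="de_novo",
                me_id=f"{circ.gene_id}_me",
                insert_seq=circ.insert_seq,
                circ_key=circ.junction_key,
                position="junction_5p",
                located=located,
                acceptor_dinuc=acc,
                donor_dinuc=don,
                gtag=gtag,
                flank_acceptor=fa,
                flank_donor=fd,
            )
        )
    return out


# ---------------------------------------------------------------------------
# motif matrix


_BASES = ["A", "C", "G", "T"]
ACCEPTOR_POSITIONS = ["-5", "-4", "-3", "-2", "-1", "+1", "+2", "+3", "+4", "+5"]
DONOR_POSITIONS = ["-5", "-4", "-3", "-2", "-1", "+1", "+2", "+3", "+4", "+5"]


def motif_matrix(calls: list[MicroexonCall]) -> MotifMatrix:
    """Base counts at the 10 positions around each microexon boundary.

    Acceptor side: positions -5..-1 are intron, +1..+5 microexon. Donor side:
    -5..-1 microexon, +1..+5 intron. Only placed calls with full 10-nt
    contexts contribute.
    """
    acc = np.zeros((4, 10), dtype=int)
    don = np.zeros((4, 10), dtype=int)
    n = 0
    b2i = {b: i for i, b in enumerate(_BASES)}
    for c in calls:
        if c.located is None or len(c.flank_acceptor) != 10 or len(c.flank_donor) != 10:
            continue
        ok = all(b in b2i for b in c.flank_acceptor + c.flank_donor)
        if not ok:
            continue
        for j, b in enumerate(c.flank_acceptor):
            acc[b2i[b], j] += 1
        for j, b in enumerate(c.flank_donor):
            don[b2i[b], j] += 1
        n += 1
    if n == 0:
        raise ValueError("no placed microexon calls; cannot build motif matrix")
    return MotifMatrix(
        acceptor=pd.DataFrame(acc, index=_BASES, columns=ACCEPTOR_POSITIONS),
        donor=pd.DataFrame(don, index=_BASES, columns=DONOR_POSITIONS),
        n_sequences=n,
    )


def write_microexon_calls(calls: list[MicroexonCall], path) -> None:
    cols = [
        "source",
        "me_id",
        "insert_seq",
        "gene_id",
        "acceptor_exon",
        "donor_exon",
        "position",
        "chrom",
        "start",
        "end",
        "strand",
        "distance",
        "tie",
        "acceptor_dinuc",
        "donor_dinuc",
        "gtag",
        "unplaced_reason",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in calls:
            gene, acc, don, _ins = c.circ_key
            loc = c.located
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        c.source,
                        c.me_id,
                        c.insert_seq,
                        gene,
                        acc,
                        don,
                        c.position,
                        loc.chrom if loc else "",
                        loc.start if loc else "",
                        loc.end if loc else "",
                        loc.strand if loc else "",
                        loc.distance if loc else "",
                        loc.tie if loc else "",
                        c.acceptor_dinuc,
                        c.donor_dinuc,
                        c.gtag,
                        c.unplaced_reason,
                    ]
                )
                + "\n"
            )


def write_motif_matrix(matrix: MotifMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_sequences={matrix.n_sequences}\n")
        fh.write("# acceptor side: -5..-1 intron, +1..+5 microexon\n")
        matrix.acceptor.to_csv(fh, sep="\t")
        fh.write("# donor side: -5..-1 microexon, +1..+5 intron\n")
        matrix.donor.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# cognate pairing


def pair_cognates(circ_calls: list[CircRNACall]) -> pd.DataFrame:
    """Annotate each ME-junction call with whether a canonical cognate exists.

    A cognate is a canonical circRNA over the identical (gene, acceptor,
    donor) exon pair, differing only by the absence of the insert.
    """
    canonical = {
        (c.gene_id, c.exon_list[0], c.exon_list[-1])
        for c in circ_calls
        if c.kind == "canonical"
    }
    rows = []
    for c in circ_calls:
        if c.kind != "me_junction":
            continue
        pair = (c.gene_id, c.exon_list[0], c.exon_list[-1])
        rows.append(
            {
                "gene_id": c.gene_id,
                "acceptor_exon": pair[1],
                "donor_exon": pair[2],
                "insert_seq": c.insert_seq,
                "read_count": c.read_count,
                "has_cognate": pair in canonical,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "acceptor_exon",
            "donor_exon",
            "insert_seq",
            "read_count",
            "has_cognate",
        ],
    )
    return df


def cognate_summary(pairing: pd.DataFrame) -> dict:
    n = len(pairing)
    n_cog = int(pairing["has_cognate"].sum()) if n else 0
    return {
        "n_me_circ": n,
        "n_with_cognate": n_cog,
        "n_orphan": n - n_cog,
        "fraction_with_cognate": (n_cog / n) if n else float("nan"),
    }
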