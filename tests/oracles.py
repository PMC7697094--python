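"""Independent brute-force oracles the implementation is checked against.

These deliberately share no code with the package's detection path: the
decomposition oracle enumerates every (donor-suffix length, gap, acceptor
prefix) split of a read directly against the exon sequences, and the
placement oracle is a naive substring scan over intron sequences.
"""

from __future__ import annotations

import mecirc as mc


def hamming_leq(a: str, b: str, limit: int) -> bool:
    if limit == 0:
        return a == b
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return False
    return True


def exhaustive_decompositions(
    read: str,
    models: dict[str, mc.GeneModel],
    min_anchor: int,
    max_mismatch: int = 0,
    min_insert: int = 3,
    max_insert: int = 30,
) -> set[tuple[str, int, int, int, int]]:
    """All valid (gene, donor_exon, acceptor_exon, p, q) decompositions.

    read[0:p] must equal a donor exon's suffix (ending at its 3' end),
    read[q:] an acceptor exon's prefix, gap q-p in {0} u [min_insert,
    max_insert], donor index >= acceptor index, each fragment >= min_anchor
    and within its exon, with <= max_mismatch mismatches per fragment.
    """
    L = len(read)
    gaps = [0] + list(range(min_insert, max_insert + 1))
    donors: dict[int, list[tuple[str, int]]] = {}
    acceptors: dict[int, list[tuple[str, int]]] = {}
    for p in range(min_anchor, L - min_anchor + 1):
        for gid, m in models.items():
            for ex in m.exons:
                if ex.length >= p and hamming_leq(
                    read[:p], ex.sequence[ex.length - p :], max_mismatch
                ):
                    donors.setdefault(p, []).append((gid, ex.exon_index))
    for q in range(min_anchor, L - min_anchor + 1):
        flen = L - q
        for gid, m in models.items():
            for ex in m.exons:
                if ex.length >= flen and hamming_leq(
                    read[q:], ex.sequence[:flen], max_mismatch
                ):
                    acceptors.setdefault(q, []).append((gid, ex.exon_index))
    out = set()
    for p, dlist in donors.items():
        for gap in gaps:
            q = p + gap
            alist = acceptors.get(q)
            if not alist:
                continue
            for gid_d, d_idx in dlist:
                for gid_a, a_idx in alist:
                    if gid_d == gid_a and d_idx >= a_idx:
                        out.add((gid_d, d_idx, a_idx, p, q))
    return out


def hit_tuples(hits) -> set[tuple[str, int, int, int, int]]:
    return {
        (
            h.gene_id,
            h.donor_exon_index,
            h.acceptor_exon_index,
            h.donor_read_span[1],
            h.acceptor_read_span[0],
        )
        for h in hits
    }


def naive_placements(
    insert: str, model: mc.GeneModel, genome
) -> list[tuple[int, int, int, int]]:
    """Every intronic occurrence of ``insert`` as (dist, dist_5p, start, end)."""
    out = []
    for i in range(1, model.n_exons):
        gs, _ = model.introns[i - 1]
        iseq = model.intron_sequence(i, genome)
        start = iseq.find(insert)
        while start != -1:
            if model.strand == "+":
                s = gs + start
            else:
                s = gs + (len(iseq) - start - len(insert))
            out.append((s, s + len(insert)))
            start = iseq.find(insert, start + 1)
    return out
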