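"""Shuffle/scramble negative controls for the microexon-circRNA caller.

Two perturbations probe the false-positive propensity of the detector:

* shuffle — each microexon insert is moved, intact, to the backsplice of a
  uniformly chosen *different* junction, with the flanking exon fragments
  rebuilt from that junction's exon sequences;
* scramble — each insert's bases are permuted in place (identity permutations
  rejected whenever the insert is not a homopolymer-like degenerate case) and
  reinserted at the same junction. Only inserts longer than 6 nt are
  scrambled; shorter ones are skipped and counted.

A control read counts as "detected" when the detector re-derives a member of
the original ME-circRNA call set. With random inserts and exon sequences the
expected collision rate is far below a percent; substantially higher rates
would indicate the detector invents junction-insert combinations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .chimera import ChimericHit, ScanParams, scan_read
from .reference import ExonIndex, GeneModel

logger = logging.getLogger(__name__)

SCRAMBLE_MIN_LEN = 7  # scramble only inserts longer than 6 nt


@dataclass
class ControlReport:
    n_input_reads: int
    n_shuffled_detected: int
    n_scrambled_detected: int
    shuffle_fp_rate: float
    scramble_fp_rate: float
    seed: int
    n_scramble_skipped_short: int = 0
    n_scramble_degenerate: int = 0


@dataclass(frozen=True)
class ControlRead:
    read_id: str
    seq: str
    degenerate: bool = False


def _junction_fragments(
    gene_id: str,
    acceptor: int,
    donor: int,
    models: dict[str, GeneModel],
    donor_len: int,
    acceptor_len: int,
) -> tuple[str, str]:
    m = models[gene_id]
    dseq = m.exon(donor).sequence
    aseq = m.exon(acceptor).sequence
    return dseq[len(dseq) - min(donor_len, len(dseq)) :], aseq[: min(acceptor_len, len(aseq))]


def shuffle_controls(
    me_hits: list[ChimericHit],
    junctions: list[tuple[str, int, int]],
    models: dict[str, GeneModel],
    seed: int,
) -> list[ControlRead]:
    """Move each insert to a uniformly chosen different junction.

    ``junctions`` are (gene_id, acceptor_exon_index, donor_exon_index)
    targets (by default all detected circRNA junctions). Fragment lengths of
    the source read are preserved, clipped to the target exon lengths.
    Deterministic for a fixed seed.
    """
    uniq = sorted(set(junctions))
    if len(uniq) < 2:
        raise ValueError("shuffle requires at least 2 distinct junctions")
    rng = np.random.default_rng(seed)
    out: list[ControlRead] = []
    for h in me_hits:
        own = (h.gene_id, h.acceptor_exon_index, h.donor_exon_index)
        choices = [j for j in uniq if j != own]
        target = choices[int(rng.integers(len(choices)))]
        d_len = h.donor_read_span[1] - h.donor_read_span[0]
        a_len = h.acceptor_read_span[1] - h.acceptor_read_span[0]
        dfrag, afrag = _junction_fragments(
            target[0], target[1], target[2], models, d_len, a_len
        )
        out.append(ControlRead(f"shuf_{h.read_id}", dfrag + h.insert_seq + afrag))
    return out


def scramble_controls(
    me_hits: list[ChimericHit],
    models: dict[str, GeneModel],
    seed: int,
) -> tuple[list[ControlRead], int]:
    """Permute each insert's bases in place; flanks unchanged.

    Returns (control reads, number skipped as too short). The identity
    permutation is rejected up to a bounded number of redraws; inserts whose
    every permutation is the identity (homopolymers) pass through flagged
    ``degenerate``.
    """
    rng = np.random.default_rng(seed)
    out: list[ControlRead] = []
    n_short = 0
    for h in me_hits:
        ins = h.insert_seq
        if len(ins) < SCRAMBLE_MIN_LEN:
            n_short += 1
            continue
        degenerate = len(set(ins)) == 1
        scrambled = ins
        if not degenerate:
            for _ in range(100):
                perm = rng.permutation(len(ins))
                scrambled = "".join(ins[i] for i in perm)
                if scrambled != ins:
                    break
        d_len = h.donor_read_span[1] - h.donor_read_span[0]
        a_len = h.acceptor_read_span[1] - h.acceptor_read_span[0]
        dfrag, afrag = _junction_fragments(
            h.gene_id, h.acceptor_exon_index, h.donor_exon_index, models, d_len, a_len
        )
        out.append(
            ControlRead(f"scr_{h.read_id}", dfrag + scrambled + afrag, degenerate)
        )
    return out, n_short


def fp_assess(
    shuffle_reads: list[ControlRead],
    scramble_reads: list[ControlRead],
    original_me_keys: set[tuple[str, int, int, str]],
    index: ExonIndex,
    models: dict[str, GeneModel],
    params: ScanParams,
    seed: int,
    n_input_reads: int | None = None,
    match_mode: str = "junction",
    n_scramble_skipped_short: int = 0,
) -> ControlReport:
    """Re-detect control reads and report false-positive rates.

    ``match_mode="junction"`` (default, strictest): a control read is a false
    positive iff its re-detected (gene, acceptor, donor, insert) key is in
    the original ME-call set. ``match_mode="sequence"``: the re-detected
    insert sequence alone must be in the original insert set.
    """
    if not original_me_keys:
        raise ValueError("original ME-circRNA set is empty")
    original_inserts = {k[3] for k in original_me_keys}

    def detected(read: ControlRead) -> bool:
        hits = scan_read(read.read_id, read.seq, index, models, params, keep="best")
        for h in hits:
            if not h.insert_seq:
                continue
            if match_mode == "junction" and h.junction_key in original_me_keys:
                return True
            if match_mode == "sequence" and h.insert_seq in original_inserts:
                return True
        return False

    n_shuf = sum(detected(r) for r in shuffle_reads)
    n_scr = sum(detected(r) for r in scramble_reads)
    n_in = n_input_reads if n_input_reads is not None else len(shuffle_reads)
    n_deg = sum(r.degenerate for r in scramble_reads)
    report = ControlReport(
        n_input_reads=n_in,
        n_shuffled_detected=n_shuf,
        n_scrambled_detected=n_scr,
        shuffle_fp_rate=n_shuf / n_in if n_in else 0.0,
        scramble_fp_rate=n_scr / n_in if n_in else 0.0,
        seed=seed,
        n_scramble_skipped_short=n_scramble_skipped_short,
        n_scramble_degenerate=n_deg,
    )
    logger.info(
        "controls: shuffle FP %.4f (%d/%d), scramble FP %.4f (%d/%d)",
        report.shuffle_fp_rate,
        n_shuf,
        n_in,
        report.scramble_fp_rate,
        n_scr,
        n_in,
    )
    return report
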