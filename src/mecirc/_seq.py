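"""Small sequence utilities shared across modules."""

from __future__ import annotations

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_RC)[::-1]


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end) (0-based half-open), uppercased.

    ``genome`` may be a pyfaidx.Fasta or a plain dict of chrom -> sequence.
    """
    if isinstance(genome, dict):
        return genome[chrom][start:end].upper()
    return str(genome[chrom][start:end]).upper()


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Mismatch count between equal-length strings, early-exiting past limit."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal-length strings")
    if limit == 0 or a == b:
        return 0 if a == b else limit + 1
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if limit is not None and n > limit:
                return n
    return n
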