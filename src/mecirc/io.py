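"""FASTQ reading (Biopython-backed) and small JSON helpers."""

from __future__ import annotations

import gzip
import json
from pathlib import Path

from Bio import SeqIO


def read_fastq(path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTQ file, optionally gzipped."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fastq")]


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
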