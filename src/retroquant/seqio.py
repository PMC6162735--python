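"""Plain-text sequence I/O and nucleotide encoding helpers.

FASTA/FASTQ parsing goes through pysam's C parser; writing is plain text.
Sequences are handled internally as 2-bit numpy codes (A=0, C=1, G=2, T=3;
anything else = 4) so that k-mer extraction and mutation are vectorised.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

import numpy as np
import pysam

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# byte -> 2-bit code lookup; unknown bases (incl. N) collapse to 4
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes 0-4."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back to an ACGT string (code 4 -> N)."""
    table = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return table[codes].tobytes().decode()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} dict."""
    out: dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            if rec.name in out:
                raise ValueError(f"duplicate FASTA record {rec.name!r}")
            out[rec.name] = rec.sequence.upper()
    return out


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]],
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ file."""
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            yield rec.name, rec.sequence.upper()


def write_fastq(path: str | os.PathLike,
                records: Iterable[tuple[str, str]]) -> None:
    """Write (read_id, sequence) records; all qualities are Q40 ('I')."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
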