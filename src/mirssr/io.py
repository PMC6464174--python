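"""FASTA reading/writing and small sequence-alphabet helpers.

Transcripts are handled as DNA (A/C/G/T/N, the de novo assembly convention);
mature miRNA references follow the miRBase dialect and may contain U.  All
conversions between the two alphabets go through :func:`dna_to_rna` /
:func:`rna_to_dna` so the rest of the package never worries about T/U.
"""

from __future__ import annotations

import os
from typing import Iterable, List, Tuple

from Bio import SeqIO

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")
_RNA_COMP = str.maketrans("ACGUN", "UGCAN")


class FastaError(ValueError):
    """Raised for unreadable or malformed FASTA input."""


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp_dna(seq: str) -> str:
    return seq.upper().translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.upper().translate(_RNA_COMP)[::-1]


def read_fasta(path: str | os.PathLike) -> List[Tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` preserving order.

    Raises :class:`FastaError` naming the offending record when a sequence is
    empty or the file cannot be parsed, and on duplicate record ids.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FastaError(f"FASTA file not found: {path}")
    records: List[Tuple[str, str]] = []
    seen = set()
    try:
        for rec in SeqIO.parse(path, "fasta"):
            seq = str(rec.seq).upper()
            if not seq:
                raise FastaError(f"empty sequence for record {rec.id!r} in {path}")
            if rec.id in seen:
                raise FastaError(f"duplicate record id {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append((rec.id, seq))
    except FastaError:
        raise
    except Exception as exc:  # malformed input surfaced by the parser
        raise FastaError(f"could not parse FASTA {path}: {exc}") from exc
    if not records:
        raise FastaError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | os.PathLike, records: Iterable[Tuple[str, str]],
                wrap: int = 70) -> None:
    """Write records as FASTA wrapped at ``wrap`` columns (byte-deterministic)."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i:i + wrap] + "\n")
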