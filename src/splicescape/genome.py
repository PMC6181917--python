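"""Genome sequence access.

All coordinates are 0-based half-open. ``fetch(chrom, start, end, "-")``
returns the reverse complement, so callers always see sequence in the
transcribed (5'->3') orientation of the requested strand.
"""

from __future__ import annotations

from typing import Iterator, Mapping, Protocol

__all__ = [
    "GenomeAccess",
    "DictGenome",
    "FastaGenome",
    "reverse_complement",
    "write_fasta",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeAccess(Protocol):
    """Indexed sequence access contract used throughout the package."""

    def chrom_length(self, chrom: str) -> int: ...

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str: ...


class DictGenome:
    """In-memory genome: a mapping of chromosome name to sequence string."""

    def __init__(self, chroms: Mapping[str, str]):
        self._chroms = {name: seq.upper() for name, seq in chroms.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def __iter__(self) -> Iterator[str]:
        return iter(self._chroms)

    def chrom_length(self, chrom: str) -> int:
        return len(self._chroms[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        seq = self._chroms[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(
                f"interval [{start}, {end}) outside {chrom} (length {len(seq)})"
            )
        sub = seq[start:end]
        return reverse_complement(sub) if strand == "-" else sub


class FastaGenome:
    """Genome backed by an indexed FASTA file (pyfaidx)."""

    def __init__(self, path: str):
        import pyfaidx

        self._fasta = pyfaidx.Fasta(path, as_raw=True, sequence_always_upper=True)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fasta

    def __iter__(self) -> Iterator[str]:
        return iter(self._fasta.keys())

    def chrom_length(self, chrom: str) -> int:
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        n = self.chrom_length(chrom)
        if start < 0 or end > n or start > end:
            raise ValueError(f"interval [{start}, {end}) outside {chrom} (length {n})")
        sub = str(self._fasta[chrom][start:end])
        return reverse_complement(sub) if strand == "-" else sub


def write_fasta(chroms: Mapping[str, str], path: str, width: int = 60) -> None:
    """Write sequences as wrapped FASTA, in mapping order."""
    with open(path, "w") as fh:
        for name, seq in chroms.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
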