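"""In-memory reference sequence store with k-mer context lookup.

Genomes handled here are desk-scale (tens of kilobases to a few megabases),
so sequences are held in memory after loading; FASTA parsing is delegated to
pyfaidx.  All lookups are 1-based to match variant coordinates.
"""

from __future__ import annotations

from typing import Mapping, Optional

import pyfaidx

from .errors import ValidationError

_VALID = frozenset("ACGT")


class ReferenceStore:
    """Uppercase reference sequences keyed by contig name."""

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValidationError("reference store needs at least one contig")
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "ReferenceStore":
        fa = pyfaidx.Fasta(str(path), rebuild=True, build_index=True)
        try:
            return cls({name: str(fa[name][:]) for name in fa.keys()})
        finally:
            fa.close()

    @property
    def contigs(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, contig: str) -> bool:
        return contig in self._seqs

    def sequence(self, contig: str) -> str:
        try:
            return self._seqs[contig]
        except KeyError:
            raise LookupError(f"contig {contig!r} not in reference") from None

    def length(self, contig: str) -> int:
        return len(self.sequence(contig))

    def base(self, contig: str, pos: int) -> str:
        """Reference base at 1-based ``pos``."""
        seq = self.sequence(contig)
        if not 1 <= pos <= len(seq):
            raise LookupError(f"position {pos} outside {contig} (length {len(seq)})")
        return seq[pos - 1]

    def fetch_kmer(self, contig: str, pos: int, k: int) -> Optional[str]:
        """The k-mer centered on 1-based ``pos``, or None when there is no
        usable context (insufficient flank or non-ACGT base in the window).
        """
        if k % 2 != 1:
            raise ValueError("k must be odd")
        seq = self.sequence(contig)
        half = k // 2
        lo, hi = pos - 1 - half, pos - 1 + half + 1
        if lo < 0 or hi > len(seq):
            return None
        kmer = seq[lo:hi]
        if not set(kmer) <= _VALID:
            return None
        return kmer


def write_fasta(store: ReferenceStore, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for contig in store.contigs:
            fh.write(f">{contig}\n")
            seq = store.sequence(contig)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
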