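"""The 96-channel single-base-substitution coordinate system.

Channels follow the COSMIC convention: six pyrimidine-oriented substitution
classes in the order C>A, C>G, C>T, T>A, T>C, T>G, each expanded over the 16
combinations of 5' and 3' flanking bases in alphabetical order, so that

    index = 16 * substitution + 4 * five_prime + three_prime

with bases enumerated A=0, C=1, G=2, T=3.  Labels use the conventional
``F[R>A]T`` form (flank, ref>alt, flank).
"""

from __future__ import annotations

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: pyrimidine-oriented substitution classes, COSMIC major order
SUBSTITUTIONS: tuple[tuple[str, str], ...] = (
    ("C", "A"), ("C", "G"), ("C", "T"),
    ("T", "A"), ("T", "C"), ("T", "G"),
)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

# IUPAC sets used by the APOBEC context flags
IUPAC_W = frozenset("AT")
IUPAC_R = frozenset("AG")
IUPAC_Y = frozenset("CT")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def channel_index(trinucleotide: str, ref: str, alt: str) -> int:
    """Index of the channel for a pyrimidine-oriented substitution.

    ``trinucleotide`` is the 3-mer around the mutated base with a pyrimidine
    center equal to ``ref``.
    """
    sub = SUBSTITUTIONS.index((ref, alt))
    return 16 * sub + 4 * BASES.index(trinucleotide[0]) + BASES.index(trinucleotide[2])


def channel_label(index: int) -> str:
    ref, alt = SUBSTITUTIONS[index // 16]
    five = BASES[(index % 16) // 4]
    three = BASES[index % 4]
    return f"{five}[{ref}>{alt}]{three}"


def channel_trinucleotide(index: int) -> str:
    """The (pyrimidine-centered) trinucleotide context of a channel."""
    ref = SUBSTITUTIONS[index // 16][0]
    five = BASES[(index % 16) // 4]
    three = BASES[index % 4]
    return five + ref + three


def channel_substitution(index: int) -> tuple[str, str]:
    return SUBSTITUTIONS[index // 16]


CHANNEL_LABELS: tuple[str, ...] = tuple(channel_label(i) for i in range(96))
CHANNEL_INDEX_BY_LABEL = {lab: i for i, lab in enumerate(CHANNEL_LABELS)}

#: the 32 pyrimidine-centered trinucleotides, each shared by 3 channels
PYRIMIDINE_TRINUCLEOTIDES: tuple[str, ...] = tuple(
    sorted({channel_trinucleotide(i) for i in range(96)})
)


def pyrimidine_trinucleotide(trinuc: str) -> tuple[str, bool]:
    """Orient a 3-mer so its center is a pyrimidine.

    Returns ``(oriented_trinuc, flipped)`` where ``flipped`` is True when the
    reverse complement was taken.  Raises ValueError for ambiguous bases.
    """
    center = trinuc[1]
    if center in PYRIMIDINES:
        return trinuc, False
    if center in PURINES:
        return revcomp(trinuc), True
    raise ValueError(f"ambiguous center base in trinucleotide {trinuc!r}")
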