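"""Somatic variant records and their validation.

Coordinates are 1-based inclusive (VCF convention) throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .errors import ValidationError

CLONALITY_STATES = ("clonal", "subclonal", "unknown")

_ALLELE_CHARS = frozenset("ACGTN")


@dataclass(frozen=True)
class Variant:
    """One somatic substitution or indel call.

    Evidence fields are optional because variants pass through the pipeline
    in stages: a simulated or parsed call may carry no caller evidence until
    it is annotated.  Filters and writers that require a field check its
    presence and emit an explicit error decision rather than silently passing.
    """

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vaf_tumor: Optional[float] = None
    depth_tumor: Optional[int] = None
    alt_reads_tumor: Optional[int] = None
    somatic_p: Optional[float] = None
    callers: frozenset[str] = field(default_factory=frozenset)
    alt_reads_normal: Optional[int] = None
    vaf_normal: Optional[float] = None
    clonality: str = "unknown"
    filter_status: Optional[str] = None  # caller FILTER column, e.g. "PASS"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _ALLELE_CHARS:
                raise ValidationError(f"{name} allele {allele!r} is not a DNA string")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if (
            self.alt_reads_tumor is not None
            and self.depth_tumor is not None
            and self.alt_reads_tumor > self.depth_tumor
        ):
            raise ValidationError(
                f"alt_reads_tumor {self.alt_reads_tumor} exceeds depth_tumor "
                f"{self.depth_tumor} at {self.chrom}:{self.pos}"
            )
        for name, frac in (
            ("vaf_tumor", self.vaf_tumor),
            ("vaf_normal", self.vaf_normal),
            ("somatic_p", self.somatic_p),
        ):
            if frac is not None and not 0.0 <= frac <= 1.0:
                raise ValidationError(f"{name} {frac} outside [0, 1]")
        for name, count in (
            ("depth_tumor", self.depth_tumor),
            ("alt_reads_tumor", self.alt_reads_tumor),
            ("alt_reads_normal", self.alt_reads_normal),
        ):
            if count is not None and count < 0:
                raise ValidationError(f"{name} {count} is negative")
        if self.clonality not in CLONALITY_STATES:
            raise ValidationError(f"clonality {self.clonality!r} not in {CLONALITY_STATES}")
        if not isinstance(self.callers, frozenset):
            object.__setattr__(self, "callers", frozenset(self.callers))

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def sort_key(self) -> tuple:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)

    def with_(self, **changes) -> "Variant":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


def sorted_variants(variants: list[Variant]) -> list[Variant]:
    """Deterministic ordering used by all writers."""
    return sorted(variants, key=Variant.sort_key)
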