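"""Pyrimidine-oriented sequence-context classification of substitutions.

Every SNV is reported on the strand whose mutated base is a pyrimidine
(C or T), the convention under which the 96 trinucleotide channels and the
APOBEC context classes are defined:

* ``TCN``  — a mutated cytosine preceded by thymine (any 3' base); C>T and
  C>G changes here are the canonical APOBEC deamination footprint.
* ``TCW``  — TCN with a 3' A or T, the preferred APOBEC substrate.
* ``RTCW`` / ``YTCW`` — pentanucleotide refinement by the base 5' of the T:
  a purine (R = A/G) marks the APOBEC3B-preferred site, a pyrimidine
  (Y = C/T) the APOBEC3A-preferred site.  They partition TCW.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .channels import (
    IUPAC_R,
    IUPAC_W,
    IUPAC_Y,
    PURINES,
    PYRIMIDINES,
    channel_index,
    revcomp,
)
from .errors import NoContext, NotAnSNV, UndefinedResultError, ValidationError
from .reference import ReferenceStore
from .variants import Variant


@dataclass(frozen=True)
class ContextCall:
    """A classified SNV: its pyrimidine-oriented context and APOBEC flags."""

    variant: Variant
    trinucleotide: str
    pentanucleotide: Optional[str]  # None when the 5-mer flank is unavailable
    ref_pyrimidine: str
    alt_pyrimidine: str
    strand_flipped: bool
    is_c_to_t_or_g: bool
    is_tcn: bool
    is_tcw: bool
    is_rtcw: bool
    is_ytcw: bool

    @property
    def channel(self) -> int:
        """COSMIC 96-channel index of this substitution."""
        return channel_index(self.trinucleotide, self.ref_pyrimidine, self.alt_pyrimidine)


def extract_context(reference: ReferenceStore, variant: Variant) -> ContextCall:
    """Classify one SNV against the reference.

    Raises :class:`NotAnSNV` for indels/MNVs (skip signal) and
    :class:`NoContext` when the trinucleotide window is out of range or
    contains a non-ACGT base.  The pentanucleotide is optional: when only the
    3-mer is available the call carries ``pentanucleotide=None`` and the
    RTCW/YTCW flags are False.
    """
    if not variant.is_snv:
        raise NotAnSNV(f"{variant.chrom}:{variant.pos} {variant.ref}>{variant.alt}")
    trimer = reference.fetch_kmer(variant.chrom, variant.pos, 3)
    if trimer is None:
        raise NoContext(f"{variant.chrom}:{variant.pos}")
    ref_base = trimer[1]
    if ref_base != variant.ref:
        raise ValidationError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"variant ref {variant.ref}, reference {ref_base}"
        )
    pentamer = reference.fetch_kmer(variant.chrom, variant.pos, 5)

    if ref_base in PYRIMIDINES:
        flipped = False
        tri, penta = trimer, pentamer
        ref_py, alt_py = variant.ref, variant.alt
    elif ref_base in PURINES:
        flipped = True
        tri = revcomp(trimer)
        penta = revcomp(pentamer) if pentamer is not None else None
        ref_py = revcomp(variant.ref)
        alt_py = revcomp(variant.alt)
    else:  # pragma: no cover - excluded by fetch_kmer ACGT check
        raise NoContext(f"{variant.chrom}:{variant.pos}")

    is_ctg = ref_py == "C" and alt_py in ("T", "G")
    is_tcn = is_ctg and tri[0] == "T"
    is_tcw = is_tcn and tri[2] in IUPAC_W
    five_of_t = penta[0] if penta is not None else None
    is_rtcw = is_tcw and five_of_t in IUPAC_R
    is_ytcw = is_tcw and five_of_t in IUPAC_Y
    return ContextCall(
        variant=variant,
        trinucleotide=tri,
        pentanucleotide=penta,
        ref_pyrimidine=ref_py,
        alt_pyrimidine=alt_py,
        strand_flipped=flipped,
        is_c_to_t_or_g=is_ctg,
        is_tcn=is_tcn,
        is_tcw=is_tcw,
        is_rtcw=is_rtcw,
        is_ytcw=is_ytcw,
    )


@dataclass
class ContextQC:
    """Bookkeeping for variants excluded from context statistics."""

    n_input: int = 0
    n_classified: int = 0
    n_non_snv: int = 0
    n_no_context: int = 0


def classify_variants(
    reference: ReferenceStore, variants: Iterable[Variant]
) -> tuple[list[ContextCall], ContextQC]:
    """Classify a variant list, counting non-SNVs and no-context mutations.

    Excluded variants are dropped from both numerator and denominator of all
    downstream fractions; their counts are returned for QC reporting.
    """
    calls: list[ContextCall] = []
    qc = ContextQC()
    for v in variants:
        qc.n_input += 1
        try:
            calls.append(extract_context(reference, v))
            qc.n_classified += 1
        except NotAnSNV:
            qc.n_non_snv += 1
        except NoContext:
            qc.n_no_context += 1
    return calls, qc


def apobec_fractions(calls: list[ContextCall]) -> dict[str, float]:
    """Per-sample fractions of mutations in APOBEC contexts.

    Each fraction uses *all* classified mutations in the sample as the
    denominator (not only C>T/G changes).  ``frac_rtcw + frac_ytcw ==
    frac_tcw`` whenever pentanucleotide context was available for every TCW
    mutation.
    """
    total = len(calls)
    if total == 0:
        raise UndefinedResultError("no classified mutations: fractions undefined")
    return {
        "frac_tcn": sum(c.is_tcn for c in calls) / total,
        "frac_tcw": sum(c.is_tcw for c in calls) / total,
        "frac_rtcw": sum(c.is_rtcw for c in calls) / total,
        "frac_ytcw": sum(c.is_ytcw for c in calls) / total,
    }


def count_apobec_mutations(
    calls: list[ContextCall], stratify_by_clonality: bool = False
) -> dict[str, int]:
    """Count APOBEC-associated mutations (C>T or C>G in a TCN context).

    With ``stratify_by_clonality`` the counts are split into the four
    {clonal, subclonal} x {APOBEC, non-APOBEC} cells, which sum to the total
    number of classified mutations.
    """
    out = {"apobec_total": sum(c.is_tcn for c in calls), "total": len(calls)}
    if not stratify_by_clonality:
        return out
    unknown = [c.variant for c in calls if c.variant.clonality == "unknown"]
    if unknown:
        locs = ", ".join(f"{v.chrom}:{v.pos}" for v in unknown[:5])
        raise ValidationError(
            f"{len(unknown)} variant(s) lack clonality labels (e.g. {locs})"
        )
    for clon in ("clonal", "subclonal"):
        sub = [c for c in calls if c.variant.clonality == clon]
        out[f"{clon}_apobec"] = sum(c.is_tcn for c in sub)
        out[f"{clon}_non_apobec"] = sum(not c.is_tcn for c in sub)
    return out
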