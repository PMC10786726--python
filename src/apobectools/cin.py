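"""Chromosomal-instability metrics: multi-region SCNA intratumor
heterogeneity and chromosome-missegregation statistics.

Segment coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import UndefinedResultError, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    total_cn: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"segment {self.chrom}:{self.start}-{self.end} is empty")
        if self.start < 0 or self.total_cn < 0:
            raise ValidationError("segment start and copy number must be nonnegative")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RegionSegments:
    """Per-tumor copy-number segments for every sampled region.

    Each region's segments must tile the same genome extent with no overlaps
    or gaps, so that a copy-number state is defined for every base in every
    region (the condition under which the per-base ITH overlay is exact).
    """

    tumor_id: str
    regions: dict[str, list[Segment]]
    baseline_cn: int = 2

    def __post_init__(self) -> None:
        extents = {}
        for region, segs in self.regions.items():
            segs.sort(key=lambda s: (s.chrom, s.start))
            self.regions[region] = segs
            per_chrom: dict[str, list[Segment]] = {}
            for s in segs:
                per_chrom.setdefault(s.chrom, []).append(s)
            ext = {}
            for chrom, cs in per_chrom.items():
                for a, b in zip(cs, cs[1:]):
                    if b.start < a.end:
                        raise ValidationError(
                            f"{self.tumor_id}/{region}: overlapping segments on "
                            f"{chrom} at {b.start} < {a.end}"
                        )
                    if b.start > a.end:
                        raise ValidationError(
                            f"{self.tumor_id}/{region}: coverage gap on {chrom} "
                            f"between {a.end} and {b.start}"
                        )
                ext[chrom] = (cs[0].start, cs[-1].end)
            extents[region] = ext
        vals = list(extents.values())
        if any(v != vals[0] for v in vals[1:]):
            raise ValidationError(
                f"{self.tumor_id}: regions do not share a genome extent: {extents}"
            )

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def chroms(self) -> list[str]:
        first = next(iter(self.regions.values()))
        return sorted({s.chrom for s in first})


def _cn_at(segments: Sequence[Segment], chrom: str, point: int) -> int:
    for s in segments:
        if s.chrom == chrom and s.start <= point < s.end:
            return s.total_cn
    raise ValidationError(f"no segment covering {chrom}:{point}")


def scna_ith(region_segments: RegionSegments) -> float:
    """Fraction of the SCNA-altered genome whose alterations are
    heterogeneous across regions.

    All regions are overlaid into elementary intervals of constant per-region
    copy number.  A base is *altered* when any region departs from the
    baseline copy number, and *heterogeneous* when, additionally, the regions
    do not all share the same copy-number state there.  The metric is
    heterogeneous bases / altered bases, and is invariant to re-splitting
    segments without changing states.
    """
    if region_segments.n_regions < 2:
        raise ValidationError("SCNA ITH requires at least 2 regions")
    baseline = region_segments.baseline_cn
    altered = 0
    heterogeneous = 0
    for chrom in region_segments.chroms():
        points = sorted(
            {
                p
                for segs in region_segments.regions.values()
                for s in segs
                if s.chrom == chrom
                for p in (s.start, s.end)
            }
        )
        for lo, hi in zip(points, points[1:]):
            states = [
                _cn_at(segs, chrom, lo) for segs in region_segments.regions.values()
            ]
            if any(cn != baseline for cn in states):
                altered += hi - lo
                if len(set(states)) > 1:
                    heterogeneous += hi - lo
    if altered == 0:
        raise UndefinedResultError(
            f"{region_segments.tumor_id}: no SCNA-altered bases, ITH undefined"
        )
    return heterogeneous / altered


@dataclass(frozen=True)
class AnaphaseCounts:
    """Missegregation scoring for one subject: lagging chromosomes plus
    anaphase bridges over the number of anaphases examined."""

    subject_id: str
    errors: int
    anaphases: int
    recombination_efficiency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.anaphases <= 0:
            raise ValidationError(f"{self.subject_id}: anaphases must be positive")
        if not 0 <= self.errors <= self.anaphases:
            raise ValidationError(f"{self.subject_id}: errors must be in [0, anaphases]")
        eff = self.recombination_efficiency
        if eff is not None and not 0 < eff <= 1:
            raise ValidationError(f"{self.subject_id}: efficiency must be in (0, 1]")


def missegregation_percent(
    counts: Iterable[AnaphaseCounts],
    normalize_efficiency: Optional[float] = None,
    zero_policy: str = "strict",
) -> float:
    """Group-level percentage of anaphases with missegregation errors.

    Per-subject percentages (100 * errors / anaphases) are averaged with the
    harmonic mean.  When a recombination efficiency is supplied (either per
    subject or as ``normalize_efficiency``), each subject's percentage is
    divided by it, capped at 100, to express the rate per recombined cell.

    The harmonic mean is undefined when any subject has zero errors; the
    default ``zero_policy='strict'`` raises, while ``'pooled'`` falls back to
    the pooled rate 100 * sum(errors) / sum(anaphases) with a warning.
    """
    subjects = list(counts)
    if not subjects:
        raise ValidationError("no subjects supplied")
    if zero_policy not in ("strict", "pooled"):
        raise ValidationError(f"unknown zero_policy {zero_policy!r}")

    def _pct(s: AnaphaseCounts) -> float:
        pct = 100.0 * s.errors / s.anaphases
        eff = s.recombination_efficiency or normalize_efficiency
        if eff is not None:
            pct = min(100.0, pct / eff)
        return pct

    pcts = [_pct(s) for s in subjects]
    if any(p == 0 for p in pcts):
        if zero_policy == "strict":
            zeros = [s.subject_id for s, p in zip(subjects, pcts) if p == 0]
            raise UndefinedResultError(
                f"harmonic mean undefined with zero-error subjects: {zeros}; "
                "use zero_policy='pooled'"
            )
        log.warning("zero-error subject present; falling back to pooled error rate")
        pooled = 100.0 * sum(s.errors for s in subjects) / sum(s.anaphases for s in subjects)
        eff = normalize_efficiency
        if eff is not None:
            pooled = min(100.0, pooled / eff)
        return pooled
    return len(pcts) / sum(1.0 / p for p in pcts)
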