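"""Post-caller somatic variant filtering cascades.

Each cascade is a pure rule evaluator over :class:`~apobectools.variants.Variant`
records and returns one auditable :class:`FilterDecision` per input.  The
word-to-operator mapping is fixed: "minimum X" / "at least X" mean >= X,
"over X" / "greater than X" / "more than X" mean strictly > X, and P-value
thresholds are strict (<).  Boundary behavior is unit-tested explicitly.

Missing required evidence yields an *error* decision (never a silent pass),
so pass + fail + error counts always equal the input count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .variants import Variant

# rule identifiers, reported in the audit trail
RULE_MIN_DEPTH = "min_depth"
RULE_MIN_ALT_READS = "min_alt_reads"
RULE_SOMATIC_P = "somatic_p"
RULE_MIN_VAF = "min_vaf"
RULE_SECOND_CALLER = "low_vaf_needs_second_caller"
RULE_CALLER_CONSENSUS = "caller_consensus"
RULE_CALLER_FILTER = "caller_filter"
RULE_GERMLINE_ALT = "germline_alt_reads"
RULE_GERMLINE_VAF = "germline_vaf"


@dataclass(frozen=True)
class CallerPreset:
    """Maps the cascade's caller roles onto free-text caller labels."""

    name: str
    primary: str = "varscan2"
    rescue: str = "mutect"  # second caller that rescues 2-5% VAF SNVs
    indel_required: frozenset[str] = frozenset({"scalpel", "varscan2"})


MOUSE_WES = CallerPreset(name="mouse-wes")
CELLLINE_WGS = CallerPreset(name="cellline-wgs", primary="mutect2", rescue="mutect2")

PRESETS = {p.name: p for p in (MOUSE_WES, CELLLINE_WGS)}


@dataclass(frozen=True)
class FilterDecision:
    variant: Variant
    passed: bool
    failed_rules: tuple[str, ...] = ()
    error: Optional[str] = None

    def __post_init__(self) -> None:
        ok = not self.failed_rules and self.error is None
        assert self.passed == ok, "passed flag inconsistent with failed_rules/error"


def _decision(v: Variant, failed: list[str]) -> FilterDecision:
    return FilterDecision(variant=v, passed=not failed, failed_rules=tuple(failed))


def _missing(v: Variant, fields: Sequence[str]) -> Optional[str]:
    absent = [f for f in fields if getattr(v, f) is None]
    if absent:
        return f"missing required evidence: {', '.join(absent)}"
    return None


def _labels(v: Variant) -> set[str]:
    return {c.lower() for c in v.callers}


def filter_snv_mouse(
    variants: Iterable[Variant], preset: CallerPreset = MOUSE_WES
) -> list[FilterDecision]:
    """SNV cascade for tumor/normal exome calls.

    Pass requires tumor depth >= 30, >= 5 alt reads, somatic P < 0.01 and
    VAF >= 5%; calls between 2% and 5% VAF are rescued only when the second
    caller also detected them, and calls below 2% VAF always fail.
    """
    out = []
    for v in variants:
        err = _missing(v, ("depth_tumor", "alt_reads_tumor", "vaf_tumor", "somatic_p"))
        if err:
            out.append(FilterDecision(variant=v, passed=False, error=err))
            continue
        failed: list[str] = []
        if v.depth_tumor < 30:
            failed.append(RULE_MIN_DEPTH)
        if v.alt_reads_tumor < 5:
            failed.append(RULE_MIN_ALT_READS)
        if not v.somatic_p < 0.01:
            failed.append(RULE_SOMATIC_P)
        if v.vaf_tumor >= 0.05:
            pass
        elif v.vaf_tumor >= 0.02:
            if preset.rescue not in _labels(v):
                failed.append(RULE_SECOND_CALLER)
        else:
            failed.append(RULE_MIN_VAF)
        out.append(_decision(v, failed))
    return out


def filter_indel_mouse(
    variants: Iterable[Variant], preset: CallerPreset = MOUSE_WES
) -> list[FilterDecision]:
    """Indel cascade: both callers must agree (primary somatic P < 0.001),
    with depth >= 50, >= 10 alt reads and VAF >= 2%."""
    out = []
    for v in variants:
        err = _missing(v, ("depth_tumor", "alt_reads_tumor", "vaf_tumor", "somatic_p"))
        if err:
            out.append(FilterDecision(variant=v, passed=False, error=err))
            continue
        failed: list[str] = []
        if not preset.indel_required <= _labels(v):
            failed.append(RULE_CALLER_CONSENSUS)
        if not v.somatic_p < 0.001:
            failed.append(RULE_SOMATIC_P)
        if v.depth_tumor < 50:
            failed.append(RULE_MIN_DEPTH)
        if v.alt_reads_tumor < 10:
            failed.append(RULE_MIN_ALT_READS)
        if v.vaf_tumor < 0.02:
            failed.append(RULE_MIN_VAF)
        out.append(_decision(v, failed))
    return out


def filter_germline(variants: Iterable[Variant]) -> list[FilterDecision]:
    """Remove calls with matched-normal support: more than 5 alternative
    reads or a normal VAF greater than 1% (both strict)."""
    out = []
    for v in variants:
        err = _missing(v, ("alt_reads_normal", "vaf_normal"))
        if err:
            out.append(FilterDecision(variant=v, passed=False, error=err))
            continue
        failed: list[str] = []
        if v.alt_reads_normal > 5:
            failed.append(RULE_GERMLINE_ALT)
        if v.vaf_normal > 0.01:
            failed.append(RULE_GERMLINE_VAF)
        out.append(_decision(v, failed))
    return out


def filter_wgs_cellline(variants: Iterable[Variant]) -> list[FilterDecision]:
    """Cell-line WGS cascade: the caller's own PASS flag, depth strictly over
    30, at least 4 alt reads and VAF strictly greater than 0.05."""
    out = []
    for v in variants:
        if v.filter_status is None:
            out.append(
                FilterDecision(variant=v, passed=False, error="missing caller filter status")
            )
            continue
        err = _missing(v, ("depth_tumor", "alt_reads_tumor", "vaf_tumor"))
        if err:
            out.append(FilterDecision(variant=v, passed=False, error=err))
            continue
        failed: list[str] = []
        if v.filter_status != "PASS":
            failed.append(RULE_CALLER_FILTER)
        if not v.depth_tumor > 30:
            failed.append(RULE_MIN_DEPTH)
        if v.alt_reads_tumor < 4:
            failed.append(RULE_MIN_ALT_READS)
        if not v.vaf_tumor > 0.05:
            failed.append(RULE_MIN_VAF)
        out.append(_decision(v, failed))
    return out


def _merge(a: FilterDecision, b: FilterDecision) -> FilterDecision:
    if a.error or b.error:
        return FilterDecision(
            variant=a.variant,
            passed=False,
            failed_rules=(),
            error="; ".join(e for e in (a.error, b.error) if e),
        )
    failed = a.failed_rules + b.failed_rules
    return FilterDecision(variant=a.variant, passed=not failed, failed_rules=failed)


def apply_preset(variants: Iterable[Variant], preset_name: str) -> list[FilterDecision]:
    """Run the full cascade for a named preset.

    ``mouse-wes`` routes SNVs and indels through their respective rule sets
    and then applies the germline filter to everything; ``cellline-wgs``
    applies the WGS cell-line rules (no matched-normal stage beyond the
    caller's own tumor/normal mode).
    """
    preset = PRESETS[preset_name]
    vs = list(variants)
    if preset_name == "cellline-wgs":
        return filter_wgs_cellline(vs)
    snvs = [v for v in vs if not v.is_indel]
    indels = [v for v in vs if v.is_indel]
    stage1 = {id(d.variant): d for d in filter_snv_mouse(snvs, preset)}
    stage1.update({id(d.variant): d for d in filter_indel_mouse(indels, preset)})
    germ = {id(d.variant): d for d in filter_germline(vs)}
    return [_merge(stage1[id(v)], germ[id(v)]) for v in vs]


def audit_summary(decisions: list[FilterDecision]) -> dict[str, int]:
    return {
        "input": len(decisions),
        "passed": sum(d.passed for d in decisions),
        "failed": sum((not d.passed) and d.error is None for d in decisions),
        "errors": sum(d.error is not None for d in decisions),
    }
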