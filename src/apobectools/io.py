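"""Readers and writers for the pipeline's external formats.

Variants travel as a minimal VCF 4.2 dialect (caller provenance in the
``CALLERS`` INFO key, somatic P in ``SOMP``, clonality in ``CLON``, evidence
in ``DP``/``ALTR``/``VAF``/``NALTR``/``NVAF``, sample in ``SAMPLE``; the
caller's own filter verdict uses the FILTER column) or as a documented TSV.
Variant coordinates are 1-based inclusive; segment tables are 0-based
half-open.  All writers order records deterministically and are exact
inverses of the corresponding readers on valid data.
"""

from __future__ import annotations

import logging
import math
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .channels import CHANNEL_LABELS
from .cin import RegionSegments, Segment
from .errors import FormatError, ValidationError
from .reference import ReferenceStore
from .signatures import SignatureSet
from .variants import Variant, sorted_variants

log = logging.getLogger(__name__)

_VCF_INFO_DEFS = [
    ("SAMPLE", "1", "String", "Sample identifier"),
    ("DP", "1", "Integer", "Tumor sequencing depth"),
    ("ALTR", "1", "Integer", "Tumor alternate read count"),
    # fractions travel as strings so full double precision round-trips
    # (VCF Float INFO fields are parsed as 32-bit floats by htslib)
    ("VAF", "1", "String", "Tumor variant allele frequency"),
    ("NALTR", "1", "Integer", "Matched-normal alternate read count"),
    ("NVAF", "1", "String", "Matched-normal variant allele frequency"),
    ("SOMP", "1", "String", "Somatic P value from the primary caller"),
    ("CALLERS", ".", "String", "Callers reporting this variant"),
    ("CLON", "1", "String", "Clonality label (clonal/subclonal/unknown)"),
]

TSV_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt",
    "depth_tumor", "alt_reads_tumor", "vaf_tumor", "somatic_p",
    "callers", "alt_reads_normal", "vaf_normal", "clonality", "filter_status",
]


def read_variants(path, format: str = "vcf") -> list[Variant]:
    """Read somatic calls from a VCF (via pysam) or a tabular TSV.

    Multi-allelic VCF records are split into one variant per alternate
    allele; per-record evidence is carried onto each split allele.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValidationError(f"unknown variant format {format!r} (expected 'vcf' or 'tsv')")


def _opt(value, cast):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return cast(value)


def _info_get(info, key, default=None):
    # pysam raises ValueError for keys absent from the header declarations
    try:
        return info.get(key, default)
    except (KeyError, ValueError):
        return default


def _read_vcf(path) -> list[Variant]:
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    variants = []
    with vf:
        for i, rec in enumerate(vf.fetch() if vf.index else vf, start=1):
            info = rec.info
            callers = _info_get(info, "CALLERS", ())
            if isinstance(callers, str):
                callers = (callers,)
            filt = list(rec.filter.keys())
            for alt in rec.alts or ():
                try:
                    variants.append(
                        Variant(
                            sample_id=str(_info_get(info, "SAMPLE", "sample")),
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            depth_tumor=_opt(_info_get(info, "DP"), int),
                            alt_reads_tumor=_opt(_info_get(info, "ALTR"), int),
                            vaf_tumor=_opt(_info_get(info, "VAF"), float),
                            somatic_p=_opt(_info_get(info, "SOMP"), float),
                            callers=frozenset(callers),
                            alt_reads_normal=_opt(_info_get(info, "NALTR"), int),
                            vaf_normal=_opt(_info_get(info, "NVAF"), float),
                            clonality=str(_info_get(info, "CLON", "unknown")),
                            filter_status=filt[0] if filt else None,
                        )
                    )
                except ValidationError as exc:
                    raise ValidationError(f"{path} record {i}: {exc}") from exc
    return variants


def _read_tsv(path) -> list[Variant]:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse variant TSV {path}: {exc}") from exc
    missing = set(TSV_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    variants = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        callers = getattr(row, "callers", None)
        if callers is None or (isinstance(callers, float) and math.isnan(callers)):
            caller_set: frozenset[str] = frozenset()
        else:
            caller_set = frozenset(c for c in str(callers).split(",") if c)
        filt = getattr(row, "filter_status", None)
        if isinstance(filt, float) and math.isnan(filt):
            filt = None
        clon = getattr(row, "clonality", "unknown")
        if isinstance(clon, float) and math.isnan(clon):
            clon = "unknown"
        try:
            variants.append(
                Variant(
                    sample_id=str(row.sample_id),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=str(row.ref),
                    alt=str(row.alt),
                    depth_tumor=_opt(getattr(row, "depth_tumor", None), int),
                    alt_reads_tumor=_opt(getattr(row, "alt_reads_tumor", None), int),
                    vaf_tumor=_opt(getattr(row, "vaf_tumor", None), float),
                    somatic_p=_opt(getattr(row, "somatic_p", None), float),
                    callers=caller_set,
                    alt_reads_normal=_opt(getattr(row, "alt_reads_normal", None), int),
                    vaf_normal=_opt(getattr(row, "vaf_normal", None), float),
                    clonality=str(clon),
                    filter_status=filt,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
    return variants


def _fmt_float(x: float) -> str:
    return repr(float(x))  # shortest exact representation


def write_variants(variants: list[Variant], path, format: str = "vcf") -> None:
    """Write variants in deterministic (sample, chrom, pos, ref, alt) order;
    output is byte-stable for a fixed input."""
    ordered = sorted_variants(list(variants))
    if format == "vcf":
        _write_vcf(ordered, path)
    elif format == "tsv":
        _write_tsv(ordered, path)
    else:
        raise ValidationError(f"unknown variant format {format!r}")


def _write_vcf(variants: list[Variant], path) -> None:
    lines = ["##fileformat=VCFv4.2", "##source=apobectools"]
    for contig in sorted({v.chrom for v in variants}):
        lines.append(f"##contig=<ID={contig}>")
    for key, num, typ, desc in _VCF_INFO_DEFS:
        lines.append(f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in variants:
        info = [f"SAMPLE={v.sample_id}"]
        if v.depth_tumor is not None:
            info.append(f"DP={v.depth_tumor}")
        if v.alt_reads_tumor is not None:
            info.append(f"ALTR={v.alt_reads_tumor}")
        if v.vaf_tumor is not None:
            info.append(f"VAF={_fmt_float(v.vaf_tumor)}")
        if v.alt_reads_normal is not None:
            info.append(f"NALTR={v.alt_reads_normal}")
        if v.vaf_normal is not None:
            info.append(f"NVAF={_fmt_float(v.vaf_normal)}")
        if v.somatic_p is not None:
            info.append(f"SOMP={_fmt_float(v.somatic_p)}")
        if v.callers:
            info.append("CALLERS=" + ",".join(sorted(v.callers)))
        if v.clonality != "unknown":
            info.append(f"CLON={v.clonality}")
        filt = v.filter_status if v.filter_status is not None else "."
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t{filt}\t" + ";".join(info)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _write_tsv(variants: list[Variant], path) -> None:
    rows = []
    for v in variants:
        rows.append(
            {
                "sample_id": v.sample_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "depth_tumor": v.depth_tumor,
                "alt_reads_tumor": v.alt_reads_tumor,
                "vaf_tumor": v.vaf_tumor,
                "somatic_p": v.somatic_p,
                "callers": ",".join(sorted(v.callers)),
                "alt_reads_normal": v.alt_reads_normal,
                "vaf_normal": v.vaf_normal,
                "clonality": v.clonality,
                "filter_status": v.filter_status,
            }
        )
    df = pd.DataFrame(rows, columns=TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_signature_matrix(path) -> SignatureSet:
    """Load a COSMIC-style signature TSV: first column the 96 channel labels,
    remaining columns one signature each.

    Rows may appear in any order but must cover exactly the 96 canonical
    labels; they are reindexed into canonical order.  Columns that do not sum
    to 1 within 1e-6 are renormalized with a logged warning.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse signature matrix {path}: {exc}") from exc
    if df.shape[0] != 96 or set(df.index) != set(CHANNEL_LABELS):
        raise FormatError(
            f"{path}: expected exactly the 96 COSMIC channel labels, "
            f"got {df.shape[0]} rows"
        )
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no signature columns")
    df = df.loc[list(CHANNEL_LABELS)]
    matrix = df.to_numpy(dtype=float)
    if (matrix < 0).any():
        raise FormatError(f"{path}: negative signature entries")
    sums = matrix.sum(axis=0)
    if (sums <= 0).any():
        raise FormatError(f"{path}: signature column sums to zero")
    off = np.abs(sums - 1.0) > 1e-6
    if off.any():
        bad = [df.columns[j] for j in np.where(off)[0]]
        log.warning("renormalizing signature columns not summing to 1: %s", bad)
        matrix = matrix / sums
    return SignatureSet(names=[str(c) for c in df.columns], matrix=matrix)


def load_bundled_signatures() -> SignatureSet:
    """The bundled *synthetic* signature reference.

    Five profiles (SBS1-, SBS2-, SBS5-, SBS13-, SBS40-like) with the
    qualitative shape of their COSMIC namesakes — CpG-deamination C>T,
    APOBEC C>T at TCN, flat clock-like, APOBEC C>G at TCN, and a flat
    C>A-tilted background.  They are deliberate approximations for
    simulation and testing; swap in a real COSMIC TSV via
    :func:`read_signature_matrix` for analyses of real data.
    """
    from importlib.resources import files

    path = files("apobectools.data") / "signatures_synthetic.tsv"
    return read_signature_matrix(str(path))


def write_signature_matrix(signatures: SignatureSet, path) -> None:
    df = pd.DataFrame(
        signatures.matrix, index=list(CHANNEL_LABELS), columns=signatures.names
    )
    df.index.name = "MutationType"
    df.to_csv(path, sep="\t", float_format="%.8f", lineterminator="\n")


SEGMENT_COLUMNS = ["tumor_id", "region_id", "chrom", "start", "end", "total_cn"]


def read_segments(path) -> dict[str, RegionSegments]:
    """Read a multi-region copy-number segment table (0-based half-open
    coordinates) into one :class:`RegionSegments` per tumor."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"tumor_id": str, "region_id": str, "chrom": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse segment table {path}: {exc}") from exc
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    tumors: dict[str, RegionSegments] = {}
    for tumor_id, tdf in df.groupby("tumor_id", sort=True):
        regions: dict[str, list[Segment]] = {}
        for row in tdf.itertuples(index=False):
            regions.setdefault(str(row.region_id), []).append(
                Segment(
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    total_cn=int(row.total_cn),
                )
            )
        tumors[str(tumor_id)] = RegionSegments(tumor_id=str(tumor_id), regions=regions)
    return tumors


def write_segments(tumors: dict[str, RegionSegments], path) -> None:
    rows = []
    for tumor_id in sorted(tumors):
        rs = tumors[tumor_id]
        for region_id in sorted(rs.regions):
            for s in rs.regions[region_id]:
                rows.append(
                    {
                        "tumor_id": tumor_id,
                        "region_id": region_id,
                        "chrom": s.chrom,
                        "start": s.start,
                        "end": s.end,
                        "total_cn": s.total_cn,
                    }
                )
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_fasta(path) -> ReferenceStore:
    """Load a FASTA reference with uppercase normalization."""
    return ReferenceStore.from_fasta(path)
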