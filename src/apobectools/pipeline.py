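"""End-to-end pipeline: simulate -> filter -> contexts -> catalogs -> refit
-> CIN metrics -> statistics, with TSV/JSON/plot outputs.

The pipeline is a pure function of (config, seed): running it twice with the
same configuration produces byte-identical JSON summaries.  Every stage logs
one structured line with its input/output counts so filtering is auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .contexts import apobec_fractions, classify_variants, count_apobec_mutations
from .errors import ApobecToolsError, ValidationError


class PipelineStageError(ApobecToolsError):
    """A pipeline stage failed; the message is tagged with the stage name."""
from .filters import apply_preset, audit_summary, PRESETS
from .cin import scna_ith
from .signatures import (
    ExposureProfile,
    apobec_signature_burden,
    build_catalog96,
    clonal_subclonal_apobec_diff,
    dominant_signature,
    refit_signatures,
)
from .simulate import (
    ApobecBurst,
    EvidenceModel,
    SimSpec,
    simulate_caller_calls,
    simulate_catalog,
    simulate_multiregion_segments,
    simulate_paired_cohort,
    simulate_reference,
)
from .reference import write_fasta
from .variants import Variant

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run configuration; loadable from YAML or JSON."""

    seed: int = 17
    signature_cutoff: float = 0.06
    min_mutations: int = 10
    out_dir: str = "results"
    preset: str = "mouse-wes"
    # simulation conditions
    genome_length: int = 100_000
    gc_fraction: float = 0.5
    sample_mutations: dict[str, int] = field(default_factory=lambda: {"S1": 2000})
    signature_weights: dict[str, float] = field(
        default_factory=lambda: {"SBS2": 0.2, "SBS13": 0.1, "SBS5": 0.7}
    )
    clonal_fraction: float = 0.6
    n_regions: int = 3
    n_clonal_events: int = 2
    n_subclonal_events: int = 2
    clonal_event_bp: int = 20_000
    subclonal_event_bp: int = 10_000
    n_patients: int = 6
    pre_mutations: int = 150
    burst_extra: int = 40
    signatures_path: Optional[str] = None
    make_plots: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.signature_cutoff < 1:
            raise ValidationError("signature_cutoff must be in [0, 1)")
        if self.min_mutations < 0:
            raise ValidationError("min_mutations must be >= 0")
        if self.preset not in PRESETS:
            raise ValidationError(f"unknown preset {self.preset!r}")


def load_config(path) -> PipelineConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(data, dict):
        raise ValidationError(f"config {path} did not parse to a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def _spec_for(config: PipelineConfig, n_mutations: int) -> SimSpec:
    return SimSpec(
        genome_length=config.genome_length,
        gc_fraction=config.gc_fraction,
        n_mutations=n_mutations,
        signature_weights=dict(config.signature_weights),
        clonal_fraction=config.clonal_fraction,
        n_regions=config.n_regions,
        n_clonal_events=config.n_clonal_events,
        n_subclonal_events=config.n_subclonal_events,
        clonal_event_bp=config.clonal_event_bp,
        subclonal_event_bp=config.subclonal_event_bp,
        seed=config.seed,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle to ``config.out_dir``.

    Returns the JSON-serializable summary that is also written to
    ``summary.json``.  Any stage failure raises with a stage-tagged message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": {"seed": config.seed, "preset": config.preset,
                                "signature_cutoff": config.signature_cutoff,
                                "min_mutations": config.min_mutations}}
    stage = "simulate"
    try:
        signatures = (
            aio.read_signature_matrix(config.signatures_path)
            if config.signatures_path
            else aio.load_bundled_signatures()
        )
        reference = simulate_reference(config.genome_length, config.gc_fraction, config.seed)
        write_fasta(reference, out / "reference.fa")

        raw: list[Variant] = []
        for i, (sample_id, n_mut) in enumerate(sorted(config.sample_mutations.items())):
            rng = np.random.default_rng([config.seed, 1, i])
            sim = simulate_catalog(
                reference, _spec_for(config, n_mut), signatures, sample_id=sample_id, rng=rng
            )
            raw.extend(sim.variants)
        model = EvidenceModel()
        calls = simulate_caller_calls(raw, model, seed=config.seed + 101)
        aio.write_variants(calls, out / "variants.vcf", format="vcf")
        segments, seg_truth = simulate_multiregion_segments(
            _spec_for(config, 0), tumor_id="T1", seed=config.seed + 202
        )
        aio.write_segments({"T1": segments}, out / "segments.tsv")
        pairs = simulate_paired_cohort(
            reference,
            _spec_for(config, config.pre_mutations),
            ApobecBurst(n_extra=config.burst_extra),
            n_patients=config.n_patients,
            seed=config.seed + 303,
            signatures=signatures,
        )
        log.info("stage=simulate samples=%d variants=%d patients=%d",
                 len(config.sample_mutations), len(calls), len(pairs))

        stage = "filter"
        decisions = apply_preset(calls, config.preset)
        audit = audit_summary(decisions)
        passing = [d.variant for d in decisions if d.passed]
        pd.DataFrame(
            {
                "sample_id": [d.variant.sample_id for d in decisions],
                "chrom": [d.variant.chrom for d in decisions],
                "pos": [d.variant.pos for d in decisions],
                "ref": [d.variant.ref for d in decisions],
                "alt": [d.variant.alt for d in decisions],
                "passed": [d.passed for d in decisions],
                "failed_rules": [",".join(d.failed_rules) for d in decisions],
                "error": [d.error or "" for d in decisions],
            }
        ).to_csv(out / "filter_audit.tsv", sep="\t", index=False, lineterminator="\n")
        summary["filter"] = audit
        log.info("stage=filter in=%d passed=%d failed=%d errors=%d",
                 audit["input"], audit["passed"], audit["failed"], audit["errors"])

        stage = "contexts"
        summary["contexts"] = {}
        context_rows = []
        sample_calls: dict[str, list] = {}
        for sample_id in sorted(config.sample_mutations):
            sample_vars = [v for v in passing if v.sample_id == sample_id]
            ctx, qc = classify_variants(reference, sample_vars)
            sample_calls[sample_id] = ctx
            entry: dict = {
                "n_classified": qc.n_classified,
                "n_no_context": qc.n_no_context,
                "n_non_snv": qc.n_non_snv,
            }
            if ctx:
                entry["fractions"] = apobec_fractions(ctx)
                entry["apobec_counts"] = count_apobec_mutations(
                    ctx, stratify_by_clonality=True
                )
            summary["contexts"][sample_id] = entry
            for c in ctx:
                context_rows.append(
                    {
                        "sample_id": sample_id,
                        "chrom": c.variant.chrom,
                        "pos": c.variant.pos,
                        "trinucleotide": c.trinucleotide,
                        "pentanucleotide": c.pentanucleotide or "",
                        "strand_flipped": c.strand_flipped,
                        "is_tcn": c.is_tcn,
                        "is_tcw": c.is_tcw,
                        "is_rtcw": c.is_rtcw,
                        "is_ytcw": c.is_ytcw,
                        "clonality": c.variant.clonality,
                    }
                )
        pd.DataFrame(context_rows).to_csv(
            out / "contexts.tsv", sep="\t", index=False, lineterminator="\n"
        )
        log.info("stage=contexts samples=%d rows=%d", len(sample_calls), len(context_rows))

        stage = "signatures"
        summary["signatures"] = {}
        summary["excluded_samples"] = []
        cat_frame = {}
        for sample_id, ctx in sample_calls.items():
            catalog = build_catalog96(ctx, sample_id=sample_id)
            cat_frame[sample_id] = catalog.counts
            exposure = refit_signatures(
                catalog, signatures,
                cutoff=config.signature_cutoff, min_mutations=config.min_mutations,
            )
            if exposure.excluded:
                summary["excluded_samples"].append(
                    {"sample_id": sample_id, "reason": exposure.exclusion_reason}
                )
                summary["signatures"][sample_id] = {"excluded": True}
                continue
            dom, tie = dominant_signature(exposure)
            summary["signatures"][sample_id] = {
                "excluded": False,
                "weights": exposure.weights,
                "dominant": dom,
                "dominant_tie": tie,
                "cosine_similarity": exposure.cosine_similarity,
                "reconstruction_error": exposure.reconstruction_error,
                "apobec_burden": apobec_signature_burden(exposure, exposure.n_mutations),
            }
            if config.make_plots:
                from .plotting import plot_catalog96

                plot_catalog96(catalog, out / f"profile_{sample_id}.png")
        from .channels import CHANNEL_LABELS

        pd.DataFrame(cat_frame, index=list(CHANNEL_LABELS)).rename_axis(
            "MutationType"
        ).to_csv(out / "catalog96.tsv", sep="\t", lineterminator="\n")
        log.info("stage=signatures samples=%d excluded=%d",
                 len(sample_calls), len(summary["excluded_samples"]))

        stage = "cin"
        summary["cin"] = {
            "scna_ith": scna_ith(segments),
            "ground_truth_ith": seg_truth["ith"],
            "heterogeneous_bp": seg_truth["heterogeneous_bp"],
            "altered_bp": seg_truth["altered_bp"],
        }
        log.info("stage=cin ith=%.4f", summary["cin"]["scna_ith"])

        stage = "stats"
        from .stats import wilcoxon_signed_rank

        pre_counts, post_counts, pre_apo, post_apo = [], [], [], []
        patient_ctx = {}
        for pair in pairs:
            pre_ctx, _ = classify_variants(reference, pair.pre)
            post_ctx, _ = classify_variants(reference, pair.post)
            patient_ctx[pair.patient_id] = post_ctx
            pre_counts.append(len(pair.pre))
            post_counts.append(len(pair.post))
            pre_apo.append(count_apobec_mutations(pre_ctx)["apobec_total"])
            post_apo.append(count_apobec_mutations(post_ctx)["apobec_total"])
        burden_test = wilcoxon_signed_rank(
            [b - a for a, b in zip(pre_counts, post_counts)], sidedness="two"
        )
        apobec_test = wilcoxon_signed_rank(
            [b - a for a, b in zip(pre_apo, post_apo)], sidedness="two"
        )
        cs = clonal_subclonal_apobec_diff(
            patient_ctx, signatures,
            cutoff=config.signature_cutoff, min_mutations=config.min_mutations,
        )
        summary["stats"] = {
            "paired_burden": {
                "pre": pre_counts, "post": post_counts,
                "p_value": burden_test.p_value, "method": burden_test.method,
            },
            "paired_apobec_count": {
                "pre": pre_apo, "post": post_apo,
                "p_value": apobec_test.p_value, "method": apobec_test.method,
            },
            "clonal_subclonal_apobec": {
                "diffs": cs["diffs"],
                "flagged": cs["flagged"],
                "p_value": cs["test"].p_value if cs["test"] else None,
            },
        }
        log.info("stage=stats patients=%d", len(pairs))
    except Exception as exc:
        raise PipelineStageError(f"[stage={stage}] {exc}") from exc

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
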