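"""Synthetic-data generators for every input the pipeline consumes.

The generators emulate the statistical structure the analysis assumes —
mutation catalogs drawn from signature mixtures on a generated reference,
paired pre-/post-treatment cohorts where the post sample adds an
APOBEC-context mutation burst, multi-caller call sets with realistic
evidence, and multi-region copy-number profiles with clonal and
region-restricted events — so that every downstream stage is testable
without controlled-access sequencing data.  Every generator is reproducible
bit-for-bit given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .channels import (
    BASES,
    CHANNEL_LABELS,
    PYRIMIDINE_TRINUCLEOTIDES,
    channel_substitution,
    channel_trinucleotide,
    COMPLEMENT,
)
from .cin import RegionSegments, Segment
from .errors import ValidationError
from .reference import ReferenceStore
from .signatures import SignatureSet
from .variants import Variant


@dataclass
class SimSpec:
    """Conditions for one simulated sample/tumor.

    Defaults describe a desk-scale tumor with a mixed APOBEC + clock-like
    mutational process (20% SBS2-like, 10% SBS13-like, 70% SBS5-like), a
    mildly clonally dominated architecture, and a three-region copy-number
    profile carrying both truncal and region-restricted events.
    """

    genome_length: int = 200_000
    gc_fraction: float = 0.5
    n_mutations: int = 5_000
    signature_weights: dict[str, float] = field(
        default_factory=lambda: {"SBS2": 0.2, "SBS13": 0.1, "SBS5": 0.7}
    )
    clonal_fraction: float = 0.6
    n_regions: int = 3
    n_clonal_events: int = 2
    n_subclonal_events: int = 2
    clonal_event_bp: int = 20_000
    subclonal_event_bp: int = 10_000
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_mutations < 0:
            raise ValidationError("n_mutations must be >= 0")
        if not 0 <= self.gc_fraction <= 1:
            raise ValidationError("gc_fraction must be in [0, 1]")
        if not 0 <= self.clonal_fraction <= 1:
            raise ValidationError("clonal_fraction must be in [0, 1]")
        w = list(self.signature_weights.values())
        if any(x < 0 for x in w):
            raise ValidationError("signature weights must be nonnegative")
        if w and abs(sum(w) - 1.0) > 1e-9:
            raise ValidationError(f"signature weights sum to {sum(w)}, not 1")


def simulate_reference(
    length: int, gc_fraction: float, seed: int, contig: str = "chr1"
) -> ReferenceStore:
    """An i.i.d. random genome with the requested GC content."""
    if length < 1000:
        raise ValidationError("reference must be at least 1 kb for context extraction")
    at, gc = (1.0 - gc_fraction) / 2.0, gc_fraction / 2.0
    rng = np.random.default_rng(seed)
    codes = rng.choice(4, size=length, p=[at, gc, gc, at])
    seq = "".join(BASES[c] for c in codes)
    return ReferenceStore({contig: seq})


_CODE = {b: i for i, b in enumerate(BASES)}


def _site_index(reference: ReferenceStore) -> dict[str, dict[str, np.ndarray]]:
    """1-based positions of every interior site, keyed by contig then by the
    pyrimidine-oriented trinucleotide at that site."""
    index: dict[str, dict[str, np.ndarray]] = {}
    for contig in reference.contigs:
        seq = reference.sequence(contig)
        codes = np.fromiter((_CODE.get(b, -1) for b in seq), dtype=np.int8, count=len(seq))
        a, b, c = codes[:-2], codes[1:-1], codes[2:]
        valid = (a >= 0) & (b >= 0) & (c >= 0)
        fwd = 16 * a.astype(np.int32) + 4 * b + c
        rev = 16 * (3 - c.astype(np.int32)) + 4 * (3 - b) + (3 - a)
        oriented = np.where((b == 1) | (b == 3), fwd, rev)  # center C or T kept
        pos = np.arange(2, len(seq), dtype=np.int64)  # 1-based center positions
        per: dict[str, np.ndarray] = {}
        for tri in PYRIMIDINE_TRINUCLEOTIDES:
            code = 16 * _CODE[tri[0]] + 4 * _CODE[tri[1]] + _CODE[tri[2]]
            per[tri] = pos[valid & (oriented == code)]
        index[contig] = per
    return index


@dataclass
class SimulatedCatalog:
    """A drawn mutation set together with its ground-truth channel counts."""

    variants: list[Variant]
    channel_counts: np.ndarray  # (96,) — the sampled channel draw
    sampling_probs: np.ndarray  # (96,) — availability-reweighted spectrum


def simulate_catalog(
    reference: ReferenceStore,
    spec: SimSpec,
    signatures: SignatureSet,
    sample_id: str = "S1",
    rng: Optional[np.random.Generator] = None,
) -> SimulatedCatalog:
    """Draw a mutation catalog from a signature mixture on the reference.

    Channels are sampled from the mixture spectrum reweighted by the
    genome's trinucleotide availability (renormalized), then a site is drawn
    uniformly without replacement among the matching sites on either strand;
    purine-strand sites are emitted as the complementary substitution.
    Clonality labels are assigned Bernoulli(``clonal_fraction``).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    for name in spec.signature_weights:
        if name not in signatures.names:
            raise ValidationError(f"signature {name!r} not in the reference set")
    spectrum = np.zeros(96)
    for name, w in spec.signature_weights.items():
        spectrum += w * signatures.profile(name)

    index = _site_index(reference)
    avail = np.zeros(96)
    for i in range(96):
        tri = channel_trinucleotide(i)
        avail[i] = sum(len(per[tri]) for per in index.values())
    needed = spectrum > 0
    starved = needed & (avail == 0)
    if starved.any():
        labels = [CHANNEL_LABELS[i] for i in np.where(starved)[0]]
        raise ValidationError(f"no available sites for required channels: {labels}")
    if spec.n_mutations == 0:
        return SimulatedCatalog([], np.zeros(96, dtype=np.int64), spectrum)

    probs = spectrum * avail
    probs = probs / probs.sum()
    counts = rng.multinomial(spec.n_mutations, probs)

    # draw distinct sites per trinucleotide (channels sharing a context draw
    # from the same site pool, so sampling is without replacement jointly)
    variants: list[Variant] = []
    for tri in PYRIMIDINE_TRINUCLEOTIDES:
        chans = [i for i in range(96) if channel_trinucleotide(i) == tri]
        n_tri = int(sum(counts[i] for i in chans))
        if n_tri == 0:
            continue
        pool = [
            (contig, p) for contig, per in index.items() for p in per[tri]
        ]
        if n_tri > len(pool):
            raise ValidationError(
                f"trinucleotide {tri}: {n_tri} mutations requested but only "
                f"{len(pool)} sites available"
            )
        picks = rng.choice(len(pool), size=n_tri, replace=False)
        cursor = 0
        for chan in chans:
            for _ in range(int(counts[chan])):
                contig, pos = pool[picks[cursor]]
                cursor += 1
                ref_py, alt_py = channel_substitution(chan)
                center = reference.base(contig, int(pos))
                if center == ref_py:
                    ref, alt = ref_py, alt_py
                else:  # purine strand: emit the complementary substitution
                    ref, alt = COMPLEMENT[ref_py], COMPLEMENT[alt_py]
                clonality = "clonal" if rng.random() < spec.clonal_fraction else "subclonal"
                variants.append(
                    Variant(
                        sample_id=sample_id,
                        chrom=contig,
                        pos=int(pos),
                        ref=ref,
                        alt=alt,
                        clonality=clonality,
                    )
                )
    return SimulatedCatalog(variants, counts.astype(np.int64), probs)


@dataclass
class ApobecBurst:
    """A treatment-associated burst of APOBEC-context mutations."""

    n_extra: int = 50
    tcw_only: bool = True
    ct_cg_odds: float = 2.0  # C>T : C>G odds at burst sites


@dataclass
class PatientPair:
    patient_id: str
    pre: list[Variant]
    post: list[Variant]


def simulate_paired_cohort(
    reference: ReferenceStore,
    spec_pre: SimSpec,
    burst: ApobecBurst,
    n_patients: int,
    seed: int,
    signatures: SignatureSet,
) -> list[PatientPair]:
    """Paired pre-/post-treatment variant sets per patient.

    The post-treatment set is the pre set plus ``burst.n_extra`` additional
    mutations placed at unused TCW sites (C>T or C>G with the configured
    odds), labelled subclonal — emulating mutagenesis acquired under therapy.
    """
    if n_patients < 1:
        raise ValidationError("n_patients must be >= 1")
    index = _site_index(reference)
    tcw_pool = [
        (contig, int(p))
        for contig, per in index.items()
        for tri in ("TCA", "TCT")
        for p in per[tri]
    ]
    pairs = []
    p_ct = burst.ct_cg_odds / (1.0 + burst.ct_cg_odds)
    for i in range(n_patients):
        rng = np.random.default_rng([seed, i])
        pid = f"P{i + 1}"
        sim = simulate_catalog(
            reference, spec_pre, signatures, sample_id=f"{pid}_pre", rng=rng
        )
        pre = sim.variants
        used = {(v.chrom, v.pos) for v in pre}
        free = [s for s in tcw_pool if s not in used]
        if burst.n_extra > len(free):
            raise ValidationError(
                f"{pid}: burst of {burst.n_extra} exceeds {len(free)} free TCW sites"
            )
        picks = rng.choice(len(free), size=burst.n_extra, replace=False)
        post = [v.with_(sample_id=f"{pid}_post") for v in pre]
        for j in picks:
            contig, pos = free[j]
            alt_py = "T" if rng.random() < p_ct else "G"
            center = reference.base(contig, pos)
            if center == "C":
                ref, alt = "C", alt_py
            else:
                ref, alt = "G", COMPLEMENT[alt_py]
            post.append(
                Variant(
                    sample_id=f"{pid}_post",
                    chrom=contig,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    clonality="subclonal",
                )
            )
        pairs.append(PatientPair(patient_id=pid, pre=pre, post=post))
    return pairs


def simulate_multiregion_segments(
    spec: SimSpec,
    tumor_id: str = "T1",
    chrom: str = "chr1",
    seed: Optional[int] = None,
) -> tuple[RegionSegments, dict]:
    """Multi-region copy-number profile with planted clonal and subclonal
    events on disjoint intervals.

    Clonal events place the same non-diploid state in every region;
    subclonal events alter a proper subset of regions, so they are
    heterogeneous by construction.  Returns the profile and the ground-truth
    heterogeneous/altered base counts.
    """
    if spec.n_regions < 2:
        raise ValidationError("need at least 2 regions")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    L = spec.genome_length
    events = []
    if spec.n_clonal_events:
        each = spec.clonal_event_bp // spec.n_clonal_events
        events += [("clonal", each)] * spec.n_clonal_events
    if spec.n_subclonal_events:
        each = spec.subclonal_event_bp // spec.n_subclonal_events
        events += [("subclonal", each)] * spec.n_subclonal_events
    total_event = sum(l for _, l in events)
    if total_event > L:
        raise ValidationError(
            f"requested event mass {total_event} exceeds genome length {L}"
        )
    order = rng.permutation(len(events))
    events = [events[i] for i in order]
    free = L - total_event
    offsets = np.sort(rng.integers(0, free + 1, size=len(events)))

    region_ids = [f"R{r + 1}" for r in range(spec.n_regions)]
    states: list[tuple[int, int, dict[str, int]]] = []  # (start, end, cn per region)
    altered_states = [1, 3, 4]
    placed = 0
    truth_het = 0
    truth_altered = 0
    for (kind, length), off in zip(events, offsets):
        start = int(off) + placed
        end = start + length
        placed += length
        if kind == "clonal":
            cn = int(rng.choice(altered_states))
            states.append((start, end, {r: cn for r in region_ids}))
            truth_altered += length
        else:
            m = int(rng.integers(1, spec.n_regions))
            carriers = set(rng.choice(spec.n_regions, size=m, replace=False))
            cn = int(rng.choice(altered_states))
            states.append(
                (start, end, {r: (cn if j in carriers else 2) for j, r in enumerate(region_ids)})
            )
            truth_altered += length
            truth_het += length

    regions: dict[str, list[Segment]] = {r: [] for r in region_ids}
    cursor = 0
    for start, end, cns in states:
        for r in region_ids:
            if start > cursor:
                regions[r].append(Segment(chrom, cursor, start, 2))
            regions[r].append(Segment(chrom, start, end, cns[r]))
        cursor = end
    if cursor < L:
        for r in region_ids:
            regions[r].append(Segment(chrom, cursor, L, 2))

    rs = RegionSegments(tumor_id=tumor_id, regions=regions, baseline_cn=2)
    truth = {
        "heterogeneous_bp": truth_het,
        "altered_bp": truth_altered,
        "ith": (truth_het / truth_altered) if truth_altered else None,
    }
    return rs, truth


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass
class EvidenceModel:
    """Distributions for caller evidence annotation.

    ``detection`` maps caller label to a detection-probability function of
    the true VAF; variants detected by no caller are dropped from the call
    set, as they would never appear in real caller output.
    """

    depth_mean: float = 80.0
    normal_depth_mean: float = 40.0
    vaf_beta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "clonal": (24.0, 36.0),  # mean 0.40
            "subclonal": (6.0, 34.0),  # mean 0.15
            "unknown": (8.0, 32.0),  # mean 0.20
        }
    )
    somatic_p_beta: tuple[float, float] = (0.5, 60.0)
    normal_contamination_vaf: float = 0.002
    detection: dict[str, Callable[[float], float]] = field(
        default_factory=lambda: {
            "varscan2": lambda v: _logistic((v - 0.03) / 0.012),
            "mutect": lambda v: _logistic((v - 0.015) / 0.008),
        }
    )

    @classmethod
    def perfect(cls, callers: Sequence[str] = ("varscan2", "mutect")) -> "EvidenceModel":
        """All callers detect every variant — useful for exact bookkeeping."""
        return cls(detection={c: (lambda v: 1.0) for c in callers})

    def mean_vaf(self, clonality: str) -> float:
        a, b = self.vaf_beta[clonality]
        return a / (a + b)


def simulate_caller_calls(
    variants: Sequence[Variant], model: EvidenceModel, seed: int
) -> list[Variant]:
    """Annotate variants with depth, alt reads, VAF, somatic P and caller
    provenance drawn from the evidence model; deterministic per seed."""
    rng = np.random.default_rng(seed)
    out = []
    for v in variants:
        a, b = model.vaf_beta[v.clonality]
        vaf_true = float(rng.beta(a, b))
        depth = max(1, int(rng.poisson(model.depth_mean)))
        alt = int(rng.binomial(depth, vaf_true))
        alt = max(1, min(alt, depth))  # a reported call always has >= 1 alt read
        callers = frozenset(
            name for name, f in model.detection.items() if rng.random() < f(vaf_true)
        )
        somatic_p = float(rng.beta(*model.somatic_p_beta))
        depth_n = max(1, int(rng.poisson(model.normal_depth_mean)))
        alt_n = int(rng.binomial(depth_n, model.normal_contamination_vaf))
        if not callers:
            continue  # undetected: never appears in a call set
        out.append(
            v.with_(
                vaf_tumor=alt / depth,
                depth_tumor=depth,
                alt_reads_tumor=alt,
                somatic_p=somatic_p,
                callers=callers,
                alt_reads_normal=alt_n,
                vaf_normal=alt_n / depth_n,
                filter_status="PASS",
            )
        )
    return out
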