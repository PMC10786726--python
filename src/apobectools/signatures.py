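"""96-channel mutation catalogs and reference-signature refitting.

Refitting expresses a sample's normalized catalog as a nonnegative mixture of
fixed single-base-substitution (SBS) signature profiles.  The fit follows the
forward-selection scheme popularized by deconstructSigs: seed with the single
best-fitting signature, then repeatedly re-optimize one signature weight at a
time with a bounded golden-section line search until the squared
reconstruction error stops improving.  Contributions below a cutoff (default
6%) are zeroed after convergence and the remaining weights renormalized;
samples with fewer than ``min_mutations`` (default 10) mutations are excluded
because signature discrimination is unreliable on tiny catalogs.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .channels import CHANNEL_LABELS, channel_index
from .contexts import ContextCall
from .errors import UnattributableError, UndefinedResultError, ValidationError

APOBEC_SIGNATURES = ("SBS2", "SBS13")

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass
class Catalog96:
    """Per-sample counts over the 96 trinucleotide substitution channels."""

    sample_id: str
    counts: np.ndarray  # shape (96,), nonnegative
    n_no_context: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96,):
            raise ValidationError(f"catalog must have 96 channels, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValidationError("catalog counts must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def fractions(self) -> np.ndarray:
        if self.total == 0:
            raise UndefinedResultError("empty catalog has no channel fractions")
        return self.counts / self.total


@dataclass
class SignatureSet:
    """Named reference signatures as columns of a 96 x k probability matrix."""

    names: list[str]
    matrix: np.ndarray  # shape (96, k), columns sum to 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.names)):
            raise ValidationError(
                f"signature matrix shape {self.matrix.shape} does not match "
                f"{len(self.names)} names"
            )
        if (self.matrix < 0).any():
            raise ValidationError("signature profiles must be nonnegative")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValidationError("signature profiles must sum to 1 within 1e-6")

    def profile(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def subset(self, names: Sequence[str]) -> "SignatureSet":
        idx = [self.names.index(n) for n in names]
        return SignatureSet(list(names), self.matrix[:, idx])


@dataclass
class ExposureProfile:
    """Refit result: per-signature contribution fractions for one sample."""

    sample_id: str
    weights: dict[str, float]
    excluded: bool = False
    exclusion_reason: Optional[str] = None
    reconstruction_error: Optional[float] = None  # sum of squared residuals
    cosine_similarity: Optional[float] = None
    n_mutations: int = 0

    def weight(self, name: str) -> float:
        return self.weights.get(name, 0.0)


def build_catalog96(calls: Iterable[ContextCall], sample_id: str = "sample") -> Catalog96:
    """Count classified SNVs into the 96 channels.

    Non-SNV / no-context mutations never reach this function (they are
    filtered out by :func:`apobectools.contexts.classify_variants`); the sum
    of the catalog equals the number of context calls supplied.
    """
    counts = np.zeros(96, dtype=np.int64)
    for call in calls:
        counts[call.channel] += 1
    return Catalog96(sample_id=sample_id, counts=counts)


def _sse(residual: np.ndarray) -> float:
    return float(residual @ residual)


def _golden_section(f, lo: float, hi: float, tol: float = 1e-4) -> tuple[float, float]:
    """Minimize a unimodal function on [lo, hi]; returns (x, f(x))."""
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    x = (a + b) / 2.0
    return x, f(x)


def refit_signatures(
    catalog: Catalog96,
    signatures: SignatureSet,
    cutoff: float = 0.06,
    min_mutations: int = 10,
    max_sweeps: int = 500,
    line_search_tol: float = 1e-4,
    improvement_tol: float = 1e-3,
) -> ExposureProfile:
    """Forward-selection signature refit with a contribution cutoff.

    The catalog is normalized to channel fractions ``m`` and the squared
    reconstruction error ``||m - P w||^2`` is minimized over nonnegative
    weights by coordinate descent: each sweep re-optimizes every signature's
    weight in turn with a golden-section search on [0, 1], starting from the
    single signature that best explains the catalog alone.  Sweeps stop when
    the relative error improvement falls below ``improvement_tol`` (or the
    error is numerically zero).  Weights are then normalized to fractions,
    contributions below ``cutoff`` are zeroed, and the survivors renormalized.
    """
    if not signatures.names:
        raise ValidationError("empty signature set")
    n_mut = int(round(catalog.total))
    if n_mut < min_mutations:
        return ExposureProfile(
            sample_id=catalog.sample_id,
            weights={name: 0.0 for name in signatures.names},
            excluded=True,
            exclusion_reason=f"only {n_mut} mutations (< {min_mutations})",
            n_mutations=n_mut,
        )
    m = catalog.fractions()
    P = signatures.matrix
    k = P.shape[1]

    # seed: best single signature, with its weight optimized alone
    w = np.zeros(k)
    seed_errs = [_sse(m - P[:, j]) for j in range(k)]
    seed = int(np.argmin(seed_errs))
    x, err = _golden_section(lambda t: _sse(m - t * P[:, seed]), 0.0, 1.0, line_search_tol)
    w[seed] = x

    for _ in range(max_sweeps):
        err_start = err
        for j in range(k):
            others = m - (P @ w - w[j] * P[:, j])
            xj, errj = _golden_section(
                lambda t: _sse(others - t * P[:, j]), 0.0, 1.0, line_search_tol
            )
            if errj < err:
                w[j] = xj
                err = errj
        if err <= 1e-14 or (err_start - err) < improvement_tol * max(err_start, 1e-12):
            break

    total_w = w.sum()
    if total_w <= 0:
        raise UndefinedResultError("refit produced all-zero weights")
    frac = w / total_w
    frac[frac < cutoff] = 0.0
    if frac.sum() == 0:
        raise UndefinedResultError("all signature contributions fell below the cutoff")
    frac /= frac.sum()

    recon = P @ frac
    resid = m - recon
    denom = np.linalg.norm(m) * np.linalg.norm(recon)
    cosine = float(m @ recon / denom) if denom > 0 else 0.0
    return ExposureProfile(
        sample_id=catalog.sample_id,
        weights={name: float(frac[j]) for j, name in enumerate(signatures.names)},
        reconstruction_error=_sse(resid),
        cosine_similarity=cosine,
        n_mutations=n_mut,
    )


def apobec_signature_burden(
    exposure: ExposureProfile,
    total_mutations: int,
    apobec_signatures: Sequence[str] = APOBEC_SIGNATURES,
) -> int:
    """APOBEC signature burden: (SBS2 + SBS13 weight) x mutation count,
    rounded half-up to a whole mutation count."""
    if exposure.excluded:
        raise UndefinedResultError(
            f"sample {exposure.sample_id} excluded: {exposure.exclusion_reason}"
        )
    weight = sum(exposure.weight(s) for s in apobec_signatures)
    return int(math.floor(weight * total_mutations + 0.5))


_SIG_NAME_RE = re.compile(r"^([A-Za-z]*)(\d*)([A-Za-z]*)$")


def _numeric_aware_key(name: str) -> tuple:
    m = _SIG_NAME_RE.match(name)
    if m:
        prefix, num, suffix = m.groups()
        return (prefix, int(num) if num else -1, suffix)
    return (name, -1, "")


def dominant_signature(exposure: ExposureProfile, tie_tol: float = 1e-9) -> tuple[str, bool]:
    """The signature with the highest contribution.

    Ties (within ``tie_tol``) are broken by numeric-aware name ordering
    (SBS2 before SBS13); the second element of the result flags a tie.
    """
    if exposure.excluded:
        raise UndefinedResultError(f"sample {exposure.sample_id} excluded")
    best = max(exposure.weights.values())
    if best <= 0:
        raise UndefinedResultError("all signature weights are zero")
    tied = sorted(
        (n for n, v in exposure.weights.items() if best - v <= tie_tol),
        key=_numeric_aware_key,
    )
    return tied[0], len(tied) > 1


def clonal_subclonal_apobec_diff(
    patient_calls: dict[str, list[ContextCall]],
    signatures: SignatureSet,
    cutoff: float = 0.06,
    min_mutations: int = 10,
    apobec_signatures: Sequence[str] = APOBEC_SIGNATURES,
    sidedness: str = "less",
):
    """Clonal-minus-subclonal APOBEC signature weight per patient, with a
    cohort-level one-sided Wilcoxon signed-rank test of the differences
    against zero.

    Signatures are refit separately on each patient's clonal and subclonal
    catalogs.  Patients whose clonal or subclonal catalog falls below
    ``min_mutations`` are flagged and omitted from the cohort test.  The
    default sidedness ("less") asks whether APOBEC activity is subclonally
    enriched, i.e. whether the differences are systematically negative.
    """
    from .stats import wilcoxon_signed_rank  # local import avoids a cycle

    diffs: dict[str, float] = {}
    flagged: list[str] = []
    for patient, calls in patient_calls.items():
        missing = [c.variant for c in calls if c.variant.clonality == "unknown"]
        if missing:
            raise ValidationError(
                f"patient {patient}: {len(missing)} variants lack clonality labels"
            )
        subsets = {}
        for clon in ("clonal", "subclonal"):
            cat = build_catalog96(
                [c for c in calls if c.variant.clonality == clon],
                sample_id=f"{patient}:{clon}",
            )
            subsets[clon] = refit_signatures(
                cat, signatures, cutoff=cutoff, min_mutations=min_mutations
            )
        if subsets["clonal"].excluded or subsets["subclonal"].excluded:
            flagged.append(patient)
            continue
        diffs[patient] = sum(
            subsets["clonal"].weight(s) for s in apobec_signatures
        ) - sum(subsets["subclonal"].weight(s) for s in apobec_signatures)

    result = None
    if diffs:
        try:
            result = wilcoxon_signed_rank(list(diffs.values()), sidedness=sidedness)
        except UndefinedResultError:
            result = None  # all diffs exactly zero: no evidence either way
    return {"diffs": diffs, "flagged": flagged, "test": result}


def attribute_mutation_signature(
    channel: int,
    exposure: ExposureProfile,
    signatures: SignatureSet,
    tie_tol: float = 1e-9,
) -> tuple[dict[str, float], str, bool]:
    """Posterior signature attribution for a single mutation channel.

    P(signature | channel) is proportional to weight x profile[channel].
    Returns (probability map over active signatures, argmax label, tie flag).
    """
    if exposure.excluded:
        raise UndefinedResultError(f"sample {exposure.sample_id} excluded")
    scores = {
        name: exposure.weight(name) * float(signatures.profile(name)[channel])
        for name in signatures.names
        if exposure.weight(name) > 0
    }
    norm = sum(scores.values())
    if norm <= 0:
        raise UnattributableError(
            f"channel {CHANNEL_LABELS[channel]} has zero probability under all "
            "active signatures"
        )
    probs = {name: s / norm for name, s in scores.items()}
    best = max(probs.values())
    tied = sorted((n for n, p in probs.items() if best - p <= tie_tol), key=_numeric_aware_key)
    return probs, tied[0], len(tied) > 1


def nnls_refit_oracle(catalog: Catalog96, signatures: SignatureSet) -> dict[str, float]:
    """Nonnegative-least-squares reference fit (scipy), normalized to sum 1.

    Used as an independent check of the forward-selection fit on exactly
    representable catalogs; it is not part of the refitting pipeline.
    """
    from scipy.optimize import nnls

    w, _ = nnls(signatures.matrix, catalog.fractions())
    if w.sum() == 0:
        raise UndefinedResultError("NNLS returned all-zero weights")
    w = w / w.sum()
    return {name: float(w[j]) for j, name in enumerate(signatures.names)}
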