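"""Catalog construction, signature refitting and derived quantities."""

import numpy as np
import pytest
from fractions import Fraction

from apobectools.channels import CHANNEL_LABELS
from apobectools.contexts import classify_variants
from apobectools.errors import (
    UnattributableError,
    UndefinedResultError,
    ValidationError,
)
from apobectools.reference import ReferenceStore
from apobectools.signatures import (
    Catalog96,
    ExposureProfile,
    SignatureSet,
    apobec_signature_burden,
    attribute_mutation_signature,
    build_catalog96,
    clonal_subclonal_apobec_diff,
    dominant_signature,
    nnls_refit_oracle,
    refit_signatures,
)
from apobectools.variants import Variant


def _catalog(counts, sample_id="s"):
    return Catalog96(sample_id=sample_id, counts=np.asarray(counts))


def _exact_blend(sigs, weights, total=1000.0):
    """Catalog with expected (unrounded) counts of a signature mixture."""
    v = np.zeros(96)
    for name, w in weights.items():
        v += w * sigs.profile(name)
    return _catalog(v * total)


class TestBuildCatalog:
    def test_single_mutation_channel_index(self):
        """A C>T in ACA context lands at index 16*2 + 0*4 + 0 = 32."""
        ref = ReferenceStore({"chr1": "AACAA"})
        calls, _ = classify_variants(
            ref, [Variant(sample_id="s", chrom="chr1", pos=3, ref="C", alt="T")]
        )
        cat = build_catalog96(calls)
        assert cat.counts[32] == 1 and cat.total == 1
        assert CHANNEL_LABELS[32] == "A[C>T]A"

    def test_empty_catalog(self):
        cat = build_catalog96([])
        assert cat.total == 0

    def test_sum_conservation(self, ref5k):
        seq = ref5k.sequence("chr1")
        rng = np.random.default_rng(41)
        variants = []
        for pos in rng.choice(np.arange(3, len(seq) - 2), size=200, replace=False):
            pos = int(pos)
            ref_base = seq[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            variants.append(Variant(sample_id="s", chrom="chr1", pos=pos, ref=ref_base, alt=alt))
        calls, _ = classify_variants(ref5k, variants)
        assert build_catalog96(calls).total == len(calls)


class TestRefit:
    def test_pure_signature_recovered_exactly(self, sigs):
        cat = _exact_blend(sigs, {"SBS2": 1.0})
        exp = refit_signatures(cat, sigs)
        assert exp.weights["SBS2"] == pytest.approx(1.0)
        assert sum(v for k, v in exp.weights.items() if k != "SBS2") == 0.0
        assert exp.cosine_similarity == pytest.approx(1.0)

    def test_two_signature_blend_matches_nnls_oracle(self, sigs):
        cat = _exact_blend(sigs, {"SBS2": 0.6, "SBS5": 0.4})
        exp = refit_signatures(cat, sigs)
        oracle = nnls_refit_oracle(cat, sigs)
        assert exp.weights["SBS2"] == pytest.approx(0.6, abs=0.02)
        assert exp.weights["SBS5"] == pytest.approx(0.4, abs=0.02)
        for name in sigs.names:
            assert exp.weights[name] == pytest.approx(oracle[name], abs=1e-3)

    def test_subcutoff_component_zeroed_and_renormalized(self, sigs):
        """A 5% third signature falls below the 6% cutoff: reported 0, and
        the surviving weights renormalize to 1."""
        cat = _exact_blend(sigs, {"SBS2": 0.57, "SBS5": 0.38, "SBS13": 0.05})
        exp = refit_signatures(cat, sigs, cutoff=0.06)
        assert exp.weights["SBS13"] == 0.0
        assert sum(exp.weights.values()) == pytest.approx(1.0)
        assert exp.weights["SBS2"] == pytest.approx(0.6, abs=0.02)

    def test_nine_mutation_sample_excluded(self, sigs):
        counts = np.zeros(96)
        counts[32] = 9
        exp = refit_signatures(_catalog(counts), sigs, min_mutations=10)
        assert exp.excluded
        assert "9" in exp.exclusion_reason

    def test_scaling_invariance(self, sigs):
        cat1 = _exact_blend(sigs, {"SBS2": 0.3, "SBS40": 0.7}, total=500)
        cat10 = _catalog(cat1.counts * 10)
        e1 = refit_signatures(cat1, sigs)
        e10 = refit_signatures(cat10, sigs)
        for name in sigs.names:
            assert e1.weights[name] == pytest.approx(e10.weights[name], abs=1e-6)

    def test_cosine_at_least_best_single_signature(self, sigs):
        rng = np.random.default_rng(47)
        counts = rng.multinomial(800, np.full(96, 1 / 96))
        cat = _catalog(counts)
        exp = refit_signatures(cat, sigs)
        m = cat.fractions()
        singles = []
        for j in range(len(sigs.names)):
            p = sigs.matrix[:, j]
            singles.append(float(m @ p / (np.linalg.norm(m) * np.linalg.norm(p))))
        assert exp.cosine_similarity >= max(singles) - 1e-9

    def test_empty_signature_set_rejected(self):
        with pytest.raises(ValidationError):
            refit_signatures(_catalog(np.ones(96)), SignatureSet([], np.zeros((96, 0))))


class TestDerivedQuantities:
    def _exposure(self, weights, **kw):
        return ExposureProfile(sample_id="s", weights=weights, **kw)

    def test_burden_arithmetic(self):
        exp = self._exposure({"SBS2": 0.3, "SBS13": 0.2, "SBS5": 0.5})
        assert apobec_signature_burden(exp, 200) == 100

    def test_burden_rounds_half_up(self):
        exp = self._exposure({"SBS2": 0.25, "SBS13": 0.0, "SBS5": 0.75})
        assert apobec_signature_burden(exp, 10) == 3  # 2.5 rounds up

    def test_burden_without_apobec_signatures(self):
        assert apobec_signature_burden(self._exposure({"SBS5": 1.0}), 500) == 0

    def test_burden_all_apobec(self):
        exp = self._exposure({"SBS2": 0.6, "SBS13": 0.4})
        assert apobec_signature_burden(exp, 123) == 123

    def test_burden_undefined_for_excluded(self):
        exp = self._exposure({}, excluded=True, exclusion_reason="too few")
        with pytest.raises(UndefinedResultError):
            apobec_signature_burden(exp, 5)

    def test_dominant_simple(self):
        name, tie = dominant_signature(self._exposure({"SBS1": 0.6, "SBS2": 0.4}))
        assert name == "SBS1" and not tie

    def test_dominant_tie_numeric_aware(self):
        """SBS2 vs SBS13 tie resolves to the lower signature number."""
        name, tie = dominant_signature(self._exposure({"SBS2": 0.5, "SBS13": 0.5}))
        assert name == "SBS2" and tie

    def test_dominant_single(self):
        name, tie = dominant_signature(self._exposure({"SBS40": 1.0}))
        assert name == "SBS40" and not tie

    def test_dominant_all_zero_rejected(self):
        with pytest.raises(UndefinedResultError):
            dominant_signature(self._exposure({"SBS1": 0.0}))

    def test_attribution_single_active_signature(self, sigs):
        exp = self._exposure({"SBS2": 1.0})
        probs, label, tie = attribute_mutation_signature(50, exp, sigs)
        assert probs == {"SBS2": 1.0} and label == "SBS2" and not tie

    def test_attribution_zero_channel_goes_to_other(self, sigs):
        """With equal weights, a channel impossible under one signature is
        attributed wholly to the other."""
        mat = np.zeros((96, 2))
        mat[0, 0] = 1.0  # S_a concentrated on channel 0
        mat[1, 1] = 1.0  # S_b on channel 1
        ss = SignatureSet(["S_a", "S_b"], mat)
        exp = self._exposure({"S_a": 0.5, "S_b": 0.5})
        probs, label, _ = attribute_mutation_signature(0, exp, ss)
        assert probs["S_a"] == pytest.approx(1.0) and label == "S_a"

    def test_attribution_weighted_tie(self):
        """weights (0.75, 0.25) x channel probs (0.01, 0.03) -> 50/50 tie."""
        mat = np.zeros((96, 2))
        mat[5, 0], mat[5, 1] = 0.01, 0.03
        mat[6, 0], mat[6, 1] = 0.99, 0.97
        ss = SignatureSet(["S_a", "S_b"], mat)
        exp = self._exposure({"S_a": 0.75, "S_b": 0.25})
        probs, label, tie = attribute_mutation_signature(5, exp, ss)
        assert probs["S_a"] == pytest.approx(0.5)
        assert probs["S_b"] == pytest.approx(0.5)
        assert tie

    def test_attribution_unattributable_channel(self, sigs):
        mat = np.zeros((96, 1))
        mat[0, 0] = 1.0
        ss = SignatureSet(["S_a"], mat)
        exp = self._exposure({"S_a": 1.0})
        with pytest.raises(UnattributableError):
            attribute_mutation_signature(3, exp, ss)


class TestClonalSubclonalDiff:
    def _patient(self, reference, sigs, clonal_weights, subclonal_weights, rng, n=400):
        """Context calls with clonality labels drawn from two mixtures."""
        from apobectools.simulate import SimSpec, simulate_catalog

        calls = []
        for clon, weights in (("clonal", clonal_weights), ("subclonal", subclonal_weights)):
            spec = SimSpec(
                genome_length=reference.length("chr1"),
                n_mutations=n,
                signature_weights=weights,
                clonal_fraction=1.0 if clon == "clonal" else 0.0,
            )
            sim = simulate_catalog(reference, spec, sigs, rng=rng)
            ctx, _ = classify_variants(reference, sim.variants)
            calls.extend(ctx)
        return calls

    def test_subclonal_apobec_gives_negative_diffs_and_exact_p(self, ref50k, sigs):
        """8 patients, APOBEC only subclonal: all diffs negative, one-sided
        signed-rank p = 1/256."""
        rng = np.random.default_rng(53)
        patients = {
            f"P{i}": self._patient(
                ref50k, sigs,
                clonal_weights={"SBS5": 1.0},
                subclonal_weights={"SBS2": 0.3, "SBS13": 0.1, "SBS5": 0.6},
                rng=rng,
            )
            for i in range(8)
        }
        res = clonal_subclonal_apobec_diff(patients, sigs, sidedness="less")
        assert all(d < 0 for d in res["diffs"].values())
        assert res["test"].p_exact == Fraction(1, 256)

    def test_identical_catalogs_give_zero_diff(self, ref50k, sigs):
        from apobectools.simulate import SimSpec, simulate_catalog

        spec = SimSpec(genome_length=50_000, n_mutations=300,
                       signature_weights={"SBS2": 0.5, "SBS5": 0.5})
        sim = simulate_catalog(ref50k, spec, sigs, rng=np.random.default_rng(3))
        ctx, _ = classify_variants(ref50k, sim.variants)
        # duplicate every mutation into both clonality classes
        calls = [c for c in ctx]
        both = []
        for c in calls:
            both.append(c.__class__(**{**c.__dict__, "variant": c.variant.with_(clonality="clonal")}))
            both.append(c.__class__(**{**c.__dict__, "variant": c.variant.with_(clonality="subclonal")}))
        res = clonal_subclonal_apobec_diff({"P1": both}, sigs, sidedness="two")
        assert res["diffs"]["P1"] == pytest.approx(0.0, abs=1e-9)

    def test_small_catalogs_flagged(self, ref50k, sigs):
        ref = ReferenceStore({"chr1": "AATCAATTAA" * 2})
        variants = [Variant(sample_id="s", chrom="chr1", pos=4, ref="C", alt="T",
                            clonality="clonal")]
        ctx, _ = classify_variants(ref, variants)
        res = clonal_subclonal_apobec_diff({"P1": ctx}, sigs)
        assert res["flagged"] == ["P1"]
        assert res["test"] is None
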