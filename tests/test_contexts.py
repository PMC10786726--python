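"""Context classification against an independent double-strand scanner."""

import numpy as np
import pytest

from apobectools.channels import revcomp
from apobectools.contexts import (
    apobec_fractions,
    classify_variants,
    count_apobec_mutations,
    extract_context,
)
from apobectools.errors import (
    NoContext,
    NotAnSNV,
    UndefinedResultError,
    ValidationError,
)
from apobectools.reference import ReferenceStore
from apobectools.variants import Variant


def _var(pos, ref, alt, chrom="chr1", **kw):
    return Variant(sample_id="s", chrom=chrom, pos=pos, ref=ref, alt=alt, **kw)


def naive_flags(seq: str, pos: int, ref: str, alt: str) -> dict:
    """Brute-force oracle: enumerate both strands explicitly and test the
    context strings with literal IUPAC sets."""
    W, R, Y = set("AT"), set("AG"), set("CT")
    i = pos - 1
    for strand_seq, strand_ref, strand_alt, idx in (
        (seq, ref, alt, i),
        (revcomp(seq), revcomp(ref), revcomp(alt), len(seq) - 1 - i),
    ):
        if strand_ref not in "CT":
            continue
        tri = strand_seq[idx - 1 : idx + 2]
        penta = strand_seq[idx - 2 : idx + 3] if 2 <= idx <= len(seq) - 3 else None
        ctg = strand_ref == "C" and strand_alt in "TG"
        tcn = ctg and tri[0] == "T"
        tcw = tcn and tri[2] in W
        rtcw = tcw and penta is not None and penta[0] in R
        ytcw = tcw and penta is not None and penta[0] in Y
        return {"tcn": tcn, "tcw": tcw, "rtcw": rtcw, "ytcw": ytcw}
    raise AssertionError("no pyrimidine strand found")


class TestExtractContext:
    def test_deaminase_substrate_site(self):
        """C>T at the center of TTCAA: the TCA context with a 5' pyrimidine."""
        ref = ReferenceStore({"chr1": "TTCAA"})
        call = extract_context(ref, _var(3, "C", "T"))
        assert call.trinucleotide == "TCA"
        assert call.pentanucleotide == "TTCAA"
        assert call.is_tcn and call.is_tcw and call.is_ytcw
        assert not call.is_rtcw
        assert not call.strand_flipped

    def test_purine_strand_collapsed(self):
        """G>A at center of ATGAA reverse-complements to C>T in TTCAT."""
        ref = ReferenceStore({"chr1": "ATGAA"})
        call = extract_context(ref, _var(3, "G", "A"))
        assert call.strand_flipped
        assert call.trinucleotide == "TCA"
        assert call.pentanucleotide == "TTCAT"
        assert (call.ref_pyrimidine, call.alt_pyrimidine) == ("C", "T")
        assert call.is_tcw and call.is_ytcw

    def test_c_to_a_has_no_apobec_flags(self):
        ref = ReferenceStore({"chr1": "TTCAA"})
        call = extract_context(ref, _var(3, "C", "A"))
        assert not call.is_c_to_t_or_g
        assert not (call.is_tcn or call.is_tcw or call.is_rtcw or call.is_ytcw)

    def test_lowercase_reference_normalized(self):
        up = extract_context(ReferenceStore({"c": "TTCAA"}), _var(3, "C", "T", chrom="c"))
        lo = extract_context(ReferenceStore({"c": "ttcaa"}), _var(3, "C", "T", chrom="c"))
        assert up.trinucleotide == lo.trinucleotide and up.is_ytcw == lo.is_ytcw

    def test_non_snv_skipped(self):
        ref = ReferenceStore({"chr1": "TTCAA"})
        with pytest.raises(NotAnSNV):
            extract_context(ref, _var(3, "CA", "C"))

    def test_n_in_window_is_no_context(self):
        ref = ReferenceStore({"chr1": "TNCAA"})
        with pytest.raises(NoContext):
            extract_context(ref, _var(3, "C", "T"))

    def test_edge_position_is_no_context(self):
        ref = ReferenceStore({"chr1": "CTTCAA"})
        with pytest.raises(NoContext):
            extract_context(ref, _var(1, "C", "T"))

    def test_reference_mismatch_rejected(self):
        ref = ReferenceStore({"chr1": "TTCAA"})
        with pytest.raises(ValidationError):
            extract_context(ref, _var(3, "A", "T"))

    def test_trinucleotide_only_when_pentamer_flank_missing(self):
        # position 2 of a 6-mer: 3-mer exists, 5-mer does not
        ref = ReferenceStore({"chr1": "TCAAAA"})
        call = extract_context(ref, _var(2, "C", "T"))
        assert call.trinucleotide == "TCA"
        assert call.pentanucleotide is None
        assert call.is_tcw and not call.is_rtcw and not call.is_ytcw


class TestOracleEquivalence:
    def test_flags_agree_with_naive_scanner(self, ref5k):
        """Random SNVs: flags match the independent double-strand scanner and
        RTCW + YTCW partitions TCW."""
        seq = ref5k.sequence("chr1")
        rng = np.random.default_rng(23)
        positions = rng.choice(np.arange(3, len(seq) - 2), size=400, replace=False)
        n_tcw = n_rtcw = n_ytcw = 0
        for pos in positions:
            ref_base = seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref_base])
            call = extract_context(ref5k, _var(int(pos), ref_base, str(alt)))
            oracle = naive_flags(seq, int(pos), ref_base, str(alt))
            assert (call.is_tcn, call.is_tcw, call.is_rtcw, call.is_ytcw) == (
                oracle["tcn"], oracle["tcw"], oracle["rtcw"], oracle["ytcw"]
            ), f"disagreement at {pos} {ref_base}>{alt}"
            n_tcw += call.is_tcw
            n_rtcw += call.is_rtcw
            n_ytcw += call.is_ytcw
        assert n_rtcw + n_ytcw == n_tcw

    def test_strand_invariance(self, ref5k):
        """Classifying on the reverse-complement genome with mirrored
        coordinates and complemented alleles yields identical flags."""
        seq = ref5k.sequence("chr1")
        flipped = ReferenceStore({"chr1": revcomp(seq)})
        rng = np.random.default_rng(29)
        for pos in rng.choice(np.arange(3, len(seq) - 2), size=100, replace=False):
            pos = int(pos)
            ref_base = seq[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            a = extract_context(ref5k, _var(pos, ref_base, alt))
            mirror_pos = len(seq) - pos + 1
            b = extract_context(
                flipped, _var(mirror_pos, revcomp(ref_base), revcomp(alt))
            )
            assert a.trinucleotide == b.trinucleotide
            assert (a.is_tcn, a.is_tcw, a.is_rtcw, a.is_ytcw) == (
                b.is_tcn, b.is_tcw, b.is_rtcw, b.is_ytcw
            )


class TestSampleStatistics:
    def _calls(self, ref, spec):
        """Build calls from (pos, ref, alt, clonality) tuples."""
        variants = [_var(p, r, a, clonality=c) for p, r, a, c in spec]
        calls, qc = classify_variants(ref, variants)
        return calls, qc

    def test_hand_counted_fractions(self):
        # genome with known contexts: AT[C]AA TCW sites and GG[C]GG non-TCW
        seq = "AATCAATTCTTAGCGGATTCAAGGCGGAAGTCTAAGGCCGGAA"
        ref = ReferenceStore({"chr1": seq})
        # 10 classified mutations, 4 TCW C>T/G (3 with 5' purine, 1 pyrimidine)
        spec = [
            (4, "C", "T", "clonal"),    # ATCAA  -> TCA, 5' A (R)
            (32, "C", "G", "clonal"),   # GTCTA  -> TCT, 5' G (R)
            (9, "C", "T", "clonal"),    # TTCTT  -> TCT, 5' T (Y)
            (39, "C", "T", "clonal"),   # GCCGG  -> CCG non-TCW
            (14, "C", "T", "subclonal"),  # AGCGG -> GCG non-TCN
            (25, "C", "G", "subclonal"),  # GGCGG -> GCG non-TCN
            (20, "C", "A", "subclonal"),  # C>A: no APOBEC class
            (12, "A", "T", "subclonal"),
            (17, "A", "C", "subclonal"),
            (36, "G", "T", "subclonal"),  # AGG center G -> C>A class
        ]
        # one extra TCW hit to make 4: position 20 TTCAA C>G
        spec[6] = (20, "C", "G", "subclonal")
        calls, qc = self._calls(ref, spec)
        assert qc.n_classified == 10
        frac = apobec_fractions(calls)
        assert frac["frac_tcw"] == pytest.approx(0.4)
        assert frac["frac_rtcw"] == pytest.approx(0.2)
        assert frac["frac_ytcw"] == pytest.approx(0.2)
        assert frac["frac_rtcw"] + frac["frac_ytcw"] == pytest.approx(frac["frac_tcw"])

    def test_no_ctg_mutations_gives_zero_fractions(self):
        ref = ReferenceStore({"chr1": "AATCAATT"})
        calls, _ = self._calls(ref, [(4, "C", "A", "clonal"), (3, "T", "A", "clonal")])
        assert all(v == 0 for v in apobec_fractions(calls).values())

    def test_empty_sample_undefined(self):
        with pytest.raises(UndefinedResultError):
            apobec_fractions([])

    def test_stratified_counts_sum_to_total(self, ref5k):
        seq = ref5k.sequence("chr1")
        rng = np.random.default_rng(31)
        spec = []
        for pos in rng.choice(np.arange(3, len(seq) - 2), size=60, replace=False):
            pos = int(pos)
            ref_base = seq[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            clon = "clonal" if rng.random() < 0.5 else "subclonal"
            spec.append((pos, ref_base, alt, clon))
        calls, _ = self._calls(ref5k, spec)
        counts = count_apobec_mutations(calls, stratify_by_clonality=True)
        assert (
            counts["clonal_apobec"] + counts["subclonal_apobec"]
            == counts["apobec_total"]
        )
        assert (
            counts["clonal_apobec"] + counts["clonal_non_apobec"]
            + counts["subclonal_apobec"] + counts["subclonal_non_apobec"]
            == counts["total"]
        )

    def test_stratify_requires_labels(self):
        ref = ReferenceStore({"chr1": "AATCAATT"})
        calls, _ = self._calls(ref, [(4, "C", "T", "unknown")])
        with pytest.raises(ValidationError):
            count_apobec_mutations(calls, stratify_by_clonality=True)

    def test_empty_input_count_is_zero(self):
        assert count_apobec_mutations([])["apobec_total"] == 0
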