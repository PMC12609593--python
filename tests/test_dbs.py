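import numpy as np
import pytest

from rdnacn import CallOptions, call_read, call_read_pair, call_reads, profile_sample
from rdnacn.dbs import (ReadCall, align_to_amplicon, conversion_rate,
                        cpg_states_from_consensus, call_allele, methylation_bin,
                        read_methylation, _consensus_from_alignments)
from rdnacn._util import encode_seq, reverse_complement
from rdnacn.model import _fastq_pairs


def _converted(ref, methylated=False, allele=None):
    """Reference sequence after complete bisulfite conversion."""
    seq = list(ref.sequence)
    cpg = set(ref.cpg_positions)
    for i, b in enumerate(seq):
        if b == "C" and (i not in cpg or not methylated):
            seq[i] = "T"
    if allele:
        seq[ref.variant_offset] = allele
    return "".join(seq)


class TestAlignment:
    def test_fully_converted_read_aligns_perfectly(self, ref):
        aln = align_to_amplicon(_converted(ref), ref)
        assert aln is not None
        assert aln.offset == 0 and not aln.reverse
        assert aln.identity == 1.0
        cons = _consensus_from_alignments([aln], ref.length)
        states = cpg_states_from_consensus(cons, ref)
        assert states == ("U",) * 25

    def test_unconverted_read_fully_methylated(self, ref):
        aln = align_to_amplicon(ref.sequence, ref)
        cons = _consensus_from_alignments([aln], ref.length)
        assert cpg_states_from_consensus(cons, ref) == ("M",) * 25
        assert conversion_rate(cons, ref) == 0.0

    def test_reverse_complement_read_maps(self, ref):
        seq = reverse_complement(_converted(ref))
        aln = align_to_amplicon(seq, ref)
        assert aln is not None and aln.reverse

    def test_internal_fragment_gets_correct_offset(self, ref):
        frag = _converted(ref)[60:180]
        aln = align_to_amplicon(frag, ref)
        assert aln.offset == 60

    def test_random_sequence_unmapped(self, ref):
        rng = np.random.default_rng(5)
        junk = "".join(rng.choice(list("ACGT"), size=150))
        assert align_to_amplicon(junk, ref) is None

    def test_short_read_rejected(self, ref):
        assert align_to_amplicon("ACGT" * 10, ref, min_length=50) is None


class TestConversionRate:
    def make_consensus(self, ref, n_unconverted):
        """Consensus with the first n non-CpG Cs left unconverted."""
        seq = list(_converted(ref))
        for p in ref.non_cpg_c_positions[:n_unconverted]:
            seq[p] = "C"
        return encode_seq("".join(seq))

    def test_full_conversion(self, ref):
        assert conversion_rate(self.make_consensus(ref, 0), ref) == 1.0

    def test_exact_boundary_fails_strict_filter(self, ref):
        # a read at exactly 38/40 = 0.95 must FAIL the strict > 0.95 rule
        seq = list(_converted(ref))
        positions = ref.non_cpg_c_positions
        for p in positions[40:]:
            seq[p] = "N"  # uninformative: excluded from both counts
        for p in positions[:2]:
            seq[p] = "C"  # unconverted
        cons = encode_seq("".join(seq))
        rate = conversion_rate(cons, ref)
        assert rate == pytest.approx(38 / 40)
        from rdnacn.dbs import _finalize_call
        call = _finalize_call("b", cons, ref, CallOptions())
        assert not call.pass_filters
        assert "low_conversion" in call.reasons
        # one fewer unconverted C (39/40 = 0.975) passes
        seq[positions[1]] = "T"
        call2 = _finalize_call("b2", encode_seq("".join(seq)), ref, CallOptions())
        assert call2.conversion_rate == pytest.approx(39 / 40)
        assert "low_conversion" not in call2.reasons

    def test_arithmetic(self, ref):
        cons = self.make_consensus(ref, 1)
        n_c = len(ref.non_cpg_c_positions)
        assert conversion_rate(cons, ref) == pytest.approx((n_c - 1) / n_c)

    def test_insufficient_coverage_returns_none(self, ref):
        cons = np.zeros(ref.length, dtype=np.uint8)  # nothing covered
        assert conversion_rate(cons, ref) is None


class TestAlleleCall:
    @pytest.mark.parametrize("base,expected", [("G", "G"), ("A", "A"), ("N", "ambiguous")])
    def test_allele_calls(self, ref, base, expected):
        cons = encode_seq(_converted(ref, allele=base))
        assert call_allele(cons, ref) == expected


class TestReadMethylation:
    @pytest.mark.parametrize("n_meth,pct,bin_idx,active", [
        (2, 8.0, 0, True),    # <= 10%: presumably active
        (3, 12.0, 1, False),  # > 10%: not active
        (25, 100.0, 9, False),
        (0, 0.0, 0, True),
    ])
    def test_binning(self, n_meth, pct, bin_idx, active):
        states = ("M",) * n_meth + ("U",) * (25 - n_meth)
        got_pct, got_bin = read_methylation(states)
        assert got_pct == pytest.approx(pct)
        assert got_bin == bin_idx
        assert (got_pct <= 10) == active

    def test_bin_edges_half_open(self):
        assert methylation_bin(10.0) == 0
        assert methylation_bin(10.0001) == 1
        assert methylation_bin(20.0) == 1
        assert methylation_bin(100.0) == 9

    def test_too_few_cpgs_rejected(self):
        states = ("M",) * 5 + (".",) * 20
        with pytest.raises(ValueError, match="analyzable"):
            read_methylation(states, min_cpgs=20)


class TestPairMerging:
    def test_pair_covers_whole_amplicon(self, ref):
        full = _converted(ref)
        m1, m2 = full[:150], reverse_complement(full[-150:])
        call = call_read_pair("p1", m1, m2, ref)
        assert call.pass_filters
        assert call.n_analyzable == 25

    def test_mate_conflict_becomes_ambiguous(self, ref):
        full = _converted(ref)
        m1 = full[:150]
        # corrupt one overlapping non-C position in mate 2
        tail = list(full[-150:])
        overlap_pos = 150 - (ref.length - 150) - 1  # inside the mate overlap
        idx = None
        for j in range(len(tail)):
            ref_pos = ref.length - 150 + j
            if ref_pos < 150 and ref.sequence[ref_pos] not in "C" and ref_pos not in ref.cpg_positions:
                idx = j
                break
        assert idx is not None
        tail[idx] = "A" if tail[idx] != "A" else "G"
        m2 = reverse_complement("".join(tail))
        call = call_read_pair("p1", m1, m2, ref)
        ref_pos = ref.length - 150 + idx
        from rdnacn.dbs import align_to_amplicon as _a
        # conflicting column must not be trusted: consensus has N there
        aln1 = _a(m1, ref)
        aln2 = _a(m2, ref)
        cons = _consensus_from_alignments([aln1, aln2], ref.length)
        assert cons[ref_pos] == ord("N")


class TestProfile:
    def _call(self, n_meth, rid="r"):
        states = ("M",) * n_meth + ("U",) * (25 - n_meth)
        return ReadCall(rid, "G", 1.0, states, True)

    def test_all_unmethylated(self):
        calls = [self._call(0, f"r{i}") for i in range(10)]
        prof = profile_sample(calls, "s")
        assert prof.mean_methylation_pct == 0.0
        assert prof.hypomethylated_fraction == 1.0

    def test_hand_computed_mixture(self):
        # 4 reads at 0%, 4 at 8% (2/25), 2 at 60% (15/25):
        # hypo fraction 0.8; pooled mean = (0*4 + 2*4 + 15*2)/250 = 15.2%
        calls = ([self._call(0, f"a{i}") for i in range(4)]
                 + [self._call(2, f"b{i}") for i in range(4)]
                 + [self._call(15, f"c{i}") for i in range(2)])
        prof = profile_sample(calls, "s")
        assert prof.hypomethylated_fraction == pytest.approx(0.8)
        assert prof.mean_methylation_pct == pytest.approx(15.2)

    def test_read_count_conservation(self, clean_reads, ref):
        pairs = _fastq_pairs(clean_reads.fastq_r1, clean_reads.fastq_r2)
        calls = call_reads(pairs, ref)
        prof = profile_sample(calls, "s")
        assert prof.n_reads_total == len(pairs)
        assert prof.n_reads_retained + sum(prof.rejection_reasons.values()) == prof.n_reads_total

    def test_zero_retained_flags_no_data(self):
        call = ReadCall("r", "A", 1.0, ("U",) * 25, False, ("minor_allele",))
        prof = profile_sample([call], "s")
        assert prof.no_data
        assert np.isnan(prof.mean_methylation_pct)

    def test_truth_sidecar_equivalence_zero_error(self, clean_reads, ref):
        pairs = _fastq_pairs(clean_reads.fastq_r1, clean_reads.fastq_r2)
        calls = call_reads(pairs, ref)
        prof = profile_sample(calls, "s")
        truth = clean_reads.truth
        major = truth[truth.allele == "G"]
        assert prof.n_reads_retained == len(major)
        expected_bins = np.bincount(major["bin"], minlength=10) / len(major)
        np.testing.assert_allclose(prof.bin_fractions, expected_bins, atol=0)

    def test_filter_monotonicity_in_conversion_threshold(self, donor, ref):
        from rdnacn.synth import simulate_reads

        sim = simulate_reads(donor, ref, n_reads=150, conversion_failure_rate=0.04,
                             seq_error_rate=0.0, minor_allele_fraction=0.0, seed=3)
        pairs = _fastq_pairs(sim.fastq_r1, sim.fastq_r2)
        retained = []
        for thr in (0.90, 0.95, 0.99):
            calls = call_reads(pairs, ref, CallOptions(min_conversion=thr))
            retained.append(profile_sample(calls, "s").n_reads_retained)
        assert retained[0] >= retained[1] >= retained[2]

    def test_bin_fractions_sum_to_one(self, clean_reads, ref):
        pairs = _fastq_pairs(clean_reads.fastq_r1, clean_reads.fastq_r2)
        prof = profile_sample(call_reads(pairs, ref), "s")
        assert prof.bin_fractions.sum() == pytest.approx(1.0, abs=1e-9)
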