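"""Spaced-seed index, scanning, alignment, clustering and the repeat gate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pseudosanger as P
from pseudosanger.overlap import OverlapParams, batch_gapless, _scan_one_strand
from pseudosanger.seqs import decode, encode, revcomp

from conftest import truth_fragment

DNA = st.text(alphabet="ACGT", min_size=1, max_size=30)


class TestSpacedSeedIndex:
    def test_contiguous_pattern_indexes_every_position(self):
        idx = P.build_spaced_index(["ACGTACGT"], pattern="1111", step=1)
        assert len(idx) == 5  # 8 - 4 + 1

    def test_empty_read_set(self):
        idx = P.build_spaced_index([])
        rows, offs = idx.lookup(0)
        assert rows.size == 0

    def test_mask_application(self):
        # pattern 11011 on AACGT keeps positions {0,1,3,4} = AAGT
        idx = P.build_spaced_index(["AACGT"], pattern="11011", step=1)
        from pseudosanger.overlap import extract_keys
        key = extract_keys(encode("AACGT"), np.array([0]), idx.care)[0, 0]
        expect = extract_keys(encode("AAGT"), np.array([0]),
                              np.arange(4))[0, 0]
        assert key == expect
        rows, offs = idx.lookup(int(key))
        assert list(rows) == [0] and list(offs) == [0]

    def test_n_positions_never_indexed(self):
        idx = P.build_spaced_index(["ACGNACGT"], pattern="1111", step=1)
        assert len(idx) == 1  # only the final ACGT window lacks an N

    def test_short_reads_skipped_not_fatal(self):
        idx = P.build_spaced_index(["ACG"], pattern="1111", step=1)
        assert len(idx) == 0 and idx.n_skipped_short == 1

    @pytest.mark.parametrize("pattern", ["", "0110", "10", "12"])
    def test_bad_patterns_rejected(self, pattern):
        with pytest.raises(ValueError):
            P.build_spaced_index(["ACGT"], pattern=pattern)

    def test_stride_skips_positions(self):
        idx = P.build_spaced_index(["ACGTACGTAC"], pattern="1111", step=2)
        assert len(idx) == 4  # positions 0, 2, 4, 6


class TestScanAnchor:
    def test_identical_read_found_on_diagonal_zero(self):
        reads = ["ACGTACGGTTACGATCAGGACTGACGGTATTGACCAGT"]
        idx = P.build_spaced_index(reads, pattern="1" * 16, step=1)
        rows, strands, diags = P.scan_anchor(encode(reads[0]), idx)
        fwd = (strands == "+")
        assert 0 in diags[fwd][rows[fwd] == 0]

    def test_all_n_anchor_yields_nothing(self, sr_index):
        rows, strands, diags = P.scan_anchor(encode("N" * 100), sr_index)
        assert rows.size == 0

    def test_shared_block_found_at_correct_diagonal(self):
        rng = np.random.default_rng(42)
        sr = decode(rng.integers(0, 4, 80).astype(np.uint8))
        ar = decode(rng.integers(0, 4, 80).astype(np.uint8))
        # plant sr[20:52] at ar position 40 => diagonal 40 - 20 = 20
        ar = ar[:40] + sr[20:52] + ar[72:]
        idx = P.build_spaced_index([sr], pattern="1" * 12 + "0" * 4 +
                                   "1" * 12, step=1)
        rows, strands, diags = P.scan_anchor(encode(ar), idx)
        fwd = strands == "+"
        assert 20 in diags[fwd]


class TestGaplessExtend:
    def test_identical_reads_full_overlap(self):
        r = encode("ACGT" * 25)
        hit = P.gapless_extend(r, r, 0)
        assert hit.overlap_len == 100 and hit.mismatches == 0

    def test_two_substitutions_counted(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 4, 100).astype(np.uint8)
        b = a[50:].copy()
        b[10] = (b[10] + 1) % 4
        b[20] = (b[20] + 2) % 4
        b = np.concatenate([b, rng.integers(0, 4, 50).astype(np.uint8)])
        hit = P.gapless_extend(a, b, 50)
        assert hit is not None
        assert hit.overlap_len == 50 and hit.mismatches == 2

    def test_excessive_mismatches_fail(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 4, 100).astype(np.uint8)
        b = a[50:].copy()
        b[:10] = (b[:10] + 1) % 4  # 10 mismatches in a 50 bp overlap
        b = np.concatenate([b, rng.integers(0, 4, 50).astype(np.uint8)])
        assert P.gapless_extend(a, b, 50) is None  # 10/50 > 8%

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_mismatches_equal_hamming_distance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, 60).astype(np.uint8)
        b = rng.integers(0, 4, 60).astype(np.uint8)
        d = int(rng.integers(-30, 31))
        ov, mism = batch_gapless(a, b[None, :], np.zeros(1, np.int64),
                                 np.array([d]))
        lo, hi = max(0, d), min(60, d + 60)
        expect = int((a[lo:hi] != b[lo - d:hi - d]).sum())
        assert mism[0] == expect and ov[0] == hi - lo


def brute_force_sw(a: str, b: str, match=1, mismatch=-2, gap_open=-3,
                   gap_extend=-1):
    """Plain-list affine local alignment, O(n*m) cells, for cross-checking."""
    n, m = len(a), len(b)
    NEG = -10**9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestSmithWaterman:
    def test_identity_alignment(self):
        aln = P.sw_align(encode("ACGT"), encode("ACGT"))
        assert aln.score == 4
        assert (aln.a_start, aln.a_end, aln.b_start, aln.b_end) == (0, 4, 0, 4)
        assert aln.cigar == [("M", 4)]

    def test_small_indel_case_matches_oracle(self):
        a, b = "ACGTTT", "ACGATTT"
        aln = P.sw_align(encode(a), encode(b))
        assert aln.score == brute_force_sw(a, b) == 3

    def test_gapped_alignment_beats_ungapped(self):
        # single-base insertion; the gapped alignment is strictly optimal
        a, b = "ACGTACGTAAACCC", "ACGTACGTGAAACCC"
        aln = P.sw_align(encode(a), encode(b))
        assert aln.score == brute_force_sw(a, b) == 11
        assert any(op in ("I", "D") for op, _ in aln.cigar)

    def test_disjoint_alphabets_give_no_alignment(self):
        assert P.sw_align(encode("AAAA"), encode("TTTT")) is None

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            P.sw_align(encode(""), encode("ACGT"))

    @given(DNA, DNA)
    @settings(max_examples=150, deadline=None)
    def test_score_equals_brute_force(self, a, b):
        aln = P.sw_align(encode(a), encode(b))
        expect = brute_force_sw(a, b)
        got = aln.score if aln is not None else 0
        assert got == expect

    @given(DNA, DNA)
    @settings(max_examples=60, deadline=None)
    def test_score_matches_biopython(self, a, b):
        from Bio import Align
        aligner = Align.PairwiseAligner(mode="local", match_score=1,
                                        mismatch_score=-2,
                                        open_gap_score=-3,
                                        extend_gap_score=-1)
        aln = P.sw_align(encode(a), encode(b))
        got = aln.score if aln is not None else 0
        assert got == max(aligner.score(a, b), 0)

    def test_cigar_consistent_with_intervals(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 4, 50).astype(np.uint8)
        b = np.concatenate([a[10:30], a[33:45]])
        aln = P.sw_align(a, b)
        ac = sum(n for op, n in aln.cigar if op in ("M", "I"))
        bc = sum(n for op, n in aln.cigar if op in ("M", "D"))
        assert ac == aln.a_end - aln.a_start
        assert bc == aln.b_end - aln.b_start


class TestExpectedCountAndRepeatGate:
    def test_formula_value(self):
        assert P.expected_sr_count(100, 30, 45) == pytest.approx(63.45)

    def test_boundary_overlap_equals_read_length(self):
        assert P.expected_sr_count(100, 100, 45) == pytest.approx(0.45)

    def test_linear_in_depth(self):
        assert P.expected_sr_count(100, 30, 90) == \
            pytest.approx(2 * P.expected_sr_count(100, 30, 45))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            P.expected_sr_count(100, 0, 45)
        with pytest.raises(ValueError):
            P.expected_sr_count(100, 120, 45)
        with pytest.raises(ValueError):
            P.expected_sr_count(100, 30, 0)

    def test_monte_carlo_confirms_expectation(self):
        # uniform read starts at depth D: count starts within +-(L-O) of an
        # anchor start, averaged over many trials
        L, O, D, G = 100, 30, 45, 10_000
        rng = np.random.default_rng(99)
        trials = 120
        counts = []
        n_reads = int(G * D / L)
        window = L - O
        for _ in range(trials):
            starts = rng.integers(0, G, n_reads)
            anchors = rng.integers(window, G - window, 1000)
            starts.sort()
            lo = np.searchsorted(starts, anchors - window)
            hi = np.searchsorted(starts, anchors + window + 1)
            counts.append(hi - lo)
        mean = np.concatenate(counts).mean()
        assert abs(mean - P.expected_sr_count(L, O, D)) / mean < 0.01

    def test_threshold_is_strict(self):
        assert P.is_repetitive(100, 63.45, 1.5)       # 100 > 95.175
        assert not P.is_repetitive(95, 63.45, 1.5)
        assert not P.is_repetitive(0, 63.45, 1.5)

    def test_exactly_expected_count_passes(self):
        assert not P.is_repetitive(60, 40.0, 1.5)  # 60 == 1.5 * 40


class TestClustering:
    def test_admission_of_truly_overlapping_pairs(self, small_ref,
                                                  nested_libraries, sr_pool,
                                                  sr_index):
        """>= 99% of SR pairs whose fragment lies within the AR span and
        whose left/right-end read overlaps an anchor read by >= O on the
        matching strand are admitted."""
        params = OverlapParams()
        ar = nested_libraries[0]
        O = params.min_overlap
        admitted = 0
        expected = 0
        for i in range(100):
            t = ar.truth[i]
            cl = P.cluster_for_anchor(ar.reads1[i], ar.reads2[i], sr_pool,
                                      sr_index, params,
                                      ar.spec.insert_range(3.0),
                                      ar.pair_ids[i])
            got = {m.pair_row for m in cl.members}
            a0, a1 = t.fragment_start, t.fragment_end
            for pr in range(sr_pool.n_pairs):
                li = sr_pool.pair_lib[pr]
                wi = sr_pool.pair_within[pr]
                tt = nested_libraries[li].truth[wi]
                if tt.haplotype != t.haplotype:
                    continue  # keep the oracle exact: same-haplotype only
                s, e = tt.fragment_start, tt.fragment_end
                if not (s >= a0 and e <= a1):
                    continue
                left_ov = min(s + 100, a0 + 100) - max(s, a0)
                right_ov = min(e, a1) - max(e - 100, a1 - 100)
                if max(left_ov, right_ov) < O:
                    continue
                expected += 1
                admitted += pr in got
        assert expected > 200
        assert admitted / expected >= 0.99

    def test_reverse_overlaps_excluded(self):
        """A read overlapping an anchor only in reverse orientation is never
        admitted (its partner points away from the gap)."""
        rng = np.random.default_rng(8)
        genome = rng.integers(0, 4, 800).astype(np.uint8)
        ar1, ar2 = genome[:100], revcomp(genome[500:600])
        # SR pair whose right-end read covers the anchor-read1 locus: stored
        # reverse-complemented, so it only matches read1 on the '-' strand
        sr_right_end = revcomp(genome[20:120])
        sr_left_end = genome[:0]
        lib = P.PairedLibrary(
            spec=P.LibrarySpec(insert_mean=300, depth=1),
            reads1=rng.integers(0, 4, (1, 100)).astype(np.uint8),
            reads2=sr_right_end[None, :],
            pair_ids=["p:0"])
        pool = P.SRPool([lib], [1])
        idx = P.SpacedSeedIndex(pool.reads, step=1)
        cl = P.cluster_for_anchor(ar1, ar2, pool, idx, OverlapParams(),
                                  (400, 800), "ar")
        assert cl.members == []

    def test_empty_cluster_when_no_overlaps(self, sr_pool, sr_index):
        rng = np.random.default_rng(9)
        ar1 = rng.integers(0, 4, 100).astype(np.uint8)
        ar2 = rng.integers(0, 4, 100).astype(np.uint8)
        cl = P.cluster_for_anchor(ar1, ar2, sr_pool, sr_index,
                                  OverlapParams(), (420, 780), "ar")
        assert cl.members == [] and cl.n_anchor_hits == 0

    def test_unique_region_false_flag_rate_below_2pct(self, nested_libraries,
                                                      sr_pool, sr_index):
        params = OverlapParams()
        ar = nested_libraries[0]
        E = P.expected_sr_count(100, params.min_overlap, 45)
        flagged = 0
        n = 150
        for i in range(n):
            cl = P.cluster_for_anchor(ar.reads1[i], ar.reads2[i], sr_pool,
                                      sr_index, params,
                                      ar.spec.insert_range(3.0),
                                      ar.pair_ids[i])
            flagged += P.is_repetitive(cl, E, params.repeat_factor)
        assert flagged / n < 0.02

    def test_clustering_reverse_complement_symmetric(self, small_ref):
        """Mirroring the entire input (genome and reads) yields clusters with
        identical pair membership."""
        spec = P.LibrarySpec(insert_mean=300, depth=30)
        lib = P.generate_library(small_ref, spec, seed=33)
        params = OverlapParams()
        pool = P.SRPool([lib], [1])
        idx = P.SpacedSeedIndex(pool.reads, params.seed_pattern,
                                params.sr_stride)
        # mirrored input: the reverse-complement world swaps pair ends
        # (reads are stored 5'->3' on their own strands already)
        mlib = P.PairedLibrary(spec, lib.reads2, lib.reads1, lib.pair_ids)
        mpool = P.SRPool([mlib], [1])
        midx = P.SpacedSeedIndex(mpool.reads, params.seed_pattern,
                                 params.sr_stride)
        ar_spec = P.LibrarySpec(insert_mean=600, depth=1)
        arlib = P.generate_library(small_ref, ar_spec, seed=34)
        rng_range = ar_spec.insert_range(3.0)
        for i in range(25):
            cl = P.cluster_for_anchor(arlib.reads1[i], arlib.reads2[i],
                                      pool, idx, params, rng_range, "x")
            mcl = P.cluster_for_anchor(arlib.reads2[i], arlib.reads1[i],
                                       mpool, midx, params, rng_range, "x")
            assert {m.pair_row for m in cl.members} == \
                {m.pair_row for m in mcl.members}
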