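import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adaptalign.genome_db import codes_to_seq, reverse_complement, seq_to_codes, unpack_codes
from adaptalign.kmer_index import (
    IndexParams,
    build_index,
    canonical_value,
    is_closed_syncmer,
    msd_radix_sort_with_lcp,
    phi_value,
    syncmer_positions,
)
from adaptalign.kmer_index import _pack_kmer_rows

dna = st.text(alphabet="acgt", min_size=1, max_size=24)


class TestPhi:
    @pytest.mark.parametrize(
        "seq,expected", [("aaaa", 0), ("acgt", 27), ("t", 3), ("ca", 4)]
    )
    def test_positional_base4(self, seq, expected):
        assert phi_value(seq) == expected

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(dna, dna)
    def test_order_isomorphic_to_lexicographic(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        assert (phi_value(x) < phi_value(y)) == (x < y)

    def test_invalid_base(self):
        with pytest.raises(ValueError):
            phi_value("acgn")


class TestCanonical:
    def test_examples(self):
        assert canonical_value("aaaa") == 0
        assert canonical_value("acgt") == phi_value("acgt")  # its own complement
        assert canonical_value("ttgc") == phi_value("gcaa") == 144

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(dna)
    def test_strand_invariant(self, s):
        assert canonical_value(s) == canonical_value(reverse_complement(s))


class TestClosedSyncmer:
    @pytest.mark.parametrize(
        "kmer,s,m,expected",
        [("aaaaa", 5, 3, True), ("caaat", 5, 3, False), ("aaaat", 5, 3, True)],
    )
    def test_examples(self, kmer, s, m, expected):
        assert is_closed_syncmer(kmer, s, m) is expected

    def test_matches_bruteforce_window_minimum(self):
        rng = np.random.default_rng(1)
        s, m = 8, 4
        for _ in range(300):
            km = codes_to_seq(rng.integers(0, 4, s, dtype=np.uint8))
            canon = [canonical_value(km[i : i + m]) for i in range(s - m + 1)]
            expected = min(canon[0], canon[-1]) == min(canon)
            assert is_closed_syncmer(km, s, m) is expected

    def test_complement_closure(self):
        # a k-mer is a closed syncmer iff its reverse complement is
        rng = np.random.default_rng(2)
        s = 12
        for _ in range(200):
            km = codes_to_seq(rng.integers(0, 4, s, dtype=np.uint8))
            assert is_closed_syncmer(km, s, 8) == is_closed_syncmer(reverse_complement(km), s, 8)

    def test_length_violation(self):
        with pytest.raises(ValueError):
            is_closed_syncmer("acg", 5, 3)


class TestSyncmerSampling:
    def test_spacing_bounds_on_random_dna(self):
        # closed (12,8) syncmers on s-mers directly: gaps at most s-m,
        # mean spacing slightly above (s-m)/2
        rng = np.random.default_rng(42)
        codes = rng.integers(0, 4, 1_000_000, dtype=np.uint8)
        pos = syncmer_positions(codes, 12, 8)
        gaps = np.diff(pos)
        assert gaps.max() <= 4
        assert 2.0 < gaps.mean() < 3.0

    def test_retained_fraction(self):
        rng = np.random.default_rng(7)
        codes = rng.integers(0, 4, 1_000_000, dtype=np.uint8)
        pos = syncmer_positions(codes, 12, 8)
        frac = len(pos) / (len(codes) - 11)
        assert 0.35 <= frac <= 0.60


class TestMsdRadixSort:
    def test_order_and_lcp_match_comparison_sort(self):
        rng = np.random.default_rng(0)
        items = rng.integers(0, 256, size=(10_000, 16), dtype=np.uint8)
        got, lcp = msd_radix_sort_with_lcp(items)
        ref = sorted(map(bytes, items))
        assert [bytes(r) for r in got] == ref
        assert lcp[0] == 0
        for i in range(1, len(ref)):
            expected = next(
                (k for k in range(16) if ref[i - 1][k] != ref[i][k]), 16
            )
            assert lcp[i] == expected

    def test_identical_block_moves_nothing(self):
        stats = np.zeros(2, np.int64)
        same = np.tile(np.arange(12, dtype=np.uint8), (64, 1))
        _, lcp = msd_radix_sort_with_lcp(same, stats=stats)
        assert stats[0] == 0  # partition-skip path: no data movement
        assert (lcp[1:] == 12).all()

    def test_ragged_widths_error(self):
        with pytest.raises(ValueError):
            msd_radix_sort_with_lcp([b"ab", b"abc"])

    def test_packed_dna_boundary_lcp_formula(self):
        # base-resolution lcps from the byte-xor boundary rule agree with
        # brute force on the unpacked strings
        rng = np.random.default_rng(3)
        K = 20
        codes = rng.integers(0, 4, 4000, dtype=np.uint8)
        rows = _pack_kmer_rows(codes, np.arange(len(codes) - K + 1, dtype=np.int64), K)
        got, lcp = msd_radix_sort_with_lcp(rows, unit="bases", kbases=K)
        un = [unpack_codes(r, K) for r in got]
        for i in range(1, len(un)):
            b = 0
            while b < K and un[i - 1][b] == un[i][b]:
                b += 1
            assert lcp[i] == b


class TestBuildIndex:
    def test_repetitive_homopolymer_filtered_to_empty(self, gdb_factory):
        gdb = gdb_factory("a" * 1000)
        ix = build_index(gdb, IndexParams(K=40, s=12, m=8, tau=10))
        # the poly-a 40-mer is a closed syncmer but occurs 961 times per
        # strand, far beyond tau
        assert ix.n == 0

    def test_matches_bruteforce_enumeration(self, gdb_factory):
        rng = np.random.default_rng(1)
        P = IndexParams(K=16, s=8, m=4, tau=10)
        seq = codes_to_seq(rng.integers(0, 4, 10_000, dtype=np.uint8))
        gdb = gdb_factory(seq)
        ix = build_index(gdb, P)
        recs = {}
        for strand, sq in ((1, seq), (-1, reverse_complement(seq))):
            for p in range(len(sq) - P.K + 1):
                km = sq[p : p + P.K]
                if is_closed_syncmer(km, P.s, P.m):
                    recs.setdefault(km, []).append((0, p, strand))
        expected = sorted(
            (km,) + loc for km, locs in recs.items() if len(locs) < P.tau for loc in locs
        )
        got = sorted(
            (ix.kmer_string(i), int(ix.contig[i]), int(ix.pos[i]), int(ix.strand[i]))
            for i in range(ix.n)
        )
        assert got == expected
        # lcp array equals brute force on the sorted k-mer strings
        ks = [ix.kmer_string(i) for i in range(ix.n)]
        assert ks == sorted(ks)
        for i in range(1, ix.n):
            b = 0
            while b < P.K and ks[i - 1][b] == ks[i][b]:
                b += 1
            assert ix.lcp[i] == b
        assert ix.lcp[0] == 0

    def test_short_contig_skipped_with_warning(self, gdb_factory):
        gdb = gdb_factory("acgtacgt")
        with pytest.warns(UserWarning, match="shorter than K"):
            ix = build_index(gdb, IndexParams(K=16, s=8, m=4))
        assert ix.n == 0

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            IndexParams(K=10, s=12, m=8)
        with pytest.raises(ValueError):
            IndexParams(tau=0)


def test_gix_roundtrip(gdb_factory, tmp_path):
    from adaptalign.kmer_index import read_gix, write_gix

    rng = np.random.default_rng(5)
    gdb = gdb_factory(codes_to_seq(rng.integers(0, 4, 400, dtype=np.uint8)))
    ix = build_index(gdb, IndexParams(K=16, s=8, m=4, tau=10))
    p = tmp_path / "x.gix"
    write_gix(ix, p)
    back = read_gix(p)
    assert back.params == ix.params
    assert (back.kmers == ix.kmers).all()
    assert (back.contig == ix.contig).all()
    assert (back.pos == ix.pos).all()
    assert (back.strand == ix.strand).all()
    assert (back.lcp == ix.lcp).all()
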