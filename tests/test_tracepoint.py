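import itertools

import edlib
import numpy as np
import pytest

from adaptalign.tracepoint import (
    TracePointOverflow,
    Trapezoid,
    cigar_to_path,
    count_gaps,
    decode_tracepoints,
    encode_tracepoints,
    extract_indel_array,
    find_refinable_segments,
    path_to_cigar,
    refine_path,
    refine_segment,
)
from adaptalign.wavefront import OP_DEL, OP_DIAG, OP_INS, global_path, path_intervals, path_stats
from conftest import mutate_codes


def edit_distance(a, b):
    return edlib.align(
        "".join(map(str, np.asarray(a))), "".join(map(str, np.asarray(b))), task="distance"
    )["editDistance"]


def random_alignment(rng, n=500, edits=40):
    A = rng.integers(0, 4, n, dtype=np.uint8)
    B = mutate_codes(rng, A, edits)
    ops, d = global_path(A, B)
    return A, B, ops, d


class TestEncode:
    def test_ten_kb_gap_free_is_hundred_bytes(self):
        ops = np.zeros(10_000, dtype=np.uint8)
        tpa = encode_tracepoints(ops, 0, 10_000, 0, 10_000, 100)
        assert tpa.panels == 100
        assert (tpa.b == 100).all()
        assert (tpa.b <= 255).all()

    def test_short_first_panel(self):
        # panels cut at multiples of delta; conservation fixes the lengths
        ops = np.zeros(200, dtype=np.uint8)
        tpa = encode_tracepoints(ops, 50, 250, 0, 200, 100)
        assert list(tpa.b) == [50, 100, 50]

    def test_conservation_on_random_alignments(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            A, B, ops, _ = random_alignment(rng)
            tpa = encode_tracepoints(ops, 0, len(A), 0, len(B), 100)
            assert int(tpa.b.sum()) == len(B)

    def test_boundary_insertions_go_left(self):
        # 100 diagonal ops, then an insertion exactly at the panel boundary
        ops = np.array([OP_DIAG] * 100 + [OP_INS] + [OP_DIAG] * 50, dtype=np.uint8)
        tpa = encode_tracepoints(ops, 0, 150, 0, 151, 100)
        assert list(tpa.b) == [101, 50]

    def test_overflow_signals_caller(self):
        ops = np.array([OP_DIAG] * 10 + [OP_INS] * 250 + [OP_DIAG] * 10, dtype=np.uint8)
        with pytest.raises(TracePointOverflow):
            encode_tracepoints(ops, 0, 20, 0, 270, 100)


class TestDecode:
    def test_identity_reconstruction(self):
        rng = np.random.default_rng(1)
        A = rng.integers(0, 4, 1000, dtype=np.uint8)
        ops = np.zeros(1000, dtype=np.uint8)
        tpa = encode_tracepoints(ops, 0, 1000, 0, 1000, 100)
        path, diffs = decode_tracepoints(tpa, 0, 1000, 0, 1000, A, A)
        assert diffs == 0 and (path == OP_DIAG).all()

    def test_per_panel_diffs_are_dp_optimal(self):
        # the reconstruction solves each delta x delta sub-problem optimally:
        # its per-panel diffs equal an independent edit-distance oracle
        from adaptalign.tracepoint import panel_edges

        rng = np.random.default_rng(2)
        A = rng.integers(0, 4, 5000, dtype=np.uint8)
        B = mutate_codes(rng, A, 500)  # ~10% divergence
        ops, d = global_path(A, B)
        tpa = encode_tracepoints(ops, 0, len(A), 0, len(B), 100)
        path, diffs = decode_tracepoints(tpa, 0, len(A), 0, len(B), A, B)
        assert diffs <= d
        na, nb = path_intervals(path)
        assert na == len(A) and nb == len(B)
        edges = panel_edges(0, len(A), 100)
        bedges = np.r_[0, np.cumsum(tpa.b)]
        oracle_total = sum(
            edit_distance(A[edges[p] : edges[p + 1]], B[bedges[p] : bedges[p + 1]])
            for p in range(len(edges) - 1)
        )
        assert diffs == oracle_total

    def test_encode_decode_encode_fixed_point(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            A, B, ops, _ = random_alignment(rng)
            tpa = encode_tracepoints(ops, 0, len(A), 0, len(B), 100)
            path, _ = decode_tracepoints(tpa, 0, len(A), 0, len(B), A, B)
            tpa2 = encode_tracepoints(path, 0, len(A), 0, len(B), 100)
            assert (tpa2.b == tpa.b).all()

    def test_inconsistent_sums_error(self):
        rng = np.random.default_rng(4)
        A = rng.integers(0, 4, 200, dtype=np.uint8)
        tpa = encode_tracepoints(np.zeros(200, dtype=np.uint8), 0, 200, 0, 200, 100)
        with pytest.raises(ValueError):
            decode_tracepoints(tpa, 0, 200, 0, 201, A, A)


class TestIndelArray:
    def test_gap_free_path_empty(self):
        assert len(extract_indel_array(np.zeros(50, dtype=np.uint8))) == 0

    def test_single_insertion_position(self):
        # acg|t vs acg+X+t: dash before A symbol 4 ... here: two diagonal
        # ops, one insertion, one diagonal: dash before A symbol 3
        path = np.array([OP_DIAG, OP_DIAG, OP_INS, OP_DIAG], dtype=np.uint8)
        assert list(extract_indel_array(path)) == [3]

    def test_deletion_uses_b_position(self):
        path = np.array([OP_DIAG, OP_DEL, OP_DEL, OP_DIAG], dtype=np.uint8)
        assert list(extract_indel_array(path)) == [-2, -2]

    def test_roundtrip_through_padded_rows(self):
        from adaptalign.tracepoint import apply_indel_array

        rng = np.random.default_rng(5)
        for _ in range(20):
            A, B, ops, _ = random_alignment(rng, n=120, edits=20)
            o = extract_indel_array(ops)
            rowa, rowb = apply_indel_array(o, *path_intervals(ops))
            assert len(rowa) == len(rowb) == len(ops)
            # dashes in the padded rows are exactly the indel columns
            assert [i for i, c in enumerate(rowa) if c == "-"] == list(
                np.flatnonzero(ops == OP_INS)
            )
            assert [i for i, c in enumerate(rowb) if c == "-"] == list(
                np.flatnonzero(ops == OP_DEL)
            )


class TestRefinableSegments:
    @pytest.mark.parametrize(
        "o,expected",
        [
            ([3, 5], [(0, 1)]),
            ([3, -5], []),
            ([3, 60], []),  # separation 57 >= R
            ([3, 5, 9, -2, -4], [(0, 2), (3, 4)]),
            ([7], []),
        ],
    )
    def test_examples(self, o, expected):
        assert find_refinable_segments(np.array(o), R=50) == expected


def oracle_min_gaps_plus_mismatches(A, B, D, L):
    """Exhaustive minimum of gaps+mismatches over all monotone placements of
    D insertions into L+1 slots."""
    best = None
    for slots in itertools.combinations_with_replacement(range(L + 1), D):
        G = len(set(slots))
        ins_before = [0] * (L + 1)
        for s in slots:
            ins_before[s] += 1
        S = 0
        off = 0
        for col in range(L):
            off += ins_before[col]
            if A[col] != B[col + off]:
                S += 1
        k = G + S
        if best is None or k < best:
            best = k
    return best


class TestRefineSegment:
    def test_single_contiguous_gap_unchanged(self):
        A = np.empty(0, dtype=np.uint8)
        B = np.array([1, 2], dtype=np.uint8)
        trap = Trapezoid(Aseg=A, Bseg=B, Dgaps=2, Lspan=0)
        path = refine_segment(trap)
        assert trap.k == 1 and (path == OP_INS).all()

    def test_two_gaps_merge_for_one_mismatch(self):
        # insertions two columns apart where fusing them costs one mismatch
        A = np.array([0, 1], dtype=np.uint8)
        B = np.array([2, 0, 3, 1], dtype=np.uint8)
        trap = Trapezoid(Aseg=A, Bseg=B, Dgaps=2, Lspan=2)
        path = refine_segment(trap)
        assert trap.k == 2
        assert count_gaps(path) == 1  # ties resolved toward fewer gaps

    @pytest.mark.parametrize("D", range(2, 7))
    def test_matches_exhaustive_oracle(self, D):
        rng = np.random.default_rng(100 + D)
        for L in range(0, 21, 4):
            for _ in range(3):
                A = rng.integers(0, 2, L, dtype=np.uint8)  # binary: many ties
                B = rng.integers(0, 2, L + D, dtype=np.uint8)
                trap = Trapezoid(Aseg=A, Bseg=B, Dgaps=D, Lspan=L)
                path = refine_segment(trap)
                assert trap.k == oracle_min_gaps_plus_mismatches(A, B, D, L)
                assert path_intervals(path) == (L, L + D)
                diffs, _ = path_stats(path, A, B, 0, 0)
                assert count_gaps(path) + (diffs - D) == trap.k


class TestRefinePath:
    def test_no_refinable_segments_unchanged(self):
        rng = np.random.default_rng(6)
        A = rng.integers(0, 4, 200, dtype=np.uint8)
        path = np.zeros(200, dtype=np.uint8)
        assert (refine_path(path, 0, 0, A, A) == path).all()

    def test_gap_count_never_increases(self):
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(200):
            A, B, ops, _ = random_alignment(rng, n=300, edits=25)
            new = refine_path(ops, 0, 0, A, B, R=50)
            assert path_intervals(new) == path_intervals(ops)
            assert count_gaps(new) <= count_gaps(ops)
            checked += 1
        assert checked == 200

    def test_refined_path_still_encodes_within_byte_cap(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            A, B, ops, _ = random_alignment(rng, n=1000, edits=120)
            new = refine_path(ops, 0, 0, A, B)
            encode_tracepoints(new, 0, len(A), 0, len(B), 100)  # must not raise


class TestCigar:
    def test_identity_dialects(self):
        A = np.zeros(100, dtype=np.uint8)
        path = np.zeros(100, dtype=np.uint8)
        assert path_to_cigar(path, A, A, 0, 0, "=X") == "100="
        assert path_to_cigar(path, A, A, 0, 0, "M") == "100M"

    def test_mismatch_and_insertion_lengths_reconcile(self):
        A = np.array([0, 1, 2, 3], dtype=np.uint8)
        B = np.array([0, 1, 1, 0, 3], dtype=np.uint8)
        path = np.array([OP_DIAG, OP_DIAG, OP_DIAG, OP_INS, OP_DIAG], dtype=np.uint8)
        cg = path_to_cigar(path, A, B, 0, 0, "=X")
        assert cg == "2=1X1I1="
        na = sum(int(n) for n, c in _iter_cigar(cg) if c in "=XMD")
        nb = sum(int(n) for n, c in _iter_cigar(cg) if c in "=XMI")
        assert (na, nb) == (len(A), len(B))

    def test_parse_back_roundtrip(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            A, B, ops, _ = random_alignment(rng, n=200, edits=30)
            cg = path_to_cigar(ops, A, B, 0, 0, "=X")
            assert (cigar_to_path(cg) == ops).all()


def _iter_cigar(cg):
    num = ""
    for ch in cg:
        if ch.isdigit():
            num += ch
        else:
            yield num, ch
            num = ""
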