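"""Shift-template library, NCC scoring and P-matrix construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from strandscan import (
    Alignment,
    build_bb_matrix,
    build_p_matrix,
    build_shift_library,
    make_ideal_sheet,
    match_alignment,
    ncc,
    shift_profile,
    SheetSpec,
)
from strandscan.shifts import shift_template


def brute_force_match(sub, library, min_contacts=3):
    """Exhaustive argmax over the library with the documented tie-break."""
    sub = np.asarray(sub)
    if not sub.any():
        return None
    best = None
    for alignment, template in library:
        t = template.sum()
        overlap = int((sub * template).sum())
        score = overlap / np.sqrt(sub.sum() * t)
        key = (
            -score,
            abs(alignment.shift),
            alignment.orientation != "parallel",
            alignment.shift < 0,
        )
        if best is None or key < best[0]:
            best = (key, alignment, score, overlap)
    _, alignment, score, overlap = best
    if overlap < min_contacts:
        return None
    return alignment, score, overlap


class TestShiftLibrary:
    def test_parallel_zero_is_identity(self):
        lib = build_shift_library(4, 1)
        assert np.array_equal(lib[Alignment("parallel", 0)], np.eye(4, dtype=np.uint8))

    def test_parallel_plus_one_superdiagonal(self):
        lib = build_shift_library(4, 1)
        t = lib[Alignment("parallel", 1)]
        assert sorted(zip(*np.nonzero(t))) == [(0, 1), (1, 2), (2, 3)]

    def test_antiparallel_zero_is_reversal(self):
        lib = build_shift_library(4, 1)
        t = lib[Alignment("antiparallel", 0)]
        assert sorted(zip(*np.nonzero(t))) == [(0, 3), (1, 2), (2, 1), (3, 0)]

    def test_template_support_size_is_overlap_length(self):
        SL, k_max = 9, 6
        lib = build_shift_library(SL, k_max)
        assert len(lib) == 2 * (2 * k_max + 1)
        for alignment, template in lib:
            assert template.sum() == SL - abs(alignment.shift)

    def test_templates_all_distinct(self):
        lib = build_shift_library(7)
        seen = {tuple(t.ravel()) for _, t in lib}
        assert len(seen) == len(lib)

    def test_k_max_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            build_shift_library(6, 4)

    def test_antiparallel_templates_symmetric_parallel_transpose_negates(self):
        lib = build_shift_library(8)
        for alignment, template in lib:
            partner = lib[alignment.reverse()]
            assert np.array_equal(template.T, partner)


class TestNCC:
    def test_equal_matrices_score_one(self):
        t = shift_template(5, Alignment("parallel", 1))
        assert ncc(t, t) == pytest.approx(1.0)

    def test_disjoint_supports_score_zero(self):
        assert ncc(np.eye(4), np.eye(4)[::-1]) == 0.0

    def test_hand_computed_value(self):
        # identity + one stray contact vs identity: 4 / sqrt(5*4)... using
        # the documented example: sub has the 4 diagonal ones plus (0, 2)
        sub = np.eye(4, dtype=int)
        sub[0, 2] = 1
        # overlap 4, sums 5 and 4 -> 4/sqrt(20); with the 3-ones variant:
        sub3 = np.zeros((4, 4), int)
        sub3[0, 0] = sub3[1, 1] = sub3[2, 2] = 1
        sub3[0, 2] = 1
        assert ncc(sub3, np.eye(4)) == pytest.approx(3 / np.sqrt(4 * 4))

    def test_all_zero_is_undefined(self):
        assert ncc(np.zeros((3, 3)), np.eye(3)) is None

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ncc(np.eye(3), np.eye(4))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        a=arrays(np.uint8, (5, 5), elements=st.integers(0, 1)),
        b=arrays(np.uint8, (5, 5), elements=st.integers(0, 1)),
    )
    def test_symmetric_and_bounded(self, a, b):
        s = ncc(a, b)
        assert s == ncc(b, a)
        if s is not None:
            assert 0.0 <= s <= 1.0

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        a=arrays(np.uint8, (5, 5), elements=st.integers(0, 1)),
        b=arrays(np.uint8, (5, 5), elements=st.integers(0, 1)),
        perm=st.permutations(range(5)),
    )
    def test_invariant_under_simultaneous_permutation(self, a, b, perm):
        perm = list(perm)
        assert ncc(a, b) == ncc(a[perm][:, perm], b[perm][:, perm])


class TestMatchAlignment:
    def test_every_library_template_matches_itself(self):
        lib = build_shift_library(10)
        for alignment, template in lib:
            m = match_alignment(template, lib)
            assert m is not None
            assert m.alignment == alignment
            assert m.score == pytest.approx(1.0)

    def test_stray_contact_still_matches_in_register(self):
        sub = np.zeros((6, 6), np.uint8)
        sub[0, 0] = sub[1, 1] = sub[2, 2] = 1
        sub[4, 1] = 1  # off-template stray
        lib = build_shift_library(6)
        m = match_alignment(sub, lib)
        assert m.alignment == Alignment("parallel", 0)
        assert m.contact_count == 3

    def test_two_contacts_below_minimum_gives_null(self):
        sub = np.zeros((6, 6), np.uint8)
        sub[0, 5] = sub[5, 0] = 1  # two ones on the antidiagonal
        assert match_alignment(sub, build_shift_library(6)) is None

    def test_all_zero_gives_null(self):
        assert match_alignment(np.zeros((5, 5)), build_shift_library(5)) is None

    def test_agrees_with_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(2024)
        lib = build_shift_library(8)
        for _ in range(300):
            sub = (rng.random((8, 8)) < 0.25).astype(np.uint8)
            got = match_alignment(sub, lib)
            expected = brute_force_match(sub, lib)
            if expected is None:
                assert got is None
            else:
                assert got.alignment == expected[0]
                assert got.score == pytest.approx(expected[1])
                assert got.contact_count == expected[2]


class TestPMatrix:
    def test_zero_bb_gives_empty_p(self, small_sheet_3x10):
        frame, topo, _ = small_sheet_3x10
        far = frame.coordinates.copy()
        far[10:20] += 100.0
        far[20:] += 200.0
        from strandscan import BackboneFrame

        bb = build_bb_matrix(BackboneFrame(far), topo)
        p = build_p_matrix(bb, build_shift_library(10))
        assert p.n_beta_interactions == 0
        assert p.get(0, 1) is None

    def test_ideal_sheet_adjacent_pairs_only(self, analyzed_sheet):
        """Next-nearest strands sit 9.6 A apart: outside the window."""
        _, _, _, p = analyzed_sheet
        assert p.n_beta_interactions == 11
        assert set(p.entries) == {(s, s + 1) for s in range(11)}
        assert all(
            m.alignment == Alignment("parallel", 0) for m in p.entries.values()
        )

    def test_alternating_antiparallel_shifts_recovered(self):
        frame, topo, _ = make_ideal_sheet(
            SheetSpec(3, 10, ["antiparallel", "antiparallel"], [1, -1])
        )
        bb = build_bb_matrix(frame, topo)
        p = build_p_matrix(bb, build_shift_library(10))
        assert p.get(0, 1).alignment == Alignment("antiparallel", 1)
        assert p.get(1, 2).alignment == Alignment("antiparallel", -1)

    def test_reverse_lookup_negates_parallel_shift(self):
        frame, topo, _ = make_ideal_sheet(SheetSpec(2, 10, "parallel", 2))
        bb = build_bb_matrix(frame, topo)
        p = build_p_matrix(bb, build_shift_library(10))
        assert p.get(0, 1).alignment == Alignment("parallel", 2)
        assert p.get(1, 0).alignment == Alignment("parallel", -2)

    def test_interaction_count_invariant_under_strand_relabeling(self):
        rng = np.random.default_rng(8)
        from strandscan import BackboneFrame, SystemTopology

        coords = rng.uniform(0, 30, size=(30, 3))
        topo = SystemTopology.regular(6, 5)
        lib = build_shift_library(5)
        bb = build_bb_matrix(BackboneFrame(coords), topo)
        baseline = build_p_matrix(bb, lib).n_beta_interactions
        perm = rng.permutation(6)
        permuted = np.concatenate(
            [coords[5 * s : 5 * s + 5] for s in perm]
        )
        bb2 = build_bb_matrix(BackboneFrame(permuted), topo)
        assert build_p_matrix(bb2, lib).n_beta_interactions == baseline


class TestShiftProfile:
    def test_empty_profile(self, small_sheet_3x10):
        frame, topo, _ = small_sheet_3x10
        from strandscan import BackboneFrame, PMatrix

        p = PMatrix(3, {})
        profile = shift_profile(p)
        assert profile.total == 0
        assert profile.dominant_orientation() is None

    def test_single_bin_fraction_one(self, analyzed_sheet):
        _, _, _, p = analyzed_sheet
        profile = shift_profile(p)
        assert profile.total == 11
        assert profile.bins[Alignment("parallel", 0)] == 11
        assert profile.fraction(Alignment("parallel", 0)) == 1.0
        assert profile.dominant_orientation() == "parallel"
        assert profile.as_rows() == [("parallel", 0, 11, 1.0)]
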