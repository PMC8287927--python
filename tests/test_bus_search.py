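import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from busscan import (
    OriginRecord,
    SearchParams,
    enumerate_candidates,
    revcomp,
    screen_candidates,
    search_origin,
)
from busscan.simulate import inert_background, mutated_box

from conftest import DEFAULT_MOTIF, LONG_MOTIF, multi_module_origin, single_box_origin, tandem_origin

PARAMS = SearchParams()


class TestEnumerateCandidates:
    def test_single_planted_module_yields_one_candidate(self):
        origin, layout = single_box_origin(mismatches=0, spacer=13, n_trios=7)
        cands = enumerate_candidates(origin, PARAMS)
        assert len(cands) == 1
        c = cands[0]
        assert (c.strand, c.box1.start, c.spacer, c.trios.count) == ("+", 30, 13, 7)
        assert c.box2 is None and c.reference_box == "box1"

    def test_spacer_over_sixteen_yields_nothing(self):
        origin, _ = single_box_origin(mismatches=0, spacer=17, n_trios=5)
        assert enumerate_candidates(origin, PARAMS) == []

    def test_unsearchable_origin_yields_empty_list(self):
        origin = OriginRecord(id="tiny", sequence="ACGTACGT")
        assert enumerate_candidates(origin, PARAMS) == []

    def test_tandem_spacer_decomposition(self):
        # perfect anchor, 2 bp gap, 3-mismatch secondary, 4 bp gap, 5 trios:
        # spacer = 2 + 9 + 4 = 15, counted from the anchor
        origin, layout = tandem_origin(box1_mm=0, box2_mm=3, interbox_gap=2, trio_gap=4)
        cands = enumerate_candidates(origin, PARAMS)
        assert len(cands) == 1
        c = cands[0]
        assert c.tandem and c.reference_box == "box1"
        assert c.reference.start == layout["box1_start"]
        assert c.spacer == 15
        assert c.box2.mismatches == 3 and c.primary_mismatches == 0

    def test_upstream_takeover_recounts_spacer_beyond_sixteen(self):
        # first-located box has 2 mismatches; a perfect box sits 3 bp
        # upstream, takes over as reference, and the spacer grows past 16
        motif = DEFAULT_MOTIF
        seq = (
            inert_background(30)
            + motif
            + inert_background(3, 3)
            + mutated_box(motif, 2)
            + inert_background(10, 6)
            + "TAG" * 5
            + inert_background(30, 9)
        )
        origin = OriginRecord(id="takeover", sequence=seq)
        cands = enumerate_candidates(origin, PARAMS)
        assert len(cands) == 1
        c = cands[0]
        assert c.reference_box == "box2" and c.reference.start == 30
        assert c.spacer == 3 + 9 + 10 == 22
        assert c.primary_mismatches == 0

    def test_equal_mismatch_tandem_keeps_first_located_as_reference(self):
        # two perfect boxes: no strict conservation difference, so no
        # takeover for the downstream-first pairing; both pairings survive
        origin, layout = tandem_origin(box1_mm=0, box2_mm=0, interbox_gap=2, trio_gap=4)
        cands = enumerate_candidates(origin, PARAMS)
        refs = {(c.reference.start, c.spacer) for c in cands}
        assert refs == {(layout["box1_start"], 15), (layout["box2_start"], 4)}

    def test_plus_only_scanning_switch(self):
        origin, _ = single_box_origin(mismatches=0, spacer=13, n_trios=5)
        flipped = OriginRecord(id="rc", sequence=revcomp(origin.sequence))
        assert enumerate_candidates(flipped, PARAMS.with_(both_strands=False)) == []
        assert len(enumerate_candidates(flipped, PARAMS)) == 1


class TestBoundaryExactness:
    @pytest.mark.parametrize(
        "motif,cap", [(DEFAULT_MOTIF, 2), (LONG_MOTIF, 3)], ids=["9bp", "12bp"]
    )
    def test_sole_box_mismatch_cap(self, motif, cap):
        at_cap, _ = single_box_origin(mismatches=cap, spacer=13, n_trios=5, motif=motif)
        over, _ = single_box_origin(mismatches=cap + 1, spacer=13, n_trios=5, motif=motif)
        assert search_origin(at_cap, PARAMS).found
        assert not search_origin(over, PARAMS).found

    @pytest.mark.parametrize("motif", [DEFAULT_MOTIF, LONG_MOTIF], ids=["9bp", "12bp"])
    def test_spacer_cap(self, motif):
        at_cap, _ = single_box_origin(mismatches=0, spacer=16, n_trios=5, motif=motif)
        over, _ = single_box_origin(mismatches=0, spacer=17, n_trios=5, motif=motif)
        assert search_origin(at_cap, PARAMS).retained.spacer == 16
        assert not search_origin(over, PARAMS).found

    @pytest.mark.parametrize("motif", [DEFAULT_MOTIF, LONG_MOTIF], ids=["9bp", "12bp"])
    def test_minimum_trio_count(self, motif):
        at_min, _ = single_box_origin(mismatches=0, spacer=13, n_trios=3, motif=motif)
        under, _ = single_box_origin(mismatches=0, spacer=13, n_trios=2, motif=motif)
        assert search_origin(at_min, PARAMS).retained.trios.count == 3
        assert not search_origin(under, PARAMS).found

    def test_secondary_box_mismatch_cap(self):
        at_cap, _ = tandem_origin(box1_mm=0, box2_mm=4)
        over, _ = tandem_origin(box1_mm=0, box2_mm=5)
        res_at = search_origin(at_cap, PARAMS)
        assert res_at.retained.tandem and res_at.retained.box2.mismatches == 4
        res_over = search_origin(over, PARAMS)
        assert res_over.found and not res_over.retained.tandem  # falls back to sole


class TestScreening:
    def _sole(self, seed, score_trios_n, mm, spacer):
        origin, _ = single_box_origin(mismatches=mm, spacer=spacer, n_trios=score_trios_n)
        return enumerate_candidates(origin, PARAMS)[0]

    def test_empty_candidate_list_not_found(self):
        res = screen_candidates([], PARAMS)
        assert not res.found and res.tie_count == 0 and res.retained is None

    def test_highest_trio_score_wins_regardless_of_other_fields(self):
        # 3 consensus trios (9.0) with a poor spacer and mismatched box vs
        # 5 non-consensus-free... the higher score must win outright
        weak = self._sole(0, 3, 0, 13)   # score 9.0, perfect everything else
        strong = self._sole(0, 5, 2, 16)  # score 15.0, worse box and spacer
        res = screen_candidates([weak, strong], PARAMS)
        assert res.retained is strong

    def test_fewest_mismatches_decides_before_spacer(self):
        better_spacer = self._sole(0, 5, 1, 13)
        fewer_mm = self._sole(0, 5, 0, 16)
        res = screen_candidates([better_spacer, fewer_mm], PARAMS)
        assert res.retained is fewer_mm

    def test_spacer_closest_to_thirteen_wins_last(self):
        s13 = self._sole(0, 5, 0, 13)
        s16 = self._sole(0, 5, 0, 16)
        res = screen_candidates([s16, s13], PARAMS)
        assert res.retained is s13 and res.tie_count == 1

    def test_filters_never_increase_survivors(self):
        cands = [self._sole(0, n, mm, sp) for n, mm, sp in [(5, 0, 13), (5, 1, 13), (4, 0, 10), (5, 0, 16)]]
        res = screen_candidates(cands, PARAMS)
        assert res.candidates_considered == 4
        assert 1 <= res.tie_count <= 4

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.permutations(range(4)))
    def test_permutation_invariance(self, order):
        cands = [self._sole(0, n, mm, sp) for n, mm, sp in [(5, 0, 13), (5, 1, 13), (4, 0, 10), (5, 0, 16)]]
        base = screen_candidates(cands, PARAMS)
        shuffled = screen_candidates([cands[i] for i in order], PARAMS)
        assert shuffled.retained.spacer == base.retained.spacer
        assert shuffled.retained.primary_mismatches == base.retained.primary_mismatches
        assert shuffled.tie_count == base.tie_count


class TestSearchOrigin:
    def test_background_only_not_found(self):
        origin = OriginRecord(id="bg", sequence=inert_background(200))
        res = search_origin(origin)
        assert not res.found and res.candidates_considered == 0

    def test_two_equal_modules_spacer_thirteen_retained(self):
        origin, offsets = multi_module_origin([(0, 7, 5), (0, 13, 5)])
        res = search_origin(origin)
        assert res.found and res.retained.spacer == 13

    def test_residual_tie_breaks_leftmost_and_reports_count(self):
        origin, offsets = multi_module_origin([(0, 13, 5), (0, 13, 5)])
        res = search_origin(origin)
        assert res.tie_count == 2
        assert res.retained.reference.start == offsets[0]

    def test_strand_symmetry_with_coordinate_mapping(self):
        origin, layout = single_box_origin(mismatches=1, spacer=11, n_trios=4)
        res_fwd = search_origin(origin)
        flipped = OriginRecord(id="rc", sequence=revcomp(origin.sequence), box_motif=origin.box_motif)
        res_rc = search_origin(flipped)
        assert res_fwd.found and res_rc.found
        a, b = res_fwd.retained, res_rc.retained
        assert (a.strand, b.strand) == ("+", "-")
        # scanned-strand coordinates coincide after the flip
        assert a.reference.start == b.reference.start
        assert a.spacer == b.spacer and a.trios.trios == b.trios.trios
        assert a.trio_score == b.trio_score and a.primary_mismatches == b.primary_mismatches
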