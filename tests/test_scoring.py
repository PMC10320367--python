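"""Index arithmetic, validation and severity-band behaviour."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semacd.scoring import (
    NOT_ASSESSED,
    SES_SEGMENTS,
    ScoringError,
    SemaRating,
    SesSegmentItems,
    classify_sema,
    classify_ses,
    compute_sema_total,
    compute_ses_total,
)
from .conftest import enumerate_valid_ratings


def rating(ileum, colon, segs, **kw):
    return SemaRating(video_id="v", reader_id="r", ileum=ileum, colon_overall=colon,
                      involved_segments=frozenset(segs), **kw)


class TestSemaTotal:
    @pytest.mark.parametrize(
        "ileum,colon,segs,total",
        [
            (4, 4, ("ascending", "transverse", "descending", "rectum"), 20),
            (0, 0, (), 0),
            (2, 3, ("ascending", "rectum"), 8),
            (3, 0, (), 3),
            (0, 1, ("transverse",), 1),
            (4, 2, ("ascending", "transverse", "descending"), 10),
        ],
    )
    def test_worked_examples(self, ileum, colon, segs, total):
        score = compute_sema_total(rating(ileum, colon, segs))
        assert score.total == total
        assert not score.partial

    def test_not_assessed_ileum_gives_partial_colon_only_total(self):
        score = compute_sema_total(rating(NOT_ASSESSED, 1, ("transverse",)))
        assert score.colon_component == 1
        assert score.total == 1
        assert score.partial and not score.ileum_assessed and score.colon_assessed

    def test_not_assessed_colon_gives_partial_ileum_only_total(self):
        score = compute_sema_total(rating(3, NOT_ASSESSED, ()))
        assert score.total == 3 and score.partial and not score.colon_assessed

    def test_fully_unassessed_total_is_none(self):
        score = compute_sema_total(rating(NOT_ASSESSED, NOT_ASSESSED, ()))
        assert score.total is None and score.partial

    @pytest.mark.parametrize(
        "ileum,colon,segs,msg",
        [
            (3, 3, (), "involved_segments"),
            (0, 0, ("rectum",), "involved_segments"),
            (5, 0, (), "ileum"),
            (0, -1, (), "colon_overall"),
            (0, 1, ("sigmoid",), "involved_segments"),
        ],
    )
    def test_invariant_violations_name_the_field(self, ileum, colon, segs, msg):
        with pytest.raises(ScoringError, match=msg):
            rating(ileum, colon, segs)

    def test_exhaustive_enumeration_range_and_monotonicity(self):
        totals = {}
        for r in enumerate_valid_ratings(include_na=False):
            t = compute_sema_total(r).total
            assert 0 <= t <= 20
            totals[(r.ileum, r.colon_overall, frozenset(r.involved_segments))] = t
        vals = list(totals.values())
        assert max(vals) == 20 and min(vals) == 0
        for (ileum, colon, segs), t in totals.items():
            if ileum < 4:
                assert totals[(ileum + 1, colon, segs)] == t + 1
            if 0 < colon < 4:
                assert totals[(ileum, colon + 1, segs)] >= t
        # only the involved-segment count matters (permutation invariance)
        a = compute_sema_total(rating(1, 2, ("ascending", "rectum"))).total
        b = compute_sema_total(rating(1, 2, ("transverse", "descending"))).total
        assert a == b

    def test_involvement_count_monotonicity(self):
        prev = -1
        segs = ("ascending", "transverse", "descending", "rectum")
        for k in range(1, 5):
            t = compute_sema_total(rating(0, 2, segs[:k])).total
            assert t > prev
            prev = t


class TestSesTotal:
    def test_all_zero_and_single_segment(self):
        zeros = [SesSegmentItems(segment=s) for s in SES_SEGMENTS]
        assert compute_ses_total(zeros).total == 0
        items = [SesSegmentItems(segment=s) for s in SES_SEGMENTS[1:]]
        items.append(SesSegmentItems("ileum", 3, 3, 3, 3))
        score = compute_ses_total(items)
        assert score.total == 12 and score.n_assessed_segments == 5

    def test_duplicate_segment_and_all_unassessed_rejected(self):
        with pytest.raises(ScoringError, match="duplicate"):
            compute_ses_total([SesSegmentItems("ileum"), SesSegmentItems("ileum")])
        with pytest.raises(ScoringError, match="unassessed"):
            compute_ses_total([SesSegmentItems("ileum", assessed=False)])

    def test_item_out_of_range_rejected(self):
        with pytest.raises(ScoringError, match="ulcer_size"):
            SesSegmentItems("ileum", ulcer_size=4)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.tuples(*(st.integers(0, 3) for _ in range(4)), st.booleans()),
            min_size=5, max_size=5,
        )
    )
    def test_matches_brute_force_summation(self, rows):
        items = [
            SesSegmentItems(seg, *vals, assessed=assessed)
            for seg, (*vals, assessed) in zip(SES_SEGMENTS, rows)
        ]
        if not any(r[-1] for r in rows):
            with pytest.raises(ScoringError):
                compute_ses_total(items)
            return
        expected = 0  # independent plain-loop oracle
        for (*vals, assessed) in rows:
            if assessed:
                for v in vals:
                    expected += v
        assert compute_ses_total(items).total == expected


class TestSeverityBands:
    def test_sema_integer_grid_reproduces_printed_partition(self):
        expected = (
            ["inactive"] + ["minimal"] + ["mild"] * 3 + ["moderate"] * 5 + ["severe"] * 11
        )
        assert [classify_sema(t) for t in range(21)] == expected

    @pytest.mark.parametrize(
        "total,band",
        [(0.5, "inactive"), (1.5, "minimal"), (4.5, "mild"), (9.5, "moderate"),
         (10.0, "severe"), (20.0, "severe")],
    )
    def test_sema_half_integer_medians(self, total, band):
        assert classify_sema(total) == band

    def test_ses_integer_grid_reproduces_printed_partition(self):
        expected = ["inactive"] * 3 + ["mild"] * 4 + ["moderate"] * 9 + ["severe"] * 25
        assert [classify_ses(t) for t in range(41)] == expected
        assert classify_ses(37) == "severe"

    def test_out_of_range_rejected(self):
        for bad in (-0.5, 20.5):
            with pytest.raises(ScoringError):
                classify_sema(bad)
        with pytest.raises(ScoringError):
            classify_ses(-1)
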