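"""Behavioral scoring: formula correctness, sign conventions, symmetries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokemap.scoring import (
    BehaviorVector,
    CancellationItem,
    CancellationResponse,
    ClockPlacement,
    ClockResponse,
    ConstructionScore,
    MissingDataError,
    NormativeParams,
    ScoringError,
    SCORE_NAMES,
    assemble_vector,
    invert_construction,
    raw_coc,
    score_allocentric,
    score_bisection,
    score_clock_asymmetry,
    score_clock_margin,
    score_egocentric,
    score_table,
)

from conftest import make_bisection, make_cancellation, make_clock, intact_construction


class TestBisection:
    def test_center_mark_is_zero(self):
        assert score_bisection(make_bisection(offsets20=(0.0,)), 200) == 0.0

    def test_mean_of_trials(self):
        assert score_bisection(make_bisection(offsets20=(10.0, 6.0)), 200) == pytest.approx(8.0)

    def test_missing_length_errors(self):
        resp = make_bisection(offsets20=(), offsets5=(1.0,))
        with pytest.raises(MissingDataError):
            score_bisection(resp, 200)

    def test_mark_off_line_rejected(self):
        with pytest.raises(ScoringError):
            make_bisection(offsets5=(30.0,))


class TestEgocentric:
    def test_symmetric_marks_zero(self):
        resp = make_cancellation(target_xs_marked=(-50, -10, 10, 50))
        assert score_egocentric(resp, "R") == pytest.approx(0.0)

    def test_right_only_marks_match_mean_oracle(self):
        xs_marked = (20.0, 40.0, 90.0)
        resp = make_cancellation(target_xs_marked=xs_marked, target_xs_unmarked=(-20, -40, -90))
        expected = np.mean(xs_marked) / 150.0
        assert score_egocentric(resp, "R") == pytest.approx(expected)
        # for a left lesion the contralesional side is the right: sign flips
        assert score_egocentric(resp, "L") == pytest.approx(-expected)

    def test_norm_centering_identity(self):
        resp = make_cancellation(target_xs_marked=(30.0, 60.0))
        raw = raw_coc(resp)
        assert score_egocentric(resp, "R", NormativeParams(raw, 1.0)) == pytest.approx(0.0)

    def test_no_marks_errors(self):
        resp = make_cancellation(target_xs_unmarked=(10.0,))
        with pytest.raises(MissingDataError):
            score_egocentric(resp, "R")

    @given(
        xs=st.lists(st.floats(-150, 150, allow_nan=False), min_size=1, max_size=20),
    )
    @settings(deadline=None, max_examples=50)
    def test_raw_coc_bounded(self, xs):
        resp = make_cancellation(target_xs_marked=tuple(xs))
        assert -1.0 <= raw_coc(resp) <= 1.0


class TestAllocentric:
    def test_balanced_errors_zero(self):
        resp = make_cancellation(
            target_xs_marked=(0.0,) * 5, left_open_marked=2, right_open_marked=2
        )
        assert score_allocentric(resp, "R") == 0.0

    def test_printed_formula(self):
        # Contra_err=4, Ipsi_err=1, Whole_corr=30 -> 0.1 (right lesion: contra = left_open)
        resp = make_cancellation(
            target_xs_marked=(0.0,) * 30, left_open_marked=4, right_open_marked=1
        )
        assert score_allocentric(resp, "R") == pytest.approx(0.1)

    def test_no_correct_targets_errors(self):
        resp = make_cancellation(target_xs_unmarked=(0.0,), left_open_marked=1)
        with pytest.raises(MissingDataError):
            score_allocentric(resp, "R")

    @given(
        contra=st.integers(0, 10),
        ipsi=st.integers(0, 10),
        whole=st.integers(1, 10),
    )
    @settings(deadline=None, max_examples=50)
    def test_antisymmetry_and_bound(self, contra, ipsi, whole):
        a = make_cancellation(
            target_xs_marked=(0.0,) * whole, left_open_marked=contra, right_open_marked=ipsi
        )
        b = make_cancellation(
            target_xs_marked=(0.0,) * whole, left_open_marked=ipsi, right_open_marked=contra
        )
        A = score_allocentric(a, "R")
        assert A == pytest.approx(-score_allocentric(b, "R"))
        assert abs(A) <= (contra + ipsi) / whole + 1e-12


def mirror_clock(resp: ClockResponse) -> ClockResponse:
    """Left-right mirror of a clock drawing (labels and angles both reflect)."""

    def mlabel(h):
        return 12 if h % 12 == 0 else (12 - h) % 12 or 12

    placements = tuple(
        ClockPlacement(
            label=mlabel(p.label), angle_deg=(360.0 - p.angle_deg) % 360.0, radial_mm=p.radial_mm
        )
        for p in resp.placements
    )
    omitted = frozenset(mlabel(h) for h in resp.omitted)
    return ClockResponse(radius_mm=resp.radius_mm, placements=placements, omitted=omitted)


class TestClockAsymmetry:
    def test_intact_clock_zero(self):
        assert score_clock_asymmetry(make_clock()) == 0.0

    def test_left_omissions(self):
        assert score_clock_asymmetry(make_clock(omitted=(9, 10, 11))) == 3.0

    def test_within_side_translocation_half_point(self):
        # hour 2 at its correct angle + 40 degrees, still in the right half
        resp = make_clock(angles={2: 100.0})
        assert score_clock_asymmetry(resp) == -0.5

    def test_cross_midline_full_point(self):
        # hour 10 (left) drawn in the right half scores 1 for the left side
        resp = make_clock(angles={10: 60.0})
        assert score_clock_asymmetry(resp) == 1.0

    def test_midline_hour_displaced_laterally(self):
        # '12' pushed into the right half beyond the 30-degree cone:
        # rightward shift = left-side deficit
        resp = make_clock(angles={12: 40.0})
        assert score_clock_asymmetry(resp) == 1.0
        resp = make_clock(angles={12: 320.0})
        assert score_clock_asymmetry(resp) == -1.0

    def test_small_displacements_ignored(self):
        resp = make_clock(angles={2: 70.0, 9: 260.0, 12: 10.0})
        assert score_clock_asymmetry(resp) == 0.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(omitted=(9, 10, 11)),
            dict(angles={2: 100.0}),
            dict(angles={10: 60.0}, omitted=(1,)),
            dict(angles={12: 40.0, 6: 140.0}),
        ],
    )
    def test_mirror_antisymmetry(self, kwargs):
        resp = make_clock(**kwargs)
        assert score_clock_asymmetry(resp) + score_clock_asymmetry(mirror_clock(resp)) == 0.0


class TestClockMargin:
    def test_symmetric_zero(self):
        assert score_clock_margin(make_clock()) == pytest.approx(0.0)

    def test_margin_arithmetic(self):
        # radius 50, leftmost |x| = 35 (hour 9), rightmost |x| = 45 (hour 3)
        resp = make_clock(radials={9: 35.0, 3: 45.0}, radial=20.0)
        assert score_clock_margin(resp) == pytest.approx(10.0)

    def test_one_sided_clock_errors(self):
        resp = make_clock(omitted=(7, 8, 9, 10, 11))
        # remaining left-half placements gone: only midline and right hours
        with pytest.raises(MissingDataError):
            score_clock_margin(resp)


class TestConstruction:
    @pytest.mark.parametrize(
        "cube,clock,expected",
        [(1, 3, (0, 0)), (0, 0, (1, 3)), (0, 2, (1, 1))],
    )
    def test_inversion(self, cube, clock, expected):
        assert invert_construction(ConstructionScore(cube, clock)) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ScoringError):
            ConstructionScore(cube_raw=2, moca_clock_raw=0)


def mirror_cancellation(resp: CancellationResponse) -> CancellationResponse:
    swap = {"left_open": "right_open", "right_open": "left_open", "full_target": "full_target"}
    return CancellationResponse(
        items=tuple(
            CancellationItem(-it.x_mm, it.y_mm, swap[it.category], it.marked)
            for it in resp.items
        ),
        page_halfwidth_mm=resp.page_halfwidth_mm,
    )


class TestAssemble:
    def _intact(self):
        return dict(
            cancellation=make_cancellation(target_xs_marked=(-50.0, 50.0)),
            bisection=make_bisection(),
            clock=make_clock(),
            construction=intact_construction(),
        )

    def test_intact_responses_score_zero(self):
        vec = assemble_vector(**self._intact(), lesion_side="R")
        assert np.allclose(vec.as_array(), 0.0)

    def test_absolute_is_idempotent(self):
        parts = self._intact()
        parts["bisection"] = make_bisection(offsets20=(-12.0,), offsets5=(-3.0,))
        v1 = assemble_vector(**parts, lesion_side="R", absolute=True)
        arr = v1.as_array()
        assert np.all(arr >= 0)
        assert np.allclose(np.abs(arr), arr)

    def test_lateral_mirror_negates_lateralized_scores(self):
        parts = dict(
            cancellation=make_cancellation(
                target_xs_marked=(10.0, 40.0), target_xs_unmarked=(-30.0,),
                left_open_marked=3, right_open_marked=1,
            ),
            bisection=make_bisection(offsets20=(14.0,), offsets5=(4.0,)),
            clock=make_clock(omitted=(10, 11), radials={9: 30.0, 3: 45.0}, radial=20.0),
            construction=ConstructionScore(0, 2),
        )
        mirrored = dict(
            cancellation=mirror_cancellation(parts["cancellation"]),
            bisection=make_bisection(offsets20=(-14.0,), offsets5=(-4.0,)),
            clock=mirror_clock(parts["clock"]),
            construction=parts["construction"],
        )
        v = assemble_vector(**parts, lesion_side="R").as_array()
        m = assemble_vector(**mirrored, lesion_side="R").as_array()
        lateral = slice(0, 6)
        assert np.allclose(v[lateral], -m[lateral])
        assert np.allclose(v[6:], m[6:])

    def test_error_names_offending_score(self):
        parts = self._intact()
        parts["bisection"] = make_bisection(offsets20=(), offsets5=(0.0,))
        with pytest.raises(MissingDataError, match="bisect20"):
            assemble_vector(**parts, lesion_side="R")

    def test_score_table_columns(self):
        responses = {"p1": self._intact(), "p2": self._intact()}
        table = score_table(responses, {"p1": "R", "p2": "L"})
        assert list(table.columns) == ["patient_id", *SCORE_NAMES]
        assert len(table) == 2
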