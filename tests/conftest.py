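import numpy as np
import pytest

from strokemap.scoring import (
    BisectionResponse,
    BisectionTrial,
    CancellationItem,
    CancellationResponse,
    ClockPlacement,
    ClockResponse,
    ConstructionScore,
)
from strokemap.simulate import SimulationConfig, make_atlas, simulate_cohort


def make_clock(angles=None, omitted=(), radius=50.0, radial=40.0, radials=None):
    """Clock response with hours at given angles (default: all correct)."""
    angles = dict(angles or {})
    radials = dict(radials or {})
    placements = []
    for h in range(1, 13):
        if h in omitted:
            continue
        placements.append(
            ClockPlacement(
                label=h,
                angle_deg=angles.get(h, (h % 12) * 30.0) % 360.0,
                radial_mm=radials.get(h, radial),
            )
        )
    return ClockResponse(radius_mm=radius, placements=tuple(placements), omitted=frozenset(omitted))


def make_cancellation(
    target_xs_marked=(),
    target_xs_unmarked=(),
    left_open_marked=0,
    right_open_marked=0,
    n_distractors=10,
    halfwidth=150.0,
):
    """Cancellation sheet with explicit marked/unmarked target positions."""
    items = [
        CancellationItem(x, 0.0, "full_target", True) for x in target_xs_marked
    ] + [CancellationItem(x, 0.0, "full_target", False) for x in target_xs_unmarked]
    for i in range(n_distractors):
        x = -100.0 + i * 20.0
        items.append(CancellationItem(x, 10.0, "left_open", i < left_open_marked))
        items.append(CancellationItem(-x, -10.0, "right_open", i < right_open_marked))
    return CancellationResponse(items=tuple(items), page_halfwidth_mm=halfwidth)


def make_bisection(offsets20=(0.0,), offsets5=(0.0,)):
    trials = tuple(BisectionTrial(200.0, o) for o in offsets20) + tuple(
        BisectionTrial(50.0, o) for o in offsets5
    )
    return BisectionResponse(trials=trials)


def intact_construction():
    return ConstructionScore(cube_raw=1, moca_clock_raw=3)


@pytest.fixture(scope="session")
def atlas():
    return make_atlas()


@pytest.fixture(scope="session")
def small_cohort():
    """A 24-patient cohort reused by pipeline-level tests."""
    return simulate_cohort(SimulationConfig(n_patients=24, seed=11))
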