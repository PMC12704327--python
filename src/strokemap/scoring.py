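"""Scoring of the eight paper-and-pencil visuospatial tests.

Converts raw per-patient test responses (cancellation marks, line-bisection
marks, clock-drawing placements, construction points) into the eight scores
used throughout the analysis:

==============  ====================================================
score           meaning
==============  ====================================================
apples_ego      z-scored egocentric centre of cancellation (CoC)
apples_allo     allocentric error asymmetry A = (Contra-Ipsi)/Whole
bisect20        mean signed bisection deviation, 20 cm lines (mm)
bisect5         mean signed bisection deviation, 5 cm lines (mm)
clock_asym      left-minus-right clock omission/translocation tally
clock_margin    left-minus-right clock margin difference (mm)
moca_cube       inverted cube/chair copy score (0 = intact)
moca_clock      inverted clock-drawing score (0 = intact)
==============  ====================================================

Sign convention for the assembled vector: positive = left-lateralized
deficit (rightward bias on the page), negative = right-lateralized.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScoringError",
    "MissingDataError",
    "CancellationItem",
    "CancellationResponse",
    "BisectionTrial",
    "BisectionResponse",
    "ClockPlacement",
    "ClockResponse",
    "ConstructionScore",
    "NormativeParams",
    "BehaviorVector",
    "SCORE_NAMES",
    "score_bisection",
    "score_egocentric",
    "score_allocentric",
    "score_clock_asymmetry",
    "score_clock_margin",
    "invert_construction",
    "assemble_vector",
    "response_from_dict",
    "load_responses",
    "score_table",
    "write_score_table",
    "read_score_table",
]

SCORE_NAMES = (
    "apples_ego",
    "apples_allo",
    "bisect20",
    "bisect5",
    "clock_asym",
    "clock_margin",
    "moca_cube",
    "moca_clock",
)

CANCELLATION_CATEGORIES = frozenset({"full_target", "left_open", "right_open"})
LEFT_HOURS = frozenset({7, 8, 9, 10, 11})
RIGHT_HOURS = frozenset({1, 2, 3, 4, 5})
MIDLINE_HOURS = frozenset({6, 12})
#: half-width (degrees) of the tolerance cone centred on the correct hour location
CONE_HALF_DEG = 15.0

Side = Literal["L", "R"]


class ScoringError(ValueError):
    """A raw response cannot be scored (invalid or degenerate input)."""


class MissingDataError(ScoringError):
    """The response lacks the data needed for the requested score."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CancellationItem:
    x_mm: float
    y_mm: float
    category: str
    marked: bool


@dataclass(frozen=True)
class CancellationResponse:
    """Apple-cancellation sheet: targets (full apples) and lateral-opening distractors."""

    items: tuple[CancellationItem, ...]
    page_halfwidth_mm: float

    def __post_init__(self):
        object.__setattr__(self, "items", tuple(self.items))
        if self.page_halfwidth_mm <= 0:
            raise ScoringError("page_halfwidth_mm must be positive")
        for it in self.items:
            if it.category not in CANCELLATION_CATEGORIES:
                raise ScoringError(f"unknown cancellation category {it.category!r}")
            if abs(it.x_mm) > self.page_halfwidth_mm:
                raise ScoringError("item x position outside the page")
        if not any(it.category == "full_target" for it in self.items):
            raise ScoringError("cancellation sheet has no full_target items")


@dataclass(frozen=True)
class BisectionTrial:
    line_length_mm: float
    mark_offset_mm: float  # signed; positive = rightwards of true centre

    def __post_init__(self):
        if abs(self.mark_offset_mm) > self.line_length_mm / 2:
            raise ScoringError("bisection mark lies off the line")


@dataclass(frozen=True)
class BisectionResponse:
    trials: tuple[BisectionTrial, ...]

    def __post_init__(self):
        object.__setattr__(self, "trials", tuple(self.trials))


@dataclass(frozen=True)
class ClockPlacement:
    label: int  # hour 1..12
    angle_deg: float  # 0 = 12 o'clock, clockwise positive, in [0, 360)
    radial_mm: float  # distance from the circle centre

    def __post_init__(self):
        if not 1 <= self.label <= 12:
            raise ScoringError(f"invalid hour label {self.label}")
        if self.radial_mm < 0:
            raise ScoringError("radial distance must be non-negative")


@dataclass(frozen=True)
class ClockResponse:
    radius_mm: float
    placements: tuple[ClockPlacement, ...]
    omitted: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "placements", tuple(self.placements))
        object.__setattr__(self, "omitted", frozenset(self.omitted))
        labels = [p.label for p in self.placements]
        if len(set(labels)) != len(labels):
            raise ScoringError("duplicate hour labels in clock drawing")
        covered = set(labels) | self.omitted
        if covered != set(range(1, 13)) or set(labels) & self.omitted:
            raise ScoringError("placements and omissions must partition hours 1..12")
        if self.radius_mm <= 0:
            raise ScoringError("clock radius must be positive")


@dataclass(frozen=True)
class ConstructionScore:
    cube_raw: int  # 0..1 points on the cube/chair copy
    moca_clock_raw: int  # 0..3 points on the MoCA clock drawing

    def __post_init__(self):
        if self.cube_raw not in (0, 1):
            raise ScoringError("cube_raw must be 0 or 1")
        if self.moca_clock_raw not in (0, 1, 2, 3):
            raise ScoringError("moca_clock_raw must be in 0..3")


@dataclass(frozen=True)
class NormativeParams:
    """Reference mean/SD for the z-transformation of the egocentric CoC."""

    coc_mean: float = 0.0
    coc_sd: float = 1.0

    def __post_init__(self):
        if self.coc_sd <= 0:
            raise ScoringError("coc_sd must be positive")


@dataclass(frozen=True)
class BehaviorVector:
    apples_ego: float
    apples_allo: float
    bisect20: float
    bisect5: float
    clock_asym: float
    clock_margin: float
    moca_cube: float
    moca_clock: float
    signed: bool = True

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in SCORE_NAMES], dtype=float)

    def __post_init__(self):
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ScoringError("behavior vector contains non-finite values")
        if not self.signed and np.any(vals < 0):
            raise ScoringError("absolute-valued vector has negative entries")


# ---------------------------------------------------------------------------
# individual scores
# ---------------------------------------------------------------------------


def score_bisection(resp: BisectionResponse, length: float) -> float:
    """Mean signed deviation (mm) from the true centre over trials of ``length``."""
    offsets = [t.mark_offset_mm for t in resp.trials if t.line_length_mm == length]
    if not offsets:
        raise MissingDataError(f"no bisection trial of length {length} mm")
    return float(np.mean(offsets))


def _check_side(lesion_side: str) -> Side:
    if lesion_side not in ("L", "R"):
        raise ScoringError(f"lesion side must be 'L' or 'R', got {lesion_side!r}")
    return lesion_side  # type: ignore[return-value]


def raw_coc(resp: CancellationResponse) -> float:
    """Page-convention raw centre of cancellation.

    Mean horizontal position of the marked full targets, normalized by the
    page half-width; positive when marks cluster on the right of the page
    (left-sided omissions). Always in [-1, 1].
    """
    marked = [it.x_mm for it in resp.items if it.category == "full_target" and it.marked]
    if not marked:
        raise MissingDataError("no full target was marked; CoC undefined")
    return float(np.mean(marked)) / resp.page_halfwidth_mm


def score_egocentric(
    resp: CancellationResponse, lesion_side: str, norm: NormativeParams = NormativeParams()
) -> float:
    """z-scored egocentric CoC, positive = contralesional omission bias."""
    side = _check_side(lesion_side)
    coc = raw_coc(resp)
    if side == "L":  # contralesional = right side of the page
        coc = -coc
    return (coc - norm.coc_mean) / norm.coc_sd


def score_allocentric(resp: CancellationResponse, lesion_side: str) -> float:
    """Allocentric score A = (Contra_err - Ipsi_err) / Whole_corr."""
    side = _check_side(lesion_side)
    whole_corr = sum(1 for it in resp.items if it.category == "full_target" and it.marked)
    if whole_corr == 0:
        raise MissingDataError("no full target was marked; allocentric score undefined")
    contra_cat = "left_open" if side == "R" else "right_open"
    ipsi_cat = "right_open" if side == "R" else "left_open"
    contra_err = sum(1 for it in resp.items if it.category == contra_cat and it.marked)
    ipsi_err = sum(1 for it in resp.items if it.category == ipsi_cat and it.marked)
    return (contra_err - ipsi_err) / whole_corr


def _clock_x(p: ClockPlacement) -> float:
    # angle 0 = 12 o'clock, clockwise positive -> x = r sin(theta), y = r cos(theta)
    return p.radial_mm * math.sin(math.radians(p.angle_deg))


def _correct_angle(label: int) -> float:
    return (label % 12) * 30.0


def _angular_deviation(angle: float, correct: float) -> float:
    """Absolute circular distance in degrees, in [0, 180]."""
    d = (angle - correct) % 360.0
    return min(d, 360.0 - d)


def score_clock_asymmetry(resp: ClockResponse) -> float:
    """Left-minus-right tally of clock-hour omissions and translocations.

    1 point per omitted lateral hour or per translocation crossing the
    vertical midline from its correct side; midline hours (12, 6) score 1
    point when displaced into a lateral half beyond a 30-degree cone centred
    on the correct location (credited to the side the hour moved away from);
    0.5 point per remaining within-side translocation beyond the cone.
    Positive = left-side deficit.
    """
    left = 0.0
    right = 0.0
    for h in resp.omitted:
        if h in LEFT_HOURS:
            left += 1.0
        elif h in RIGHT_HOURS:
            right += 1.0
        # omitted midline hours carry no lateralized information
    for p in resp.placements:
        x = _clock_x(p)
        dev = _angular_deviation(p.angle_deg, _correct_angle(p.label))
        if p.label in MIDLINE_HOURS:
            if dev > CONE_HALF_DEG and x > 0:
                left += 1.0
            elif dev > CONE_HALF_DEG and x < 0:
                right += 1.0
            continue
        own_left = p.label in LEFT_HOURS
        crossed = (x > 0) if own_left else (x < 0)
        if crossed:
            if own_left:
                left += 1.0
            else:
                right += 1.0
        elif dev > CONE_HALF_DEG:
            if own_left:
                left += 0.5
            else:
                right += 0.5
    return left - right


def score_clock_margin(resp: ClockResponse) -> float:
    """Left-minus-right difference of the circumference-to-extreme-hour margins (mm)."""
    left_x = [abs(_clock_x(p)) for p in resp.placements if _clock_x(p) < 0]
    right_x = [abs(_clock_x(p)) for p in resp.placements if _clock_x(p) > 0]
    if not left_x or not right_x:
        raise MissingDataError("clock margin needs at least one hour on each half")
    left_margin = resp.radius_mm - max(left_x)
    right_margin = resp.radius_mm - max(right_x)
    return left_margin - right_margin


def invert_construction(raw: ConstructionScore) -> tuple[int, int]:
    """Convert MoCA points to impairment scores (higher = more impaired)."""
    return 1 - raw.cube_raw, 3 - raw.moca_clock_raw


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def assemble_vector(
    cancellation: CancellationResponse,
    bisection: BisectionResponse,
    clock: ClockResponse,
    construction: ConstructionScore,
    lesion_side: str,
    norm: NormativeParams = NormativeParams(),
    absolute: bool = False,
) -> BehaviorVector:
    """Score all tests and assemble the eight-score vector.

    Signed convention: positive = left-lateralized deficit. The cancellation
    scores are computed contralesionally and remapped onto this page-based
    convention using ``lesion_side``.
    """
    side = _check_side(lesion_side)
    flip = 1.0 if side == "R" else -1.0

    def _component(name, fn):
        try:
            return fn()
        except ScoringError as e:
            raise type(e)(f"{name}: {e}") from e

    ego = _component("apples_ego", lambda: flip * score_egocentric(cancellation, side, norm))
    allo = _component("apples_allo", lambda: flip * score_allocentric(cancellation, side))
    b20 = _component("bisect20", lambda: score_bisection(bisection, 200))
    b5 = _component("bisect5", lambda: score_bisection(bisection, 50))
    asym = _component("clock_asym", lambda: score_clock_asymmetry(clock))
    margin = _component("clock_margin", lambda: score_clock_margin(clock))
    cube, mclock = _component("moca", lambda: invert_construction(construction))

    vals = dict(
        apples_ego=ego,
        apples_allo=allo,
        bisect20=b20,
        bisect5=b5,
        clock_asym=asym,
        clock_margin=margin,
        moca_cube=float(cube),
        moca_clock=float(mclock),
    )
    if absolute:
        vals = {k: abs(v) for k, v in vals.items()}
    return BehaviorVector(signed=not absolute, **vals)


# ---------------------------------------------------------------------------
# I/O: per-patient JSON responses and TSV score tables
# ---------------------------------------------------------------------------


def response_from_dict(doc: Mapping) -> dict:
    """Parse one patient's raw-response JSON document.

    Expected keys: ``cancellation`` (items, page_halfwidth_mm), ``bisection``
    (trials), ``clock`` (radius_mm, placements, omitted), ``construction``
    (cube_raw, moca_clock_raw). All geometry in millimetres.
    """
    canc = doc["cancellation"]
    cancellation = CancellationResponse(
        items=tuple(CancellationItem(**it) for it in canc["items"]),
        page_halfwidth_mm=canc["page_halfwidth_mm"],
    )
    bisection = BisectionResponse(
        trials=tuple(BisectionTrial(**t) for t in doc["bisection"]["trials"])
    )
    clk = doc["clock"]
    clock = ClockResponse(
        radius_mm=clk["radius_mm"],
        placements=tuple(ClockPlacement(**p) for p in clk["placements"]),
        omitted=frozenset(clk.get("omitted", [])),
    )
    construction = ConstructionScore(**doc["construction"])
    return dict(
        cancellation=cancellation, bisection=bisection, clock=clock, construction=construction
    )


def load_responses(path: str | Path) -> dict:
    with open(path) as fh:
        return response_from_dict(json.load(fh))


def score_table(
    responses: Mapping[str, Mapping],
    lesion_sides: Mapping[str, str],
    norm: NormativeParams = NormativeParams(),
    absolute: bool = False,
) -> pd.DataFrame:
    """Score a cohort of parsed responses into the standard score table."""
    rows = []
    for pid, resp in responses.items():
        vec = assemble_vector(
            resp["cancellation"],
            resp["bisection"],
            resp["clock"],
            resp["construction"],
            lesion_sides[pid],
            norm=norm,
            absolute=absolute,
        )
        rows.append({"patient_id": pid, **dict(zip(SCORE_NAMES, vec.as_array()))})
    return pd.DataFrame(rows, columns=["patient_id", *SCORE_NAMES])


def write_score_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_score_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in ("patient_id", *SCORE_NAMES) if c not in table.columns]
    if missing:
        raise ScoringError(f"score table missing columns: {missing}")
    return table
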