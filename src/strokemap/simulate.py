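"""Synthetic cohorts with planted lesion-symptom effects.

Generates everything the pipeline consumes without any external data: a
mirror-symmetric cuboid parcellation with named anatomo-functional roles,
straight-line streamline bundles (including homotopic cross-midline ones),
blob-shaped single-hemisphere lesions grown to a target volume, behavioral
scores that are noisy linear functions of damage to designated parcels or
tracts, and raw test responses that the scoring module maps back onto those
scores.

Defaults emulate the study conditions: a two-phase cohort (about half
acute), roughly 64% right-hemisphere lesions, and a three-way effect
structure (a frontal-like parcel drives the cancellation/long-bisection
scores, a temporoparietal-like parcel the constructional scores, a dorsal
longitudinal tract the clock scores).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .lesion import (
    LesionMap,
    Parcellation,
    Streamline,
    StreamlineSet,
    damage_profile,
    mirror_flip,
)
from .scoring import (
    SCORE_NAMES,
    BisectionResponse,
    BisectionTrial,
    CancellationItem,
    CancellationResponse,
    ClockPlacement,
    ClockResponse,
    ConstructionScore,
    NormativeParams,
    ScoringError,
)

__all__ = [
    "Effect",
    "SimulationConfig",
    "Cohort",
    "default_affine",
    "make_atlas",
    "sample_lesion",
    "generate_scores",
    "generate_raw_responses",
    "simulate_cohort",
    "SCORE_SCALE",
]


class SimulationError(ValueError):
    pass


#: per-score unit scale: converts the dimensionless effect/noise structure into
#: each test's native units (z units, points, millimetres) while keeping every
#: score inside the range a raw response can represent
SCORE_SCALE = {
    "apples_ego": 1.0,
    "apples_allo": 0.15,
    "bisect20": 20.0,
    "bisect5": 5.0,
    "clock_asym": 1.0,
    "clock_margin": 8.0,
    "moca_cube": 0.3,
    "moca_clock": 0.8,
}


@dataclass(frozen=True)
class Effect:
    """One planted linear effect: score += weight * scale * damage_pct / 100."""

    source_level: Literal["parcel", "tract", "edge"]
    source: object  # parcel name/id, tract name, or (a, b) parcel pair
    score: str
    weight: float

    def __post_init__(self):
        if self.score not in SCORE_NAMES:
            raise SimulationError(f"unknown score {self.score!r}")


DEFAULT_EFFECTS = (
    Effect("parcel", "R_frontal_mid_midsup", "apples_ego", 2.0),
    Effect("parcel", "R_frontal_mid_midsup", "apples_allo", 2.0),
    Effect("parcel", "R_frontal_mid_midsup", "bisect20", 2.0),
    Effect("parcel", "R_temporoparietal_mid_midinf", "moca_cube", 2.0),
    Effect("parcel", "R_temporoparietal_mid_midinf", "moca_clock", 2.0),
    Effect("parcel", "R_temporoparietal_mid_midinf", "bisect5", 2.0),
    Effect("tract", "R_dorsal_longitudinal", "clock_asym", 2.0),
    Effect("tract", "R_dorsal_longitudinal", "clock_margin", 2.0),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generation conditions.

    Defaults mirror the study population: 77 patients, 40 acute and 37
    chronic, 49 right- and 28 left-hemisphere lesions; lesion volumes are
    log-uniform over 16-96 cm^3 on the 2 mm grid, the right-skewed range
    typical of the large middle-cerebral-artery strokes that produce
    visuospatial deficits.
    """

    shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size_mm: float = 2.0
    n_patients: int = 77
    acute_fraction: float = 40 / 77
    right_fraction: float = 49 / 77
    volume_range_vox: tuple[int, int] = (2000, 12000)
    effects: tuple[Effect, ...] = DEFAULT_EFFECTS
    noise_sd: float = 0.5
    noise: Literal["gaussian", "laplace"] = "gaussian"
    coc_norm: tuple[float, float] = (0.0, 0.2)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.acute_fraction <= 1 or not 0 <= self.right_fraction <= 1:
            raise SimulationError("phase/side fractions must lie in [0, 1]")
        if self.volume_range_vox[0] < 1 or self.volume_range_vox[0] > self.volume_range_vox[1]:
            raise SimulationError("invalid lesion volume range")


@dataclass
class Cohort:
    config: SimulationConfig
    parcellation: Parcellation
    streamlines: StreamlineSet
    lesions: list[LesionMap]  # as drawn (left lesions unflipped)
    demographics: pd.DataFrame
    scores: pd.DataFrame
    truth: dict


def default_affine(shape: Sequence[int], voxel_size_mm: float = 2.0) -> np.ndarray:
    """Axis-aligned affine with the grid centred on the world origin.

    Voxel centres are symmetric about every world axis, so the midsagittal
    plane x = 0 falls between the two hemispheres and mirror flipping is an
    exact voxel permutation.
    """
    aff = np.eye(4)
    for ax in range(3):
        aff[ax, ax] = voxel_size_mm
        aff[ax, 3] = -voxel_size_mm * (shape[ax] - 1) / 2.0
    return aff


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

_BANDS = (
    "occipital",
    "temporooccipital",
    "temporoparietal",
    "central",
    "frontal",
)  # posterior -> anterior (y)
_HEIGHTS = ("inf", "midinf", "midsup", "sup")  # z
_DEPTHS = ("medial", "mid", "lateral")  # |x| from the midline outwards


def make_atlas(
    shape: Sequence[int] = (40, 48, 40), voxel_size_mm: float = 2.0
) -> tuple[Parcellation, StreamlineSet]:
    """Mirror-symmetric cuboid parcellation plus straight streamline bundles.

    Sixty parcels per hemisphere (5 anteroposterior bands x 4 heights x 3
    depths, about 3 cm^3 each on the default grid, comparable to the
    granularity of connectome-style atlases); bundles of 8 parallel
    streamlines connect frontal to temporoparietal parcels within each
    hemisphere (dorsal and ventral longitudinal tracts) and homotopic
    parcels across the midline (callosal-like bundles).
    """
    nx, ny, nz = shape
    if nx < 26 or ny < 38 or nz < 28:
        raise SimulationError(f"grid {shape} too small for the synthetic atlas")
    affine = default_affine(shape, voxel_size_mm)
    labels = np.zeros(shape, dtype=np.int32)

    half = nx // 2
    right_x = (half, nx - 3)  # inclusive bounds, outer margin of 2
    my, mz = 4, 4
    y0, y1 = my, ny - my - 1
    z0, z1 = mz, nz - mz - 1
    y_edges = np.linspace(y0, y1 + 1, len(_BANDS) + 1).astype(int)
    z_edges = np.linspace(z0, z1 + 1, len(_HEIGHTS) + 1).astype(int)
    x_edges = np.linspace(right_x[0], right_x[1] + 1, len(_DEPTHS) + 1).astype(int)
    x_slabs = {d: (x_edges[i], x_edges[i + 1] - 1) for i, d in enumerate(_DEPTHS)}

    lookup: dict[int, dict] = {}
    pid = 0
    right_boxes = {}
    for bi, band in enumerate(_BANDS):
        for di, depth in enumerate(_DEPTHS):
            for hi, height in enumerate(_HEIGHTS):
                pid += 1
                xs = x_slabs[depth]
                box = (xs, (y_edges[bi], y_edges[bi + 1] - 1), (z_edges[hi], z_edges[hi + 1] - 1))
                right_boxes[f"{band}_{depth}_{height}"] = (pid, box)
                labels[xs[0] : xs[1] + 1, box[1][0] : box[1][1] + 1, box[2][0] : box[2][1] + 1] = pid
                lookup[pid] = {"name": f"R_{band}_{depth}_{height}", "hemisphere": "R"}
    n_right = pid
    for key, (rpid, box) in right_boxes.items():
        pid = rpid + n_right
        (xa, xb), yr, zr = box
        # mirror voxel i -> nx - 1 - i
        xs = (nx - 1 - xb, nx - 1 - xa)
        labels[xs[0] : xs[1] + 1, yr[0] : yr[1] + 1, zr[0] : zr[1] + 1] = pid
        lookup[pid] = {"name": f"L_{key}", "hemisphere": "L"}

    parc = Parcellation(labels=labels, affine=affine, lookup=lookup)
    name_to_id = {v["name"]: k for k, v in lookup.items()}

    def _centre(pid_: int) -> np.ndarray:
        return np.mean(np.argwhere(labels == pid_), axis=0)

    def _bundle(tract: str, name_a: str, name_b: str) -> list[Streamline]:
        ia, ib = name_to_id[name_a], name_to_id[name_b]
        a, b = sorted((ia, ib))
        ca, cb = _centre(ia), _centre(ib)
        offsets = [(0, 0), (2, 0), (-2, 0), (0, 2), (0, -2), (2, 2), (-2, -2), (-2, 2)]
        out = []
        for oj, ok in offsets:
            p0 = ca + np.array([0, oj, ok])
            p1 = cb + np.array([0, oj, ok])
            n = int(np.abs(p1 - p0).max()) * 2 + 2
            pts = np.rint(np.linspace(p0, p1, n)).astype(int)
            path = [tuple(int(v) for v in pts[0])]
            for pt in pts[1:]:
                tpt = tuple(int(v) for v in pt)
                if tpt != path[-1]:
                    path.append(tpt)
            out.append(
                Streamline(tract=tract, parcel_a=int(a), parcel_b=int(b), path=tuple(path))
            )
        return out

    streamlines: list[Streamline] = []
    for hemi in ("R", "L"):
        streamlines += _bundle(
            f"{hemi}_dorsal_longitudinal",
            f"{hemi}_frontal_lateral_sup",
            f"{hemi}_temporoparietal_lateral_sup",
        )
        streamlines += _bundle(
            f"{hemi}_ventral_longitudinal",
            f"{hemi}_temporoparietal_lateral_inf",
            f"{hemi}_occipital_lateral_inf",
        )
    streamlines += _bundle("callosal_frontal", "R_frontal_medial_sup", "L_frontal_medial_sup")
    streamlines += _bundle(
        "callosal_parietal", "R_temporoparietal_medial_sup", "L_temporoparietal_medial_sup"
    )
    streams = StreamlineSet(streamlines=tuple(streamlines))
    streams.validate(parc)
    return parc, streams


# ---------------------------------------------------------------------------
# lesions
# ---------------------------------------------------------------------------


def sample_lesion(
    shape: Sequence[int],
    affine: np.ndarray,
    side: str,
    n_voxels: int,
    rng: np.random.Generator,
    patient_id: str = "",
    max_retries: int = 5,
) -> LesionMap:
    """Region-grown random blob of exactly ``n_voxels``, confined to one hemisphere.

    Starting from a random seed voxel, growth repeatedly adds a random
    subset of the blob's 26-connected frontier, which yields a single
    connected, roughly convex component of exactly the target size.
    Hemisphere membership is evaluated in world coordinates (x > 0 = right).
    """
    from scipy import ndimage

    nx = shape[0]
    xs = affine[0, 0] * np.arange(nx) + affine[0, 3]
    allowed_i = np.flatnonzero(xs > 0) if side == "R" else np.flatnonzero(xs < 0)
    if allowed_i.size == 0:
        raise SimulationError(f"no voxel column on side {side}")
    if n_voxels > allowed_i.size * shape[1] * shape[2]:
        raise SimulationError("target lesion volume exceeds the hemisphere")
    hemi = np.zeros(shape, dtype=bool)
    hemi[allowed_i] = True
    structure = ndimage.generate_binary_structure(3, 3)
    for _ in range(max_retries):
        blob = np.zeros(shape, dtype=bool)
        seed_vox = (
            int(rng.choice(allowed_i)),
            int(rng.integers(2, shape[1] - 2)),
            int(rng.integers(2, shape[2] - 2)),
        )
        blob[seed_vox] = True
        size = 1
        while size < n_voxels:
            frontier = ndimage.binary_dilation(blob, structure) & ~blob & hemi
            cand = np.argwhere(frontier)
            if cand.size == 0:
                break
            need = n_voxels - size
            # accept roughly half the frontier per round for irregular edges
            k = min(need, max(1, cand.shape[0] // 2))
            pick = cand[rng.choice(cand.shape[0], size=k, replace=False)]
            blob[tuple(pick.T)] = True
            size += k
        if size == n_voxels:
            return LesionMap(
                grid=blob, affine=affine, patient_id=patient_id, lesion_side=side
            )
    raise SimulationError("lesion growth failed to reach the target volume")


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------


def _resolve_parcel(source, parc: Parcellation) -> int:
    if isinstance(source, str):
        for pid, info in parc.lookup.items():
            if info["name"] == source:
                return pid
        raise SimulationError(f"unknown parcel {source!r}")
    if int(source) not in parc.lookup:
        raise SimulationError(f"unknown parcel id {source}")
    return int(source)


def generate_scores(
    lesions: Sequence[LesionMap],
    parc: Parcellation,
    streams: StreamlineSet,
    effects: Sequence[Effect] = DEFAULT_EFFECTS,
    noise_sd: float = 0.5,
    rng: np.random.Generator | None = None,
    noise: str = "gaussian",
) -> tuple[pd.DataFrame, dict]:
    """Behavioral scores as noisy linear functions of planted damage.

    Left-hemisphere lesions are mirror-flipped before damage is computed,
    matching the analysis pipeline. Each effect contributes
    ``weight * SCORE_SCALE[score] * damage_pct / 100``; every score also
    receives ``SCORE_SCALE[score] * noise_sd`` noise (Gaussian by default,
    Laplace behind the flag for robustness checks).
    """
    rng = np.random.default_rng() if rng is None else rng
    profiles = []
    for les in lesions:
        flipped = mirror_flip(les) if les.lesion_side == "L" else les
        profiles.append(damage_profile(flipped, parc, streams))

    n = len(lesions)
    mat = np.zeros((n, len(SCORE_NAMES)))
    truth: dict[str, set] = {"parcel": set(), "tract": set(), "edge": set()}
    for eff in effects:
        col = SCORE_NAMES.index(eff.score)
        scale = SCORE_SCALE[eff.score]
        if eff.source_level == "parcel":
            pid = _resolve_parcel(eff.source, parc)
            dmg = np.array([p.parcel_damage_pct.loc[pid] for p in profiles])
            truth["parcel"].add(pid)
        elif eff.source_level == "tract":
            if eff.source not in streams.tracts:
                raise SimulationError(f"unknown tract {eff.source!r}")
            dmg = np.array([p.tract_disconnection_pct.loc[eff.source] for p in profiles])
            truth["tract"].add(eff.source)
        elif eff.source_level == "edge":
            a, b = sorted(int(v) for v in eff.source)
            if (a, b) not in streams.pairs:
                raise SimulationError(f"no streamlines connect parcels {(a, b)}")
            dmg = np.array([p.edge_disconnection_pct.loc[a, b] for p in profiles])
            truth["edge"].add((a, b))
        else:
            raise SimulationError(f"unknown effect level {eff.source_level!r}")
        mat[:, col] += eff.weight * scale * dmg / 100.0
    scales = np.array([SCORE_SCALE[s] for s in SCORE_NAMES])
    if noise_sd > 0:
        if noise == "gaussian":
            eps = rng.standard_normal((n, len(SCORE_NAMES)))
        elif noise == "laplace":
            eps = rng.laplace(0.0, 1.0 / math.sqrt(2.0), (n, len(SCORE_NAMES)))
        else:
            raise SimulationError(f"unknown noise family {noise!r}")
        mat += noise_sd * eps * scales[None, :]
    scores = pd.DataFrame(mat, columns=list(SCORE_NAMES))
    scores.insert(0, "patient_id", [les.patient_id or f"p{i:03d}" for i, les in enumerate(lesions)])
    truth_out = {
        "parcel": sorted(truth["parcel"]),
        "tract": sorted(truth["tract"]),
        "edge": sorted(truth["edge"]),
        "effects": [
            {"level": e.source_level, "source": e.source, "score": e.score, "weight": e.weight}
            for e in effects
        ],
    }
    return scores, truth_out


# ---------------------------------------------------------------------------
# raw responses (inverse of the scoring module)
# ---------------------------------------------------------------------------

_CLOCK_RADIUS = 80.0
_CLOCK_EXTREME_RADIAL = 60.0  # hours 3 and 9 anchor the lateral extremes
_CLOCK_OTHER_RADIAL = 22.0
_MARGIN_LIMIT = 38.0
_N_TARGETS = 50
_N_DISTRACTORS = 50  # per opening side
_PAGE_HALFWIDTH = 150.0


def _quantize_half(x: float) -> float:
    return round(2.0 * x) / 2.0


def generate_raw_responses(
    target: dict | pd.Series,
    lesion_side: str,
    norm: NormativeParams = NormativeParams(0.0, 0.2),
    rng: np.random.Generator | None = None,
) -> dict:
    """Construct raw test responses whose scores reproduce ``target``.

    ``target`` maps score names to signed values (positive = left-lateralized
    deficit). Continuous scores are reproduced within +-0.02 in their native
    units; discrete scores (allocentric numerator, clock-asymmetry
    half-points, MoCA points) are quantized to the nearest representable
    value and reproduced exactly. Raises when a value lies outside the range
    the test geometry can represent.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    t = {k: float(target[k]) for k in SCORE_NAMES}

    # -- cancellation ------------------------------------------------------
    raw_coc = t["apples_ego"] * norm.coc_sd + norm.coc_mean
    if abs(raw_coc) > 0.95:
        raise ScoringError(f"apples_ego: raw CoC {raw_coc:.3f} outside the page")
    c_mm = raw_coc * _PAGE_HALFWIDTH
    spread = min(20.0, _PAGE_HALFWIDTH - abs(c_mm) - 1.0)
    items = []
    for i in range(_N_TARGETS):
        dx = spread if i % 2 == 0 else -spread
        items.append(
            CancellationItem(
                x_mm=c_mm + dx, y_mm=-100.0 + (i % 10) * 20.0, category="full_target", marked=True
            )
        )
    d = int(round(t["apples_allo"] * _N_TARGETS))
    if abs(d) > _N_DISTRACTORS:
        raise ScoringError("apples_allo: more errors than available distractors")
    n_left_marked = max(d, 0)
    n_right_marked = max(-d, 0)
    for i in range(_N_DISTRACTORS):
        y = -100.0 + (i % 10) * 20.0 + float(rng.uniform(-2, 2))
        items.append(
            CancellationItem(
                x_mm=-120.0 + (i % 25) * 9.0, y_mm=y, category="left_open",
                marked=i < n_left_marked,
            )
        )
        items.append(
            CancellationItem(
                x_mm=120.0 - (i % 25) * 9.0, y_mm=y, category="right_open",
                marked=i < n_right_marked,
            )
        )
    cancellation = CancellationResponse(items=tuple(items), page_halfwidth_mm=_PAGE_HALFWIDTH)

    # -- bisection ---------------------------------------------------------
    if abs(t["bisect20"]) > 95 or abs(t["bisect5"]) > 23:
        raise ScoringError("bisection: deviation larger than the line allows")
    bisection = BisectionResponse(
        trials=(
            BisectionTrial(200.0, t["bisect20"]),
            BisectionTrial(200.0, t["bisect20"]),
            BisectionTrial(50.0, t["bisect5"]),
            BisectionTrial(50.0, t["bisect5"]),
        )
    )

    # -- clock -------------------------------------------------------------
    asym = _quantize_half(t["clock_asym"])
    if abs(asym) > 4.0:
        raise ScoringError(f"clock_asym: tally {asym} not representable")
    margin = t["clock_margin"]
    if abs(margin) > _MARGIN_LIMIT:
        raise ScoringError(f"clock_margin: {margin:.1f} mm outside the dial")
    deficit_hours = {"L": [11, 10, 8, 7], "R": [1, 2, 4, 5]}
    side_of_deficit = "L" if asym > 0 else "R"
    n_omit = int(abs(asym))
    half_point = abs(asym) - n_omit > 0
    omitted = set(deficit_hours[side_of_deficit][:n_omit]) if asym != 0 else set()
    translocated = None
    if half_point:
        translocated = next(h for h in deficit_hours[side_of_deficit] if h not in omitted)
    placements = []
    for h in range(1, 13):
        if h in omitted:
            continue
        angle = (h % 12) * 30.0
        if h == 9:
            radial = _CLOCK_EXTREME_RADIAL - max(margin, 0.0)
        elif h == 3:
            radial = _CLOCK_EXTREME_RADIAL - max(-margin, 0.0)
        else:
            radial = _CLOCK_OTHER_RADIAL
        if h == translocated:
            # within-side translocation beyond the 30-degree cone
            angle += 40.0 if h in (7, 8, 1, 2) else -40.0
        placements.append(ClockPlacement(label=h, angle_deg=angle % 360.0, radial_mm=radial))
    clock = ClockResponse(
        radius_mm=_CLOCK_RADIUS, placements=tuple(placements), omitted=frozenset(omitted)
    )

    # -- construction ------------------------------------------------------
    cube_imp = int(np.clip(round(t["moca_cube"]), 0, 1))
    clock_imp = int(np.clip(round(t["moca_clock"]), 0, 3))
    construction = ConstructionScore(cube_raw=1 - cube_imp, moca_clock_raw=3 - clock_imp)

    return dict(
        cancellation=cancellation, bisection=bisection, clock=clock, construction=construction
    )


def response_to_dict(resp: dict) -> dict:
    """JSON-serializable form of a parsed response set."""
    return {
        "cancellation": {
            "page_halfwidth_mm": resp["cancellation"].page_halfwidth_mm,
            "items": [
                {"x_mm": it.x_mm, "y_mm": it.y_mm, "category": it.category, "marked": it.marked}
                for it in resp["cancellation"].items
            ],
        },
        "bisection": {
            "trials": [
                {"line_length_mm": t.line_length_mm, "mark_offset_mm": t.mark_offset_mm}
                for t in resp["bisection"].trials
            ]
        },
        "clock": {
            "radius_mm": resp["clock"].radius_mm,
            "placements": [
                {"label": p.label, "angle_deg": p.angle_deg, "radial_mm": p.radial_mm}
                for p in resp["clock"].placements
            ],
            "omitted": sorted(resp["clock"].omitted),
        },
        "construction": {
            "cube_raw": resp["construction"].cube_raw,
            "moca_clock_raw": resp["construction"].moca_clock_raw,
        },
    }


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimulationConfig = SimulationConfig()) -> Cohort:
    """Deterministic end-to-end cohort: atlas, lesions, demographics, scores."""
    rng = np.random.default_rng(config.seed)
    parc, streams = make_atlas(config.shape, config.voxel_size_mm)
    affine = parc.affine
    n = config.n_patients
    n_acute = int(round(config.acute_fraction * n))
    n_right = int(round(config.right_fraction * n))
    phases = np.array(["acute"] * n_acute + ["chronic"] * (n - n_acute))
    sides = np.array(["R"] * n_right + ["L"] * (n - n_right))
    rng.shuffle(phases)
    rng.shuffle(sides)

    lesions = []
    rows = []
    lo, hi = config.volume_range_vox
    for i in range(n):
        pid = f"p{i:03d}"
        # log-uniform: lesion volumes are right-skewed in stroke cohorts
        vol = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        lesions.append(
            sample_lesion(config.shape, affine, sides[i], vol, rng, patient_id=pid)
        )
        days = int(rng.integers(1, 21)) if phases[i] == "acute" else int(rng.integers(90, 400))
        rows.append(
            {
                "patient_id": pid,
                "phase": phases[i],
                "lesion_side": sides[i],
                "age": float(np.clip(rng.normal(63.0, 12.0), 30, 90).round(1)),
                "gender": "F" if rng.random() < 0.3 else "M",
                "days_post_stroke": days,
                "target_volume_vox": vol,
            }
        )
    demographics = pd.DataFrame(rows)
    scores, truth = generate_scores(
        lesions, parc, streams, config.effects, config.noise_sd, rng, config.noise
    )
    return Cohort(
        config=config,
        parcellation=parc,
        streamlines=streams,
        lesions=lesions,
        demographics=demographics,
        scores=scores,
        truth=truth,
    )
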