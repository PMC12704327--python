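"""Lesion and disconnection quantification.

Loads binary lesion masks in a common stereotaxic space, mirror-flips
left-hemisphere lesions across the midsagittal plane (world x = 0, positive
x = right hemisphere), and summarizes each lesion at four granularities:
lesioned voxels, percent damage per grey-matter parcel, percent
disconnection per white-matter tract, and percent disconnection per
parcel pair (edge). A streamline is counted as disconnected as soon as any
voxel on its path is lesioned.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "LesionMap",
    "Parcellation",
    "Streamline",
    "StreamlineSet",
    "DamageProfile",
    "CoverageMask",
    "load_lesion",
    "save_map",
    "mirror_flip",
    "lesion_volume",
    "coverage_mask",
    "parcel_damage",
    "tract_disconnection",
    "edge_disconnection",
    "edge_count",
    "damage_profile",
    "load_parcellation",
    "save_parcellation",
    "load_streamlines",
    "save_streamlines",
]


class LesionFormatError(ValueError):
    pass


@dataclass
class LesionMap:
    grid: np.ndarray  # 3D boolean
    affine: np.ndarray  # 4x4 voxel-to-world (mm)
    patient_id: str = ""
    lesion_side: str = ""  # "L", "R" or "R-flipped"
    space: str = "MNI-like"

    def __post_init__(self):
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 3:
            raise LesionFormatError("lesion grid must be 3D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or np.linalg.det(self.affine[:3, :3]) == 0:
            raise LesionFormatError("affine must be an invertible 4x4 transform")

    @property
    def n_lesioned(self) -> int:
        return int(self.grid.sum())


@dataclass
class Parcellation:
    labels: np.ndarray  # 3D integer, 0 = background
    affine: np.ndarray
    lookup: dict[int, dict]  # id -> {"name": ..., "hemisphere": ...}

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.lookup)
        if missing:
            raise LesionFormatError(f"labels missing from lookup: {sorted(missing)}")
        empty = [pid for pid in self.lookup if pid not in present]
        if empty:
            raise LesionFormatError(f"lookup parcels with no voxels: {empty}")

    @property
    def ids(self) -> list[int]:
        return sorted(self.lookup)


@dataclass(frozen=True)
class Streamline:
    tract: str
    parcel_a: int
    parcel_b: int
    path: tuple[tuple[int, int, int], ...]  # ordered voxel indices

    def __post_init__(self):
        if self.parcel_a >= self.parcel_b:
            raise LesionFormatError("endpoint parcels must satisfy a < b")
        if len(self.path) == 0:
            raise LesionFormatError("empty streamline path")


@dataclass
class StreamlineSet:
    streamlines: tuple[Streamline, ...]

    def __post_init__(self):
        self.streamlines = tuple(self.streamlines)

    def validate(self, parc: Parcellation) -> None:
        shape = parc.labels.shape
        ids = set(parc.lookup)
        for s in self.streamlines:
            if s.parcel_a not in ids or s.parcel_b not in ids:
                raise LesionFormatError(f"streamline endpoints not in parcellation: {s.tract}")
            arr = np.asarray(s.path)
            if np.any(arr < 0) or np.any(arr >= np.array(shape)):
                raise LesionFormatError(f"streamline path out of grid bounds: {s.tract}")

    @property
    def tracts(self) -> list[str]:
        return sorted({s.tract for s in self.streamlines})

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return sorted({(s.parcel_a, s.parcel_b) for s in self.streamlines})


@dataclass
class DamageProfile:
    patient_id: str
    lesion_volume_mm3: float
    parcel_damage_pct: pd.Series  # index: parcel id
    tract_disconnection_pct: pd.Series  # index: tract name
    edge_disconnection_pct: pd.DataFrame  # symmetric parcel x parcel


@dataclass
class CoverageMask:
    included: np.ndarray  # boolean over features
    n_patients: int
    min_fraction: float
    feature_ids: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# lesion maps
# ---------------------------------------------------------------------------


def load_lesion(path: str | Path, patient_id: str = "", lesion_side: str = "") -> LesionMap:
    """Load a NIfTI lesion volume, binarizing at > 0.5."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise LesionFormatError(f"expected a 3D volume, got shape {data.shape}")
    grid = data > 0.5
    if not grid.any():
        warnings.warn(f"empty lesion in {path}", stacklevel=2)
    return LesionMap(grid=grid, affine=img.affine, patient_id=patient_id, lesion_side=lesion_side)


def save_map(lesion: LesionMap, path: str | Path) -> None:
    img = nib.Nifti1Image(lesion.grid.astype(np.uint8), lesion.affine)
    nib.save(img, str(path))


def mirror_flip(lesion: LesionMap) -> LesionMap:
    """Reflect the lesion through the world midsagittal plane x = 0.

    Nearest-neighbour mapping onto the same grid; requires the world x axis
    to couple to a single voxel axis (no shear across x), which keeps binary
    maps and voxel counts exact.
    """
    M = lesion.affine[:3, :3]
    x_row = M[0]
    if np.count_nonzero(x_row) != 1:
        raise LesionFormatError("affine shears across x; mirror flip unsupported")
    ijk = np.argwhere(lesion.grid)
    flipped = np.zeros_like(lesion.grid)
    if ijk.size:
        world = ijk @ M.T + lesion.affine[:3, 3]
        world[:, 0] *= -1
        inv = np.linalg.inv(lesion.affine)
        back = world @ inv[:3, :3].T + inv[:3, 3]
        back = np.rint(back).astype(int)
        if np.any(back < 0) or np.any(back >= np.array(lesion.grid.shape)):
            raise LesionFormatError("reflected lesion falls outside the grid")
        flipped[tuple(back.T)] = True
        if flipped.sum() != lesion.n_lesioned:
            raise LesionFormatError("mirror flip was not volume-preserving on this grid")
    side = {"L": "R-flipped", "R-flipped": "L"}.get(lesion.lesion_side, lesion.lesion_side)
    return replace(lesion, grid=flipped, lesion_side=side)


def lesion_volume(lesion: LesionMap) -> float:
    """Lesion volume in mm^3 (voxel count times voxel volume)."""
    return float(lesion.n_lesioned * abs(np.linalg.det(lesion.affine[:3, :3])))


# ---------------------------------------------------------------------------
# coverage and damage summaries
# ---------------------------------------------------------------------------


def coverage_mask(values, min_fraction: float = 0.10, feature_ids=None) -> CoverageMask:
    """Features damaged (> 0) in at least ``min_fraction`` of patients.

    ``values`` is an n_patients x n_features array (binary voxels or percent
    damage alike). The boundary is inclusive: the study excludes features
    present in < 10% of participants, so exactly 10% is retained.
    """
    if not 0 < min_fraction < 1:
        raise ValueError("min_fraction must lie in (0, 1)")
    arr = np.asarray(values)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("values must be n_patients x n_features with >= 1 patient")
    frac = np.mean(arr > 0, axis=0)
    included = frac >= min_fraction
    return CoverageMask(
        included=included,
        n_patients=arr.shape[0],
        min_fraction=min_fraction,
        feature_ids=list(feature_ids) if feature_ids is not None else list(range(arr.shape[1])),
    )


def _check_grids(a_shape, b_shape, what: str) -> None:
    if tuple(a_shape) != tuple(b_shape):
        raise LesionFormatError(f"grid mismatch between lesion and {what}")


def parcel_damage(lesion: LesionMap, parc: Parcellation) -> pd.Series:
    """Percent of each parcel's voxels that are lesioned."""
    _check_grids(lesion.grid.shape, parc.labels.shape, "parcellation")
    n_bins = max(parc.ids) + 1
    sizes = np.bincount(parc.labels.ravel(), minlength=n_bins)
    hit = np.bincount(parc.labels.ravel(), weights=lesion.grid.ravel(), minlength=n_bins)
    ids = parc.ids
    pct = 100.0 * hit[ids] / sizes[ids]
    return pd.Series(pct, index=pd.Index(ids, name="parcel_id"), name="damage_pct")


def _hit_streamline(lesion_grid: np.ndarray, s: Streamline) -> bool:
    arr = np.asarray(s.path)
    return bool(lesion_grid[arr[:, 0], arr[:, 1], arr[:, 2]].any())


def tract_disconnection(lesion: LesionMap, streams: StreamlineSet) -> pd.Series:
    """Percent of each tract's streamlines interrupted by the lesion."""
    totals: dict[str, int] = {}
    hits: dict[str, int] = {}
    for s in streams.streamlines:
        totals[s.tract] = totals.get(s.tract, 0) + 1
        if _hit_streamline(lesion.grid, s):
            hits[s.tract] = hits.get(s.tract, 0) + 1
    tracts = sorted(totals)
    pct = [100.0 * hits.get(t, 0) / totals[t] for t in tracts]
    return pd.Series(pct, index=pd.Index(tracts, name="tract"), name="disconnection_pct")


def edge_disconnection(
    lesion: LesionMap, streams: StreamlineSet, parc: Parcellation
) -> pd.DataFrame:
    """Symmetric parcel x parcel percent-disconnection matrix.

    Parcel pairs with no connecting streamlines are structural zeros.
    """
    _check_grids(lesion.grid.shape, parc.labels.shape, "parcellation")
    streams.validate(parc)
    ids = parc.ids
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    totals: dict[tuple[int, int], int] = {}
    hits: dict[tuple[int, int], int] = {}
    for s in streams.streamlines:
        key = (s.parcel_a, s.parcel_b)
        totals[key] = totals.get(key, 0) + 1
        if _hit_streamline(lesion.grid, s):
            hits[key] = hits.get(key, 0) + 1
    for (a, b), tot in totals.items():
        pct = 100.0 * hits.get((a, b), 0) / tot
        mat.loc[a, b] = pct
        mat.loc[b, a] = pct
    return mat


def edge_count(n_nodes: int) -> int:
    """Number of undirected edges among n nodes: n(n-1)/2."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    return n_nodes * (n_nodes - 1) // 2


def damage_profile(
    lesion: LesionMap, parc: Parcellation, streams: StreamlineSet
) -> DamageProfile:
    return DamageProfile(
        patient_id=lesion.patient_id,
        lesion_volume_mm3=lesion_volume(lesion),
        parcel_damage_pct=parcel_damage(lesion, parc),
        tract_disconnection_pct=tract_disconnection(lesion, streams),
        edge_disconnection_pct=edge_disconnection(lesion, streams, parc),
    )


# ---------------------------------------------------------------------------
# parcellation / streamline I/O
# ---------------------------------------------------------------------------


def load_parcellation(nifti_path: str | Path, lookup_tsv: str | Path) -> Parcellation:
    img = nib.load(str(nifti_path))
    labels = np.asanyarray(img.dataobj).astype(int)
    table = pd.read_csv(lookup_tsv, sep="\t")
    lookup = {
        int(row["id"]): {"name": row["name"], "hemisphere": row["hemisphere"]}
        for _, row in table.iterrows()
    }
    return Parcellation(labels=labels, affine=img.affine, lookup=lookup)


def save_parcellation(parc: Parcellation, nifti_path: str | Path, lookup_tsv: str | Path) -> None:
    nib.save(nib.Nifti1Image(parc.labels.astype(np.int32), parc.affine), str(nifti_path))
    rows = [
        {"id": pid, "name": info["name"], "hemisphere": info["hemisphere"]}
        for pid, info in sorted(parc.lookup.items())
    ]
    pd.DataFrame(rows).to_csv(lookup_tsv, sep="\t", index=False)


def load_streamlines(path: str | Path) -> StreamlineSet:
    """Streamlines as a JSON list of {tract, parcel_a, parcel_b, path}.

    A TRK/TCK tractogram would map onto this structure by converting each
    streamline's mm coordinates to voxel indices under the reference affine
    and annotating endpoint parcels from the parcellation; that converter is
    intentionally not implemented here.
    """
    with open(path) as fh:
        docs = json.load(fh)
    streamlines = tuple(
        Streamline(
            tract=d["tract"],
            parcel_a=int(d["parcel_a"]),
            parcel_b=int(d["parcel_b"]),
            path=tuple(tuple(int(v) for v in p) for p in d["path"]),
        )
        for d in docs
    )
    return StreamlineSet(streamlines=streamlines)


def save_streamlines(streams: StreamlineSet, path: str | Path) -> None:
    docs = [
        {
            "tract": s.tract,
            "parcel_a": s.parcel_a,
            "parcel_b": s.parcel_b,
            "path": [list(p) for p in s.path],
        }
        for s in streams.streamlines
    ]
    with open(path, "w") as fh:
        json.dump(docs, fh)


def profiles_to_tables(profiles: Sequence[DamageProfile]) -> dict[str, pd.DataFrame]:
    """Stack per-patient profiles into cohort TSV-ready tables.

    Returns ``volume`` (patient_id, lesion_volume_mm3), ``parcel`` and
    ``tract`` wide tables, and the ``edge`` long format
    (patient_id, parcel_a, parcel_b, pct) restricted to connected pairs.
    """
    vol = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in profiles],
            "lesion_volume_mm3": [p.lesion_volume_mm3 for p in profiles],
        }
    )
    parcel = pd.DataFrame(
        [p.parcel_damage_pct for p in profiles],
        index=[p.patient_id for p in profiles],
    )
    parcel.index.name = "patient_id"
    tract = pd.DataFrame(
        [p.tract_disconnection_pct for p in profiles],
        index=[p.patient_id for p in profiles],
    )
    tract.index.name = "patient_id"
    edge_rows = []
    for p in profiles:
        mat = p.edge_disconnection_pct
        ids = list(mat.index)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                edge_rows.append(
                    {"patient_id": p.patient_id, "parcel_a": a, "parcel_b": b,
                     "pct": mat.loc[a, b]}
                )
    return {
        "volume": vol,
        "parcel": parcel.reset_index(),
        "tract": tract.reset_index(),
        "edge": pd.DataFrame(edge_rows),
    }
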