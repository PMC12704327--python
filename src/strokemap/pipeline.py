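"""End-to-end orchestration: score -> factors -> quantify -> map -> report.

`run_full` executes the whole analysis on either a simulated cohort or
user-supplied files, writing a fixed output layout::

    out/
      scores/scores.tsv
      factors/factor_report.json, component_scores.tsv
      damage/volume.tsv, parcel.tsv, tract.tsv, edge.tsv
      lsm/<level>/<component>.tsv (+ clusters.tsv at voxel level)
      report.json

All randomness flows from one master seed, split deterministically per
stage. Subgroup analyses (acute/chronic, right/left) are row filters over
the same pipeline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import factors as fm
from . import lesion as lq
from . import scoring, stats
from .simulate import Cohort, SimulationConfig, simulate_cohort
from .svr import SVRConfig, run_lsm, svrmap_to_table

__all__ = ["RunConfig", "run_full", "compare_groups", "write_cohort"]


@dataclass
class RunConfig:
    output_dir: str = "strokemap_out"
    simulation: SimulationConfig | None = None
    # file-based inputs (used when simulation is None)
    scores_tsv: str | None = None
    responses_dir: str | None = None
    demographics_tsv: str | None = None
    lesions_dir: str | None = None
    atlas_nifti: str | None = None
    atlas_lookup: str | None = None
    streamlines_json: str | None = None
    # analysis toggles
    absolute_scores: bool = True
    flip_left: bool = True
    subgroup: str | None = None  # None | acute | chronic | right | left
    levels: tuple[str, ...] = ("parcel", "tract", "edge")
    n_components: int | None = None
    coc_norm: tuple[float, float] = (0.0, 1.0)
    svr: SVRConfig = field(default_factory=SVRConfig)
    seed: int = 0

    def config_hash(self) -> str:
        doc = json.dumps(_as_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _load_inputs(config: RunConfig):
    """Return (scores, demographics, lesions, parcellation, streamlines)."""
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        cohort = simulate_cohort(sim)
        return (
            cohort.scores,
            cohort.demographics,
            cohort.lesions,
            cohort.parcellation,
            cohort.streamlines,
        )
    if config.demographics_tsv is None:
        raise ValueError("demographics_tsv is required without a simulation block")
    demo = pd.read_csv(config.demographics_tsv, sep="\t")
    if config.scores_tsv is not None:
        scores = scoring.read_score_table(config.scores_tsv)
    elif config.responses_dir is not None:
        responses = {}
        for path in sorted(Path(config.responses_dir).glob("*.json")):
            responses[path.stem] = scoring.load_responses(path)
        sides = dict(zip(demo["patient_id"], demo["lesion_side"]))
        scores = scoring.score_table(
            responses, sides, norm=scoring.NormativeParams(*config.coc_norm)
        )
    else:
        raise ValueError("either scores_tsv or responses_dir is required")
    lesions = None
    parc = None
    streams = None
    if config.lesions_dir is not None:
        sides = dict(zip(demo["patient_id"], demo["lesion_side"]))
        lesions = [
            lq.load_lesion(p, patient_id=p.stem, lesion_side=sides.get(p.stem, ""))
            for p in sorted(Path(config.lesions_dir).glob("*.nii*"))
        ]
    if config.atlas_nifti is not None:
        parc = lq.load_parcellation(config.atlas_nifti, config.atlas_lookup)
    if config.streamlines_json is not None:
        streams = lq.load_streamlines(config.streamlines_json)
    return scores, demo, lesions, parc, streams


def _subgroup_mask(demo: pd.DataFrame, subgroup: str | None) -> np.ndarray:
    if subgroup is None:
        return np.ones(len(demo), dtype=bool)
    if subgroup in ("acute", "chronic"):
        return (demo["phase"] == subgroup).to_numpy()
    if subgroup in ("right", "left"):
        return (demo["lesion_side"] == subgroup[0].upper()).to_numpy()
    raise ValueError(f"unknown subgroup {subgroup!r}")


def run_full(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run report."""
    out = Path(config.output_dir)
    for sub in ("scores", "factors", "damage", "lsm"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "warnings": [],
        "excluded": [],
    }

    scores, demo, lesions, parc, streams = _load_inputs(config)
    keep = _subgroup_mask(demo, config.subgroup)
    excluded_ids = demo.loc[~keep, "patient_id"].tolist()
    for pid in excluded_ids:
        report["excluded"].append({"patient_id": pid, "reason": f"subgroup={config.subgroup}"})
    demo = demo.loc[keep].reset_index(drop=True)
    scores = scores.loc[scores["patient_id"].isin(demo["patient_id"])].reset_index(drop=True)
    if lesions is not None:
        lesions = [l for l in lesions if l.patient_id in set(demo["patient_id"])]
    report["stages"]["cohort"] = {
        "n_patients": int(len(demo)),
        "n_excluded": len(excluded_ids),
        "subgroup": config.subgroup,
    }

    # -- scoring stage -----------------------------------------------------
    analysis_scores = scores.copy()
    if config.absolute_scores:
        analysis_scores[list(scoring.SCORE_NAMES)] = analysis_scores[
            list(scoring.SCORE_NAMES)
        ].abs()
    scoring.write_score_table(analysis_scores, out / "scores" / "scores.tsv")
    report["stages"]["scores"] = {
        "absolute": config.absolute_scores,
        "n_patients": int(len(analysis_scores)),
    }

    # -- factor stage ------------------------------------------------------
    if len(demo) < 10:
        # too few patients for a stable 8-score PCA or any mapping: report
        # descriptives only
        report["warnings"].append("subgroup too small (n < 10); factors and mapping skipped")
        report["stages"]["descriptives"] = {
            "score_means": analysis_scores[list(scoring.SCORE_NAMES)].mean().round(4).to_dict()
        }
        _write_report(report, out)
        return report
    model = fm.fit_pca(analysis_scores)
    k = fm.select_components(model, k=config.n_components)
    if k > 1:
        model = fm.rotate_oblimin(model, k)
    else:
        model = fm.rotate_oblimin(model, 1)
    comp_scores = fm.subject_scores(model, analysis_scores)
    fm.write_factor_report(model, out / "factors" / "factor_report.json")
    fm.write_subject_scores(comp_scores, out / "factors" / "component_scores.tsv")
    report["stages"]["factors"] = {
        "k": int(model.k),
        "variance_explained_top_k_pct": float(model.variance_explained_pct[: model.k].sum()),
        "eigenvalues": model.eigenvalues.round(4).tolist(),
    }

    # -- damage stage ------------------------------------------------------
    if lesions is None or parc is None or streams is None:
        report["stages"]["damage"] = {"skipped": "no lesion/atlas inputs"}
        _write_report(report, out)
        return report
    flipped = [
        lq.mirror_flip(l) if (config.flip_left and l.lesion_side == "L") else l for l in lesions
    ]
    profiles = [lq.damage_profile(l, parc, streams) for l in flipped]
    tables = lq.profiles_to_tables(profiles)
    for name, tbl in tables.items():
        tbl.to_csv(out / "damage" / f"{name}.tsv", sep="\t", index=False)
    report["stages"]["damage"] = {
        "n_parcels": len(parc.ids),
        "n_tracts": len(streams.tracts),
        "n_edges_connected": len(streams.pairs),
        "n_flipped": sum(l.lesion_side == "L" for l in lesions) if config.flip_left else 0,
    }

    # -- mapping stage -----------------------------------------------------
    volumes = np.array([p.lesion_volume_mm3 for p in profiles])
    covariates = np.column_stack(
        [
            demo["age"].to_numpy(float),
            (demo["gender"] == "F").to_numpy(float),
            demo["days_post_stroke"].to_numpy(float),
        ]
    )
    feature_sets = _feature_sets(config.levels, tables, flipped)
    report["stages"]["lsm"] = {}
    for level, (values, ids, grid_shape) in feature_sets.items():
        level_dir = out / "lsm" / level
        level_dir.mkdir(parents=True, exist_ok=True)
        maps = run_lsm(
            level,
            values,
            ids,
            comp_scores,
            config.svr,
            covariates=covariates,
            volumes=volumes,
            grid_shape=grid_shape,
        )
        level_report = {}
        for comp, res in maps.items():
            tbl = svrmap_to_table(res)
            tbl.to_csv(level_dir / f"{comp}.tsv", sep="\t", index=False)
            if res.clusters is not None:
                res.clusters.to_csv(level_dir / f"{comp}_clusters.tsv", sep="\t", index=False)
            level_report[comp] = {
                "n_features_retained": int(res.coverage.included.sum()),
                "n_survivors": int(res.survives.sum()),
            }
        report["stages"]["lsm"][level] = level_report

    _write_report(report, out)
    return report


def _feature_sets(levels, tables, flipped_lesions):
    """Assemble the per-level feature matrices from the damage tables."""
    out = {}
    for level in levels:
        if level == "parcel":
            df = tables["parcel"].drop(columns="patient_id")
            out[level] = (df.to_numpy(float), list(df.columns), None)
        elif level == "tract":
            df = tables["tract"].drop(columns="patient_id")
            out[level] = (df.to_numpy(float), list(df.columns), None)
        elif level == "edge":
            wide = tables["edge"].pivot_table(
                index="patient_id", columns=["parcel_a", "parcel_b"], values="pct", sort=True
            )
            wide = wide.loc[tables["volume"]["patient_id"]]
            out[level] = (wide.to_numpy(float), [tuple(c) for c in wide.columns], None)
        elif level == "voxel":
            grids = np.stack([l.grid for l in flipped_lesions])
            any_hit = grids.any(axis=0)
            idx = np.argwhere(any_hit)
            values = grids[:, any_hit].astype(float)
            out[level] = (values, [tuple(v) for v in idx], flipped_lesions[0].grid.shape)
        else:
            raise ValueError(f"unknown level {level!r}")
    return out


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(_as_jsonable(report), fh, indent=2)


# ---------------------------------------------------------------------------
# cohort comparisons
# ---------------------------------------------------------------------------


def compare_groups(
    scores: pd.DataFrame,
    demographics: pd.DataFrame,
    volumes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """KS tests per score across phase and lesion-side splits, plus
    Bonferroni-adjusted Mann-Whitney tests on lesion volume when given."""
    rows = []
    merged = scores.merge(demographics, on="patient_id")
    splits = {
        "acute_vs_chronic": merged["phase"] == "acute",
        "right_vs_left": merged["lesion_side"] == "R",
    }
    for split_name, mask in splits.items():
        for score in scoring.SCORE_NAMES:
            a = merged.loc[mask, score].to_numpy(float)
            b = merged.loc[~mask, score].to_numpy(float)
            if a.size == 0 or b.size == 0:
                rows.append(
                    {"comparison": split_name, "variable": score, "test": "ks",
                     "statistic": np.nan, "p": np.nan, "note": "empty group; skipped"}
                )
                continue
            res = stats.ks_two_sample(a, b)
            rows.append(
                {"comparison": split_name, "variable": score, "test": "ks",
                 "statistic": res.statistic, "p": res.p_value, "note": ""}
            )
    if volumes is not None:
        mv = volumes.merge(demographics, on="patient_id")
        mask = mv["phase"] == "acute"
        a = mv.loc[mask, "lesion_volume_mm3"].to_numpy(float)
        b = mv.loc[~mask, "lesion_volume_mm3"].to_numpy(float)
        if a.size and b.size:
            res = stats.mann_whitney_u(a, b)
            rows.append(
                {"comparison": "acute_vs_chronic", "variable": "lesion_volume_mm3",
                 "test": "mannwhitney", "statistic": res.statistic,
                 "p": float(stats.bonferroni([res.p_value])[0]), "note": "bonferroni m=1"}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writing a simulated cohort to disk
# ---------------------------------------------------------------------------


def write_cohort(cohort: Cohort, out_dir: str | Path, write_responses: bool = True) -> None:
    """Write a simulated cohort in the pipeline's file formats."""
    from .simulate import generate_raw_responses, response_to_dict
    from .scoring import NormativeParams

    out = Path(out_dir)
    (out / "lesions").mkdir(parents=True, exist_ok=True)
    lq.save_parcellation(cohort.parcellation, out / "atlas.nii.gz", out / "atlas_lookup.tsv")
    lq.save_streamlines(cohort.streamlines, out / "streamlines.json")
    cohort.demographics.to_csv(out / "demographics.tsv", sep="\t", index=False)
    cohort.scores.to_csv(out / "scores.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(_as_jsonable(cohort.truth), fh, indent=2)
    for les in cohort.lesions:
        lq.save_map(les, out / "lesions" / f"{les.patient_id}.nii.gz")
    if write_responses:
        (out / "responses").mkdir(exist_ok=True)
        norm = NormativeParams(*cohort.config.coc_norm)
        rng = np.random.default_rng(cohort.config.seed + 1)
        sides = dict(zip(cohort.demographics["patient_id"], cohort.demographics["lesion_side"]))
        for _, row in cohort.scores.iterrows():
            pid = row["patient_id"]
            resp = generate_raw_responses(row, sides[pid], norm=norm, rng=rng)
            with open(out / "responses" / f"{pid}.json", "w") as fh:
                json.dump(response_to_dict(resp), fh)
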