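"""Planted-truth validation experiments for the mapping pipeline.

Each function builds synthetic cohorts with known ground truth and measures
a calibration or recovery property of the SVR mapping chain end to end:
agreement of the linear-SVR weight vector with an ordinary-least-squares
oracle on noiseless data, the family-wise false-positive rate on null
cohorts, recovery of a single seeded parcel, and survival of a planted
voxel cluster under cluster-extent correction.

These are the experiments the test suite and the acceptance script run;
they are deterministic given their seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import lesion as lq
from .simulate import Effect, SimulationConfig, simulate_cohort
from .svr import SVRConfig, cluster_threshold, fit_svr, permutation_null, run_lsm

__all__ = [
    "svr_ols_cosine",
    "parcel_level_run",
    "null_calibration",
    "recovery",
    "voxel_cluster_run",
]

#: the parcel carrying the planted effect in the recovery experiments; a
#: centrally located temporoparietal parcel that stroke-like blobs damage often
SEEDED_PARCEL = "R_temporoparietal_mid_midinf"
SEEDED_SCORE = "moca_cube"


def svr_ols_cosine(
    seed: int = 0, n: int = 60, p: int = 200, n_informative: int = 5
) -> float:
    """Cosine similarity between linear-SVR beta and the OLS weight oracle.

    Noiseless linear target on binary features, fitted with a large cost and
    a vanishing epsilon tube; the OLS oracle is the minimum-norm
    least-squares solution on the same data.
    """
    rng = np.random.default_rng(seed)
    X = (rng.random((n, p)) < 0.3).astype(float)
    w = np.zeros(p)
    w[rng.choice(p, size=n_informative, replace=False)] = rng.uniform(1.0, 2.0, n_informative)
    y = X @ w
    beta = fit_svr(X, y, SVRConfig(C=1e4, epsilon=1e-6))
    # OLS-with-intercept oracle: minimum-norm solution on centred data
    # (rcond guards against numerically null singular directions)
    w_ols = np.linalg.pinv(X - X.mean(axis=0), rcond=1e-10) @ ((y - y.mean()) / y.std())
    return float(beta @ w_ols / (np.linalg.norm(beta) * np.linalg.norm(w_ols)))


def _parcel_cohort(seed: int, n: int, effects: tuple[Effect, ...]):
    sim = SimulationConfig(n_patients=n, effects=effects, noise_sd=0.5, seed=seed)
    cohort = simulate_cohort(sim)
    flipped = [
        lq.mirror_flip(l) if l.lesion_side == "L" else l for l in cohort.lesions
    ]
    profiles = [lq.damage_profile(l, cohort.parcellation, cohort.streamlines) for l in flipped]
    damage = pd.DataFrame([p.parcel_damage_pct for p in profiles])
    volumes = np.array([p.lesion_volume_mm3 for p in profiles])
    return cohort, damage, volumes


def parcel_level_run(
    seed: int, n: int = 60, n_permutations: int = 500, seeded: bool = True
) -> dict:
    """One parcel-level mapping run on a cohort with or without a planted effect.

    Returns the seeded parcel's FWE p (when seeded), whether it attains the
    maximal |beta|, and the number of FWE survivors.
    """
    effects = (Effect("parcel", SEEDED_PARCEL, SEEDED_SCORE, 2.0),) if seeded else ()
    cohort, damage, volumes = _parcel_cohort(seed, n, effects)
    target = cohort.scores[SEEDED_SCORE].to_numpy()
    comps = pd.DataFrame({"C1": target})
    cfg = SVRConfig(n_permutations=n_permutations, seed=seed)
    res = run_lsm(
        "parcel", damage.to_numpy(), list(damage.columns), comps, cfg, volumes=volumes
    )["C1"]
    out = {"n_survivors": int(res.survives.sum())}
    if seeded:
        pid = cohort.truth["parcel"][0]
        j = res.feature_ids.index(pid)
        out["seeded_fwe_p"] = float(res.fwe_p[j])
        out["seeded_is_top_beta"] = bool(
            res.feature_ids[int(np.argmax(np.abs(res.beta)))] == pid
        )
        out["seeded_survives"] = bool(res.survives[j])
    return out


def null_calibration(
    n_runs: int = 20, seed: int = 0, n: int = 60, n_permutations: int = 500
) -> dict:
    """FWE false-positive runs over null cohorts (no planted effect)."""
    with_survivor = 0
    for i in range(n_runs):
        res = parcel_level_run(seed + i, n=n, n_permutations=n_permutations, seeded=False)
        with_survivor += res["n_survivors"] > 0
    return {"n_runs": n_runs, "runs_with_any_survivor": with_survivor}


def recovery(
    n_runs: int = 20, seed: int = 0, n: int = 60, n_permutations: int = 500
) -> dict:
    """Seeded-parcel recovery across replicate cohorts (effect/noise = 4)."""
    fwe_hits = top_hits = 0
    for i in range(n_runs):
        res = parcel_level_run(seed + i, n=n, n_permutations=n_permutations, seeded=True)
        fwe_hits += res["seeded_fwe_p"] < 0.05
        top_hits += res["seeded_is_top_beta"]
    return {"n_runs": n_runs, "fwe_hits": fwe_hits, "top_beta_hits": top_hits}


def voxel_cluster_run(
    seed: int = 0,
    n: int = 60,
    n_permutations: int = 500,
    region_size: tuple[int, int, int] = (4, 5, 2),
) -> dict:
    """Planted 40-voxel effect under voxel-level cluster-extent correction.

    The target score is a noisy linear function of the lesioned fraction of
    a fixed 40-voxel region in the right hemisphere; the run reports whether
    a surviving cluster overlaps the region.
    """
    sim = SimulationConfig(n_patients=n, effects=(), noise_sd=0.0, seed=seed)
    cohort = simulate_cohort(sim)
    flipped = [
        lq.mirror_flip(l) if l.lesion_side == "L" else l for l in cohort.lesions
    ]
    shape = flipped[0].grid.shape
    # region centred in the right hemisphere
    i0 = 3 * shape[0] // 4 - region_size[0] // 2
    j0 = shape[1] // 2 - region_size[1] // 2
    k0 = shape[2] // 2 - region_size[2] // 2
    region = np.zeros(shape, dtype=bool)
    region[i0 : i0 + region_size[0], j0 : j0 + region_size[1], k0 : k0 + region_size[2]] = True
    n_region = int(region.sum())

    grids = np.stack([l.grid for l in flipped])
    frac = grids[:, region].mean(axis=1)
    rng = np.random.default_rng(seed + 7)
    y = 2.0 * frac + 0.5 * rng.standard_normal(n)
    volumes = np.array([lq.lesion_volume(l) for l in flipped])

    comps = pd.DataFrame({"C1": y})
    any_hit = grids.any(axis=0)
    idx = np.argwhere(any_hit)
    values = grids[:, any_hit].astype(float)
    cfg = SVRConfig(n_permutations=n_permutations, seed=seed)
    res = run_lsm(
        "voxel",
        values,
        [tuple(v) for v in idx],
        comps,
        cfg,
        volumes=volumes,
        grid_shape=shape,
    )["C1"]
    clusters = res.clusters
    overlap_p = None
    survived = False
    if len(clusters):
        ids = np.asarray(res.feature_ids)
        in_region = region[ids[:, 0], ids[:, 1], ids[:, 2]]
        # a surviving cluster overlaps the planted region iff some surviving
        # voxel lies inside it
        survived = bool(np.any(res.survives & in_region))
        surviving_rows = clusters.loc[clusters["survives"]]
        if len(surviving_rows):
            overlap_p = float(surviving_rows["cluster_p"].min())
    return {
        "region_voxels": n_region,
        "n_clusters": int(len(clusters)),
        "n_surviving_clusters": int(clusters["survives"].sum()) if len(clusters) else 0,
        "planted_cluster_survives": survived,
        "best_cluster_p": overlap_p,
    }
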