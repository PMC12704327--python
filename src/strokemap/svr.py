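"""Multivariate lesion/disconnection-symptom mapping by support vector regression.

An epsilon-SVR predicts a behavioral component from all lesion features
jointly (binary voxels, or percent damage of parcels, tracts or parcel
pairs). The back-projected weight vector, scaled to unit Euclidean norm, is
the SVR-beta map. Significance is assessed by permuting the (nuisance- and
lesion-volume-adjusted) behavior vector and refitting: per-feature one-tailed
p-values, family-wise error control through the permutation max-statistic at
the parcel/tract/edge levels, and cluster-extent control at the voxel level
(voxel-forming threshold on the permutation p-values, null distribution of
maximal cluster size).

Family-wise error correction uses the studentized beta (the "corrected
z-map": each feature's beta centred and scaled by its own permutation-null
moments) under the max-statistic distribution; studentization equalizes the
null scale across features of very different lesion frequency, which the
raw beta maximum does not.

The linear kernel is fitted through a precomputed Gram matrix so that the
thousands of permutation refits reuse the same kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.svm import SVR

from .lesion import CoverageMask, coverage_mask

__all__ = [
    "SVRConfig",
    "SVRMap",
    "PermutationNull",
    "residualize",
    "correct_lesion_volume",
    "apply_nuisance",
    "fit_svr",
    "permutation_null",
    "fwe_threshold",
    "cluster_threshold",
    "run_lsm",
]

Level = Literal["voxel", "parcel", "tract", "edge"]


class MappingError(ValueError):
    pass


@dataclass(frozen=True)
class SVRConfig:
    """Hyperparameters and thresholds of the mapping pipeline.

    Defaults: linear epsilon-SVR with C = 1, epsilon = 0.1 (RBF with
    gamma = 5 behind the ``kernel`` flag), triple lesion-volume regression
    (behavior and features), 5000 permutations, voxel-forming p < 0.005
    (one-tailed), cluster p < 0.05, FWE p < 0.05 (one-tailed),
    26-connectivity clusters.
    """

    kernel: Literal["linear", "rbf"] = "linear"
    C: float = 1.0
    epsilon: float = 0.1
    gamma: float = 5.0
    volume_correction: Literal["both", "behavior_only", "features_only", "none"] = "both"
    n_permutations: int = 5000
    voxel_p: float = 0.005
    cluster_p: float = 0.05
    fwe_p: float = 0.05
    one_tailed: bool = True
    connectivity: Literal[6, 18, 26] = 26
    seed: int = 0

    def __post_init__(self):
        if self.n_permutations < 1:
            raise MappingError("n_permutations must be >= 1")
        for name in ("voxel_p", "cluster_p", "fwe_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise MappingError(f"{name} must lie in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise MappingError("connectivity must be 6, 18 or 26")


@dataclass
class PermutationNull:
    p_uncorrected: np.ndarray  # per feature
    perm_betas: np.ndarray  # n_permutations x n_features (float32)
    n_permutations: int
    beta_mean: np.ndarray  # per-feature null mean (of the tail statistic)
    beta_sd: np.ndarray  # per-feature null SD
    z_observed: np.ndarray  # studentized observed statistic
    max_z_distribution: np.ndarray  # per permutation, max studentized stat


@dataclass
class SVRMap:
    level: str
    component: str
    feature_ids: list
    beta: np.ndarray
    p_uncorrected: np.ndarray
    fwe_p: np.ndarray | None
    survives: np.ndarray
    clusters: pd.DataFrame | None
    coverage: CoverageMask
    config: SVRConfig


# ---------------------------------------------------------------------------
# shared linear-model primitives
# ---------------------------------------------------------------------------


def residualize(y: np.ndarray, X: np.ndarray | None) -> np.ndarray:
    """Least-squares residuals of y on [1, X] (intercept always included)."""
    y = np.asarray(y, dtype=float)
    if X is None or np.size(X) == 0:
        return y - y.mean(axis=0)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    design = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        r = 1
        for j in range(X.shape[1]):
            sub = np.column_stack([np.ones(len(X)), X[:, : j + 1]])
            rr = np.linalg.matrix_rank(sub)
            if rr == r:
                bad.append(j)
            r = rr
        raise MappingError(f"rank-deficient design; collinear column(s): {bad}")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def correct_lesion_volume(
    features: np.ndarray,
    behavior: np.ndarray,
    volumes: np.ndarray,
    mode: str = "both",
) -> tuple[np.ndarray, np.ndarray]:
    """Regress lesion volume out of behavior, features, or both.

    ``both`` applies the triple correction: behavior and every feature
    column are residualized on lesion volume. Assumes the coverage mask has
    already dropped never-lesioned (all-zero) columns, which a volume
    regression could not adjust.
    """
    if mode not in ("both", "behavior_only", "features_only", "none"):
        raise MappingError(f"unknown volume-correction mode {mode!r}")
    features = np.asarray(features, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if len(volumes) != len(behavior) or len(volumes) != features.shape[0]:
        raise MappingError("volumes, behavior and features must align by patient")
    if mode == "none":
        return features, behavior
    if np.std(volumes) == 0:
        warnings.warn("lesion volume has zero variance; correction skipped", stacklevel=2)
        return features, behavior
    if mode in ("both", "behavior_only"):
        behavior = residualize(behavior, volumes)
    if mode in ("both", "features_only"):
        features = residualize(features, volumes)
    return features, behavior


def apply_nuisance(behavior: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residualize behavior on the nuisance covariates (age, gender, time)."""
    if covariates is None:
        return np.asarray(behavior, dtype=float)
    return residualize(behavior, covariates)


# ---------------------------------------------------------------------------
# SVR fitting
# ---------------------------------------------------------------------------


class _SVREngine:
    """Caches the kernel matrix so permutation refits only re-solve the dual."""

    def __init__(self, X: np.ndarray, config: SVRConfig):
        X = np.asarray(X, dtype=float)
        self.config = config
        # global (direction-preserving) feature normalization: unit mean
        # squared row norm. Keeps the Gram matrix O(1) regardless of whether
        # features are binary voxels or 0-100 percentages, which the SMO
        # solver and the RBF gamma both require.
        scale = np.sqrt(np.mean(np.sum(X**2, axis=1)))
        self.X = X / scale if scale > 0 else X
        if config.kernel == "linear":
            self.K = self.X @ self.X.T
        elif config.kernel == "rbf":
            self.K = rbf_kernel(self.X, gamma=config.gamma)
        else:
            raise MappingError(f"unsupported kernel {config.kernel!r}")

    def beta(self, y: np.ndarray) -> np.ndarray:
        sd = np.std(y)
        if sd == 0:
            raise MappingError("target has zero variance")
        # behavior is z-scored before fitting so that epsilon is expressed in
        # SD units of the target, as in standard SVR-LSM practice
        y = (y - np.mean(y)) / sd
        svr = SVR(kernel="precomputed", C=self.config.C, epsilon=self.config.epsilon)
        svr.fit(self.K, y)
        alpha = svr.dual_coef_.ravel()
        sv = svr.support_
        if self.config.kernel == "linear":
            b = self.X[sv].T @ alpha
        else:
            # sensitivity map: gradient of the fitted function averaged over
            # the training points
            g = self.config.gamma
            Ksv = self.K[:, sv]  # (n, n_sv)
            diff = self.X[:, None, :] - self.X[sv][None, :, :]  # (n, n_sv, p)
            grads = np.einsum("s,ns,nsp->np", alpha, Ksv, diff) * (-2.0 * g)
            b = grads.mean(axis=0)
        nrm = np.linalg.norm(b)
        return b / nrm if nrm > 0 else b


def fit_svr(features: np.ndarray, target: np.ndarray, config: SVRConfig) -> np.ndarray:
    """Unit-norm SVR weight (beta) vector for one behavioral target."""
    features = np.asarray(features, dtype=float)
    if features.shape[0] < 10:
        raise MappingError("need at least 10 patients for SVR mapping")
    return _SVREngine(features, config).beta(np.asarray(target, dtype=float))


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------


def _tail_stat(beta: np.ndarray, one_tailed: bool) -> np.ndarray:
    return beta if one_tailed else np.abs(beta)


def permutation_null(
    features: np.ndarray,
    target: np.ndarray,
    config: SVRConfig,
    observed_beta: np.ndarray | None = None,
    engine: "_SVREngine | None" = None,
) -> tuple[np.ndarray, PermutationNull]:
    """Permute the target, refit, and derive per-feature one-tailed p-values.

    p_j = (1 + #{permuted beta_j >= observed beta_j}) / (n_permutations + 1),
    with per-permutation maxima retained for FWE correction.
    """
    if config.n_permutations < 20:
        warnings.warn("fewer than 20 permutations gives very coarse p-values", stacklevel=2)
    if engine is None:
        engine = _SVREngine(np.asarray(features, dtype=float), config)
    y = np.asarray(target, dtype=float)
    if observed_beta is None:
        observed_beta = engine.beta(y)
    rng = np.random.default_rng(config.seed)
    n_perm = config.n_permutations
    p_feat = engine.X.shape[1]
    perm_betas = np.empty((n_perm, p_feat), dtype=np.float32)
    for m in range(n_perm):
        perm_betas[m] = engine.beta(rng.permutation(y))
    obs_stat = _tail_stat(observed_beta, config.one_tailed)
    perm_stat = _tail_stat(perm_betas.astype(float), config.one_tailed)
    exceed = np.sum(perm_stat >= obs_stat[None, :], axis=0)
    p_unc = (1.0 + exceed) / (n_perm + 1.0)
    mu = perm_stat.mean(axis=0)
    sd = perm_stat.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    z_obs = (obs_stat - mu) / sd
    max_z = ((perm_stat - mu[None, :]) / sd[None, :]).max(axis=1)
    null = PermutationNull(
        p_uncorrected=p_unc,
        perm_betas=perm_betas,
        n_permutations=n_perm,
        beta_mean=mu,
        beta_sd=sd,
        z_observed=z_obs,
        max_z_distribution=max_z,
    )
    return observed_beta, null


def fwe_threshold(
    observed_beta: np.ndarray, null: PermutationNull, fwe_p: float = 0.05, one_tailed: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Max-statistic FWE-corrected p per feature and the surviving set.

    The statistic is the studentized beta (permutation z); corrected
    p_j = (1 + #{permutation max z >= z_j}) / (n_permutations + 1).
    """
    exceed = np.sum(
        null.max_z_distribution[:, None] >= null.z_observed[None, :], axis=0
    )
    fwe = (1.0 + exceed) / (null.n_permutations + 1.0)
    return fwe, fwe < fwe_p


def _connectivity_structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])


def _supra_from_p(p: np.ndarray, threshold: float) -> np.ndarray:
    return p < threshold


def _perm_voxel_p(perm_stat: np.ndarray) -> np.ndarray:
    """Per-permutation, per-voxel p of each permutation beta within the null.

    A permutation's own value plays the role of the observed value's +1
    (it is included once in the exceedance count), so permutation maps are
    thresholded on the same scale as the observed map.
    """
    n_perm = perm_stat.shape[0]
    sorted_stat = np.sort(perm_stat, axis=0)
    p = np.empty_like(perm_stat)
    for j in range(perm_stat.shape[1]):
        below = np.searchsorted(sorted_stat[:, j], perm_stat[:, j], side="left")
        p[:, j] = (n_perm - below) / (n_perm + 1.0)
    return p


def cluster_threshold(
    observed_beta: np.ndarray,
    null: PermutationNull,
    voxel_index: np.ndarray,
    grid_shape: tuple[int, int, int],
    config: SVRConfig,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Cluster-extent correction for voxel-level maps.

    Suprathreshold voxels (permutation p < ``voxel_p``) are grouped by the
    configured 3D connectivity; each permutation's own map, thresholded
    identically, contributes its maximal cluster size to the null. Returns
    the cluster table and the boolean per-voxel map of voxels inside
    surviving clusters.
    """
    voxel_index = np.asarray(voxel_index, dtype=int)
    if voxel_index.ndim != 2 or voxel_index.shape[1] != 3:
        raise MappingError("voxel_index must be an (n_features, 3) array of ijk triples")
    obs_stat = _tail_stat(observed_beta, config.one_tailed)
    perm_stat = _tail_stat(null.perm_betas.astype(float), config.one_tailed)
    n_perm = null.n_permutations
    supra_obs = _supra_from_p(null.p_uncorrected, config.voxel_p)
    structure = _connectivity_structure(config.connectivity)

    def _cluster_sizes(mask_1d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        vol = np.zeros(grid_shape, dtype=bool)
        vol[tuple(voxel_index[mask_1d].T)] = True
        lab, n = ndimage.label(vol, structure=structure)
        if n == 0:
            return lab, np.array([], dtype=int)
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        return lab, sizes.astype(int)

    # null distribution of the maximal cluster size
    perm_p = _perm_voxel_p(perm_stat)
    max_sizes = np.zeros(n_perm, dtype=int)
    for m in range(n_perm):
        _, sizes = _cluster_sizes(_supra_from_p(perm_p[m], config.voxel_p))
        if sizes.size:
            max_sizes[m] = sizes.max()

    lab_obs, sizes_obs = _cluster_sizes(supra_obs)
    rows = []
    surviving = np.zeros(len(observed_beta), dtype=bool)
    lab_at_feature = lab_obs[tuple(voxel_index.T)]
    for cid, size in enumerate(sizes_obs, start=1):
        members = lab_at_feature == cid
        cluster_p = (1.0 + np.sum(max_sizes >= size)) / (n_perm + 1.0)
        peak = int(np.flatnonzero(members)[np.argmax(obs_stat[members])])
        survives = cluster_p < config.cluster_p
        if survives:
            surviving |= members
        rows.append(
            {
                "cluster_id": cid,
                "size": int(size),
                "cluster_p": cluster_p,
                "peak_i": int(voxel_index[peak, 0]),
                "peak_j": int(voxel_index[peak, 1]),
                "peak_k": int(voxel_index[peak, 2]),
                "peak_beta": float(observed_beta[peak]),
                "survives": bool(survives),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "size", "cluster_p",
            "peak_i", "peak_j", "peak_k", "peak_beta", "survives",
        ],
    )
    return table, surviving


# ---------------------------------------------------------------------------
# full mapping pipeline
# ---------------------------------------------------------------------------


def run_lsm(
    level: str,
    features: np.ndarray,
    feature_ids: Sequence,
    components: pd.DataFrame,
    config: SVRConfig,
    covariates: np.ndarray | None = None,
    volumes: np.ndarray | None = None,
    grid_shape: tuple[int, int, int] | None = None,
) -> dict[str, SVRMap]:
    """Coverage mask -> volume correction -> nuisance -> SVR -> permutation inference.

    ``components`` holds one column per behavioral component (any non-id
    column); one SVRMap is produced per component. At the voxel level
    ``feature_ids`` must be ijk triples and ``grid_shape`` given, and
    cluster-extent correction replaces the max-statistic FWE.
    """
    if level not in ("voxel", "parcel", "tract", "edge"):
        raise MappingError(f"unknown level {level!r}")
    features = np.asarray(features, dtype=float)
    comp_cols = [c for c in components.columns if c != "patient_id"]
    if features.shape[0] != len(components):
        raise MappingError("features and component scores must align by patient")

    def _stage(name, fn):
        try:
            return fn()
        except Exception as e:
            raise MappingError(f"stage {name!r} failed: {e}") from e

    cov = _stage("coverage", lambda: coverage_mask(features, feature_ids=list(feature_ids)))
    kept = features[:, cov.included]
    kept_ids = [fid for fid, inc in zip(feature_ids, cov.included) if inc]
    if kept.shape[1] == 0:
        raise MappingError("no feature passes the coverage threshold")

    results: dict[str, SVRMap] = {}
    engine_features = None
    for ci, col in enumerate(comp_cols):
        y = components[col].to_numpy(dtype=float)
        if volumes is not None:
            feats_c, y = _stage(
                "volume_correction",
                lambda y=y: correct_lesion_volume(kept, y, volumes, config.volume_correction),
            )
        else:
            feats_c = kept
        y = _stage("nuisance", lambda y=y: apply_nuisance(y, covariates))
        # feature correction does not depend on the component; reuse the engine
        if engine_features is None or not np.array_equal(engine_features, feats_c):
            engine_features = feats_c
            engine = _SVREngine(feats_c, config)
        cfg_c = SVRConfig(**{**config.__dict__, "seed": config.seed + ci})
        obs_beta, null = _stage(
            "permutation",
            lambda y=y, cfg=cfg_c: permutation_null(feats_c, y, cfg, engine=engine),
        )
        if level == "voxel":
            if grid_shape is None:
                raise MappingError("voxel level requires grid_shape")
            clusters, survives = _stage(
                "cluster_threshold",
                lambda: cluster_threshold(obs_beta, null, np.asarray(kept_ids), grid_shape, cfg_c),
            )
            fwe = None
        else:
            fwe, survives = _stage(
                "fwe_threshold",
                lambda: fwe_threshold(obs_beta, null, cfg_c.fwe_p, cfg_c.one_tailed),
            )
            clusters = None
        results[col] = SVRMap(
            level=level,
            component=col,
            feature_ids=kept_ids,
            beta=obs_beta,
            p_uncorrected=null.p_uncorrected,
            fwe_p=fwe,
            survives=survives,
            clusters=clusters,
            coverage=cov,
            config=cfg_c,
        )
    return results


def svrmap_to_table(result: SVRMap) -> pd.DataFrame:
    """Flat per-feature TSV-ready table (parcel/tract/edge) or voxel table."""
    if result.level == "edge":
        ids = pd.DataFrame(result.feature_ids, columns=["parcel_a", "parcel_b"])
    elif result.level == "voxel":
        ids = pd.DataFrame(result.feature_ids, columns=["i", "j", "k"])
    else:
        ids = pd.DataFrame({"feature": result.feature_ids})
    ids["beta"] = result.beta
    ids["p"] = result.p_uncorrected
    if result.fwe_p is not None:
        ids["fwe_p"] = result.fwe_p
    ids["survives"] = result.survives
    return ids
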