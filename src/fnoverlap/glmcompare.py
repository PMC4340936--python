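"""Voxelwise GLM comparison arm: massively univariate subject-level OLS
contrasts, group one-sample t with sign-flip permutation cluster-extent
inference, and the two checks that connect the GLM view to the
component view — cancellation (overlapping opposite-modulated FNs leave
no net GLM signal) and additivity (the component reconstruction carries
the same GLM contrast as the data).

Family-wise error over clusters is controlled by the maximum-statistic
permutation method: under the null, subject contrast maps are sign-
symmetric, so randomly flipping each subject's map yields the null
distribution of the largest supra-threshold cluster extent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from . import preprocess
from .formats import BrainMask
from .sorting import RegressorMatrix
from .synthio import Volume4D

log = logging.getLogger(__name__)

CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ContrastMap:
    """Per-subject voxelwise contrast estimates c'beta (in-mask vector)."""

    values: np.ndarray
    contrast: np.ndarray

    def to_volume(self, mask: BrainMask) -> np.ndarray:
        return preprocess.unmask(self.values, mask)


@dataclass
class Cluster:
    voxels: np.ndarray       # in-mask indices
    extent: int
    peak_t: float
    p_corrected: float
    significant: bool


@dataclass
class ClusterResult:
    t: np.ndarray            # in-mask group t
    df: int
    height_t: float
    clusters: list = field(default_factory=list)
    null_max_extent: np.ndarray = None
    mask: BrainMask = None

    def significance_vector(self) -> np.ndarray:
        sig = np.zeros(self.t.shape, dtype=bool)
        for c in self.clusters:
            if c.significant:
                sig[c.voxels] = True
        return sig


def fit_subject_glm(v: Volume4D, regressors: RegressorMatrix,
                    contrast, mask: BrainMask) -> ContrastMap:
    """Voxelwise OLS of one run on the design matrix; returns c'beta.

    ``contrast`` is over the condition columns (the intercept gets weight
    0 automatically if the vector is one short of the design width).
    """
    X = regressors.matrix
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    c = np.asarray(contrast, dtype=float)
    if c.size == X.shape[1] - 1:
        c = np.concatenate([c, [0.0]])
    if c.size != X.shape[1]:
        raise ValueError(
            f"contrast length {c.size} does not match design width {X.shape[1]}"
        )
    Y = preprocess.to_matrix(v.data, mask)
    if Y.shape[0] != X.shape[0]:
        raise ValueError(
            f"run has {Y.shape[0]} timepoints but design has {X.shape[0]}"
        )
    beta = np.linalg.lstsq(X, Y, rcond=None)[0]
    return ContrastMap(values=c @ beta, contrast=c)


def _t_vector(maps: np.ndarray) -> np.ndarray:
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    t = np.zeros(maps.shape[1])
    np.divide(mean, sd / np.sqrt(n), out=t, where=sd > 0)
    return t


def _max_cluster_extent(t3d: np.ndarray, height_t: float) -> int:
    best = 0
    for supra in (t3d > height_t, t3d < -height_t):
        if supra.any():
            labels, n = ndimage.label(supra, structure=CONN26)
            if n:
                best = max(best, int(np.bincount(labels.ravel())[1:].max()))
    return best


def group_cluster_inference(contrast_maps, mask: BrainMask,
                            height_p: float = 0.01, cluster_alpha: float = 0.05,
                            n_permutations: int = 500, seed: int = 0) -> ClusterResult:
    """Second-level one-sample t with cluster-extent FWE by sign-flip
    permutation.

    Supra-threshold voxels (two-sided height ``height_p``) form 26-connected
    clusters, positive and negative t separately. A cluster is significant
    iff its corrected p — the fraction of the max-extent null at or above
    its extent — is <= ``cluster_alpha``. If ``n_permutations`` >= 2^n the
    null is enumerated exhaustively (logged) and is deterministic.
    """
    A = np.stack([m.values if isinstance(m, ContrastMap) else np.asarray(m)
                  for m in contrast_maps])
    n = A.shape[0]
    if n < 2:
        raise ValueError("group inference needs at least 2 subjects")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    df = n - 1
    height_t = float(stats.t.isf(height_p / 2.0, df))
    t_obs = _t_vector(A)
    t3d = preprocess.unmask(t_obs, mask)
    in_mask3d = mask.values.astype(bool)
    t3d[~in_mask3d] = 0.0

    exhaustive = n_permutations >= 2**n
    if exhaustive:
        log.info("enumerating all %d sign flips exhaustively", 2**n)
        signs_iter = (
            np.array([1 if (i >> b) & 1 == 0 else -1 for b in range(n)])
            for i in range(2**n)
        )
        n_null = 2**n
    else:
        rng = np.random.default_rng(seed)
        signs_iter = (rng.choice([-1, 1], size=n) for _ in range(n_permutations))
        n_null = n_permutations

    null_max = np.empty(n_null, dtype=int)
    for i, signs in enumerate(signs_iter):
        tp = _t_vector(A * signs[:, None])
        tp3 = preprocess.unmask(tp, mask)
        tp3[~in_mask3d] = 0.0
        null_max[i] = _max_cluster_extent(tp3, height_t)

    clusters = []
    flat_idx = preprocess.mask_indices(mask)
    lut = {v: i for i, v in enumerate(flat_idx)}
    for sign, supra in (("pos", t3d > height_t), ("neg", t3d < -height_t)):
        if not supra.any():
            continue
        labels, n_lab = ndimage.label(supra, structure=CONN26)
        for lab in range(1, n_lab + 1):
            vox3d = labels == lab
            extent = int(vox3d.sum())
            flat = np.flatnonzero(vox3d.ravel(order="F"))
            inmask_idx = np.array([lut[f] for f in flat if f in lut], dtype=int)
            if exhaustive:
                p_corr = float((null_max >= extent).mean())
            else:
                p_corr = float((1 + (null_max >= extent).sum()) / (n_null + 1))
            peak = t_obs[inmask_idx]
            peak_t = float(peak[np.abs(peak).argmax()]) if peak.size else 0.0
            clusters.append(Cluster(
                voxels=inmask_idx, extent=extent, peak_t=peak_t,
                p_corrected=p_corr, significant=p_corr <= cluster_alpha,
            ))
    clusters.sort(key=lambda c: -c.extent)
    return ClusterResult(t=t_obs, df=df, height_t=height_t, clusters=clusters,
                         null_max_extent=null_max, mask=mask)


def cancellation_report(glm: ClusterResult, overlap, fn_label_table,
                        masks) -> dict:
    """Where at least one positive-labeled and one negative-labeled FN
    overlap, report how much of that region the GLM calls significant.

    ``masks`` is the list of SubNetworkMask that built ``overlap``;
    ``fn_label_table`` maps (ic, polarity) -> fn_label for one condition
    (a DataFrame from :func:`fnoverlap.sorting.fn_labels`, one condition).
    """
    label_of = {(r.ic, r.polarity): r.fn_label for r in fn_label_table.itertuples()}
    n_vox = overlap.counts.shape[0]
    if glm.t.shape[0] != n_vox:
        raise ValueError("GLM result and overlap map are on different grids")
    pos_cover = np.zeros(n_vox, dtype=bool)
    neg_cover = np.zeros(n_vox, dtype=bool)
    for m in masks:
        lab = label_of.get((m.ic_id, m.polarity), "neutral")
        if lab == "positive":
            pos_cover |= m.values
        elif lab == "negative":
            neg_cover |= m.values
    region = pos_cover & neg_cover & (overlap.counts >= 2)
    sig = glm.significance_vector()
    n_region = int(region.sum())
    n_sig = int((region & sig).sum())
    return {
        "n_region_voxels": n_region,
        "n_glm_significant": n_sig,
        "glm_significant_fraction": (n_sig / n_region) if n_region else 0.0,
        "glm_null_fraction": (1.0 - n_sig / n_region) if n_region else 0.0,
        "region": region,
    }


def additivity_check(X_subject: np.ndarray, subject_maps: np.ndarray,
                     subject_timecourses: np.ndarray,
                     regressors: RegressorMatrix, contrast,
                     region: np.ndarray) -> dict:
    """Compare the GLM contrast of the component reconstruction
    sum_k map_k (x) timecourse_k against the GLM contrast of the data
    itself, inside ``region`` (boolean in-mask vector).

    If the component set spans the data, the two contrasts agree — the
    additivity property: summed component-wise task effects equal the
    voxelwise task effect.
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        return {"n_voxels": 0, "relative_discrepancy": 0.0}
    X = regressors.matrix
    c = np.asarray(contrast, dtype=float)
    if c.size == X.shape[1] - 1:
        c = np.concatenate([c, [0.0]])
    recon = subject_timecourses @ subject_maps            # T x V
    est_data = c @ np.linalg.lstsq(X, X_subject, rcond=None)[0]
    est_recon = c @ np.linalg.lstsq(X, recon, rcond=None)[0]
    a, b = est_data[region], est_recon[region]
    denom = np.linalg.norm(a)
    disc = float(np.linalg.norm(a - b) / denom) if denom > 0 else 0.0
    return {
        "n_voxels": int(region.sum()),
        "relative_discrepancy": disc,
        "contrast_data": a,
        "contrast_reconstruction": b,
    }
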