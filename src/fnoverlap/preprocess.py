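"""Minimal preprocessing before group ICA: spatial smoothing, analysis-mask
construction, and per-voxel standardization to a timepoints-by-voxels matrix.

In-mask voxels are enumerated in a fixed Fortran scan order (x fastest) so
that matrix columns, component maps, and reconstructed volumes always line
up; :func:`mask_indices`, :func:`to_matrix`, and :func:`unmask` are the one
source of truth for that ordering.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import gaussian_filter

from .formats import BrainMask
from .synthio import Volume4D

log = logging.getLogger(__name__)

FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.3548


def gaussian_smooth(v: Volume4D, fwhm_mm: float) -> Volume4D:
    """Smooth each 3D frame with an isotropic Gaussian of the given FWHM (mm).

    The kernel sd per axis is fwhm / 2.3548 converted to voxel units by the
    voxel size, so anisotropic voxels get per-axis sigmas. The kernel is
    truncated at the volume edge (no wraparound). fwhm_mm = 0 is identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return v
    sd_vox = [fwhm_mm / FWHM_TO_SD / s for s in v.voxel_size_mm]
    out = gaussian_filter(v.data, sigma=sd_vox + [0.0], mode="constant")
    return Volume4D(out, v.voxel_size_mm, v.tr, v.affine)


def compute_mask(volumes, fraction: float = 0.1) -> BrainMask:
    """Analysis mask: voxels whose mean absolute signal across all runs
    exceeds ``fraction`` of the global mean absolute signal."""
    if len(volumes) < 1:
        raise ValueError("need at least one run")
    mean_abs = np.zeros(volumes[0].grid_dims)
    for v in volumes:
        if v.grid_dims != volumes[0].grid_dims:
            raise ValueError("runs are not on a common grid")
        mean_abs += np.abs(v.data).mean(axis=3)
    mean_abs /= len(volumes)
    global_mean = mean_abs.mean()
    values = (mean_abs > fraction * global_mean).astype(np.uint8)
    if values.sum() == 0:
        raise ValueError(
            "mask is empty; lower the mask fraction (all-zero data?)"
        )
    return BrainMask(values, volumes[0].voxel_size_mm)


def mask_indices(mask: BrainMask) -> np.ndarray:
    """Flat (Fortran-order, x fastest) indices of in-mask voxels."""
    return np.flatnonzero(np.asarray(mask.values).ravel(order="F"))


def to_matrix(data4d: np.ndarray, mask: BrainMask) -> np.ndarray:
    """Extract (timepoints, in-mask voxels) from a 4D array."""
    t = data4d.shape[3]
    flat = data4d.reshape(-1, t, order="F")
    return flat[mask_indices(mask)].T


def unmask(values: np.ndarray, mask: BrainMask, fill: float = 0.0) -> np.ndarray:
    """Scatter an in-mask vector back to a full 3D volume."""
    out = np.full(int(np.prod(mask.grid_dims)), fill, dtype=float)
    out[mask_indices(mask)] = values
    return out.reshape(mask.grid_dims, order="F")


def standardize(v: Volume4D, mask: BrainMask, variance_normalize: bool = False):
    """Demean (and optionally variance-normalize) each in-mask voxel's
    time series.

    Variance normalization equalizes every voxel's amplitude, which
    flattens the spatial contrast of source maps; it is off by default and
    exposed for sensitivity analyses.

    Returns (X, means, sds): X is (timepoints, voxels) in mask scan order;
    means/sds allow exact un-standardization. Zero-variance voxels are set
    to all-zero columns and logged rather than raising.
    """
    if v.grid_dims != mask.grid_dims:
        raise ValueError(
            f"volume grid {v.grid_dims} does not match mask grid {mask.grid_dims}"
        )
    X = to_matrix(v.data, mask)
    means = X.mean(axis=0)
    X = X - means
    sds = X.std(axis=0, ddof=0)
    if variance_normalize:
        zero = sds == 0
        if zero.any():
            log.warning("%d zero-variance voxels set to zero columns", zero.sum())
        safe = np.where(zero, 1.0, sds)
        X = X / safe
        X[:, zero] = 0.0
    return X, means, sds


def unstandardize(X: np.ndarray, means: np.ndarray, sds: np.ndarray,
                  variance_normalize: bool = True) -> np.ndarray:
    if variance_normalize:
        X = X * np.where(sds == 0, 1.0, sds)
    return X + means
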