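"""Per-component group statistics and overlap accounting: one-sample
t-maps over subject maps, BH-FDR thresholding into positive/negative
sub-network masks, integer overlap maps, volume summaries, and spectral
artifact indicators.

Terminology: an IC's thresholded t-map has positive and negative voxel
sets; each polarity is one functional network (FN). An overlap map is the
voxelwise sum of binary sub-network masks — a count of 2 or more marks FN
overlap at that voxel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import preprocess
from .formats import BrainMask

log = logging.getLogger(__name__)


@dataclass
class TMap:
    """Voxelwise one-sample t over subject maps (in-mask vectors)."""

    t: np.ndarray            # in-mask vector
    p: np.ndarray            # two-sided p, in-mask vector
    df: int
    zero_variance: np.ndarray  # bool, in-mask

    def to_volume(self, mask: BrainMask) -> np.ndarray:
        return preprocess.unmask(self.t, mask)


@dataclass
class SubNetworkMask:
    """Binary mask of one polarity (one FN) of one IC."""

    ic_id: int
    polarity: str            # "positive" | "negative"
    values: np.ndarray       # bool, in-mask vector

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"bad polarity {self.polarity!r}")
        self.values = np.asarray(self.values, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def to_volume(self, mask: BrainMask) -> np.ndarray:
        return preprocess.unmask(self.values.astype(float), mask)


@dataclass
class OverlapMap:
    """Voxelwise count of covering sub-network masks."""

    counts: np.ndarray       # int, in-mask vector
    mask_ids: list           # contributing (ic_id, polarity)

    @property
    def max_overlap(self) -> int:
        return int(self.counts.max()) if self.counts.size else 0

    def to_volume(self, mask: BrainMask) -> np.ndarray:
        return preprocess.unmask(self.counts.astype(float), mask)


def group_t_map(subject_maps: np.ndarray) -> TMap:
    """One-sample t of per-subject component weights against zero, voxelwise.

    ``subject_maps`` is (n_subjects, voxels) for a single IC. Zero-variance
    voxels are flagged and reported as t = 0, p = 1.
    """
    A = np.asarray(subject_maps, dtype=float)
    n = A.shape[0]
    if n < 2:
        raise ValueError("group t-map needs at least 2 subjects")
    mean = A.mean(axis=0)
    sd = A.std(axis=0, ddof=1)
    zero = sd == 0
    t = np.zeros(A.shape[1])
    np.divide(mean, sd / np.sqrt(n), out=t, where=~zero)
    df = n - 1
    p = 2.0 * stats.t.sf(np.abs(t), df)
    t[zero] = 0.0
    p[zero] = 1.0
    if zero.any():
        log.info("%d zero-variance voxels flagged in group t-map", int(zero.sum()))
    return TMap(t=t, p=p, df=df, zero_variance=zero)


def bh_reject(pvals: np.ndarray, level: float) -> np.ndarray:
    """Benjamini-Hochberg rejection set at FDR ``level`` (boolean array)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    return multipletests(pvals, alpha=level, method="fdr_bh")[0]


def fdr_threshold(tmap: TMap, level: float = 0.001, ic_id: int = 0):
    """Threshold a t-map by BH-FDR over in-mask voxels; split the surviving
    voxels by t sign into the positive and negative sub-network masks.

    Zero-variance voxels are excluded from the p-value pool (they can never
    be rejected). Empty rejection sets yield empty masks, not errors.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    pool = ~tmap.zero_variance
    reject = np.zeros(tmap.p.shape, dtype=bool)
    reject[pool] = bh_reject(tmap.p[pool], level)
    pos = SubNetworkMask(ic_id, "positive", reject & (tmap.t > 0))
    neg = SubNetworkMask(ic_id, "negative", reject & (tmap.t < 0))
    return pos, neg


def overlap_map(masks) -> OverlapMap:
    """Voxelwise integer sum of binary sub-network masks."""
    masks = list(masks)
    if not masks:
        raise ValueError("need at least one mask")
    sizes = {m.values.shape for m in masks}
    if len(sizes) != 1:
        raise ValueError(f"masks are on different grids: {sizes}")
    counts = np.sum([m.values.astype(int) for m in masks], axis=0)
    return OverlapMap(counts=counts, mask_ids=[(m.ic_id, m.polarity) for m in masks])


def volume_summary(class_masks: dict, brain_mask: BrainMask):
    """Union volumes per FN class, pairwise class intersections, and the
    all-class union, each as a voxel count and % of the whole brain.

    ``class_masks`` maps class name ("positive"/"negative"/"neutral") to a
    list of SubNetworkMask.
    """
    allowed = {"positive", "negative", "neutral"}
    if not set(class_masks) <= allowed:
        raise ValueError(f"classes must be within {sorted(allowed)}")
    total = brain_mask.n_voxels
    unions = {}
    for cls, masks in class_masks.items():
        u = np.zeros(total, dtype=bool)
        for m in masks:
            u |= m.values
        unions[cls] = u

    def row(label, arr):
        n = int(arr.sum())
        return {"region": label, "n_voxels": n,
                "pct_whole_brain": 100.0 * n / total}

    rows = [row(f"union_{cls}", unions[cls]) for cls in sorted(unions)]
    names = sorted(unions)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rows.append(row(f"intersection_{a}_{b}", unions[a] & unions[b]))
    if len(names) > 1:
        all_u = np.zeros(total, dtype=bool)
        inter = np.ones(total, dtype=bool)
        for u in unions.values():
            all_u |= u
            inter &= u
        rows.append(row("union_all_classes", all_u))
        if len(names) > 2:
            rows.append(row("intersection_all_classes", inter))
    return rows


def power_ratio(timecourse: np.ndarray, tr: float,
                low_hz: float = 0.10, band=(0.15, 0.25)):
    """Ratio of integrated spectral power below ``low_hz`` to power inside
    ``band``, from a Hann-windowed periodogram sampled at 1/TR."""
    fs = 1.0 / tr
    nyq = fs / 2.0
    f, p = sp_signal.periodogram(timecourse, fs=fs, window="hann")
    lo, hi = band
    if nyq < hi:
        log.warning("Nyquist %.3f Hz < band top %.2f Hz; band truncated", nyq, hi)
        hi = nyq
    if lo >= hi:
        return np.inf, f, p
    num = p[f < low_hz].sum()
    den = p[(f >= lo) & (f <= hi)].sum()
    return (num / den if den > 0 else np.inf), f, p


def flag_artifact_components(result, tr: float, ratio_cutoff: float = 2.0,
                             dynamic_range_cutoff: float = 0.0,
                             tissue_masks: dict = None,
                             group_tmaps: list = None):
    """Advisory artifact indicators per IC.

    For each component: (a) the low/high power ratio of the mean subject
    timecourse spectrum (BOLD-like components concentrate power below
    0.10 Hz), (b) the dynamic range (max - min) of the lightly smoothed
    spectrum, and (c) if tissue masks (e.g. {"wm": ..., "csf": ...} as
    in-mask boolean vectors) and group t-maps are given, whether the peak
    |t| voxel falls inside one. Components are flagged, never deleted.
    """
    n_ics = result.n_ics
    rows = []
    for k in range(n_ics):
        spectra = []
        ratios = []
        for tcs in result.subject_timecourses:
            r, f, p = power_ratio(tcs[:, k], tr)
            ratios.append(r)
            spectra.append(p)
        mean_spec = np.mean(spectra, axis=0)
        ratio = float(np.mean([r for r in ratios if np.isfinite(r)] or [np.inf]))
        smooth = np.convolve(mean_spec, np.ones(3) / 3.0, mode="same")
        dyn = float(smooth.max() - smooth.min())
        in_tissue = False
        tissue = ""
        if tissue_masks and group_tmaps is not None:
            peak = int(np.abs(group_tmaps[k].t).argmax())
            for name, tmask in tissue_masks.items():
                if np.asarray(tmask, dtype=bool)[peak]:
                    in_tissue = True
                    tissue = name
                    break
        flagged = (ratio < ratio_cutoff) or (dyn < dynamic_range_cutoff) or in_tissue
        rows.append({
            "ic_id": k, "power_ratio": ratio, "dynamic_range": dyn,
            "peak_in_tissue": tissue, "artifact_flag": bool(flagged),
        })
    return rows
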