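"""Cross-decomposition goodness of fit: spatial Pearson correlation
between component maps from two ICA results, optimal one-to-one matching,
and flagging of highly correlated pairs (r >= 0.5, the conventional
criterion for calling two components the same network).

ICA component signs are arbitrary, so orientation is resolved per pair by
taking the sign that maximizes the correlation; the chosen sign is
recorded alongside |r|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

HIGH_R = 0.5


@dataclass
class MatchTable:
    pairs: pd.DataFrame        # ic_a, ic_b, r, sign, highly_correlated
    r_matrix: np.ndarray       # |r| after orientation resolution
    signs: np.ndarray
    unmatched_a: list
    unmatched_b: list

    @property
    def fraction_high(self) -> float:
        if not len(self.pairs):
            return 0.0
        return float(self.pairs["highly_correlated"].mean())


def correlate_maps(set_a: np.ndarray, set_b: np.ndarray):
    """Pairwise Pearson correlation over in-mask voxels.

    Returns (|r| matrix (Ka x Kb), signs): sign is the orientation that
    maximizes each pair's correlation. Zero-variance maps get zero rows or
    columns (they correlate with nothing).
    """
    A = np.asarray(set_a, dtype=float)
    B = np.asarray(set_b, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValueError("map sets are on different voxel grids")
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    sa = np.linalg.norm(A, axis=1)
    sb = np.linalg.norm(B, axis=1)
    sa_safe = np.where(sa == 0, 1.0, sa)
    sb_safe = np.where(sb == 0, 1.0, sb)
    r = (A / sa_safe[:, None]) @ (B / sb_safe[:, None]).T
    r[sa == 0, :] = 0.0
    r[:, sb == 0] = 0.0
    signs = np.where(r >= 0, 1.0, -1.0)
    return np.abs(r), signs


def match_components(r_matrix: np.ndarray, signs: np.ndarray = None,
                     threshold: float = HIGH_R, method: str = "optimal") -> MatchTable:
    """One-to-one matching of components maximizing total |r|.

    ``method='optimal'`` solves the assignment problem globally;
    ``method='greedy'`` repeatedly takes the best remaining pair (for
    parity with ad-hoc practice). Non-square matrices leave the surplus
    components unmatched.
    """
    r = np.asarray(r_matrix, dtype=float)
    if not np.isfinite(r).all():
        raise ValueError("correlation matrix contains non-finite entries")
    if signs is None:
        signs = np.ones_like(r)
    ka, kb = r.shape
    if method == "optimal":
        rows, cols = linear_sum_assignment(-r)
    elif method == "greedy":
        rows, cols = [], []
        used_a, used_b = set(), set()
        order = np.dstack(np.unravel_index(np.argsort(-r, axis=None), r.shape))[0]
        for i, j in order:
            if i not in used_a and j not in used_b:
                rows.append(i)
                cols.append(j)
                used_a.add(i)
                used_b.add(j)
            if len(rows) == min(ka, kb):
                break
        rows, cols = np.asarray(rows), np.asarray(cols)
    else:
        raise ValueError(f"unknown method {method!r}")
    pairs = pd.DataFrame({
        "ic_a": rows, "ic_b": cols,
        "r": r[rows, cols],
        "sign": signs[rows, cols].astype(int),
        "highly_correlated": r[rows, cols] >= threshold,
    }).sort_values("ic_a").reset_index(drop=True)
    return MatchTable(
        pairs=pairs, r_matrix=r, signs=signs,
        unmatched_a=sorted(set(range(ka)) - set(rows.tolist())),
        unmatched_b=sorted(set(range(kb)) - set(cols.tolist())),
    )


def match_maps(set_a: np.ndarray, set_b: np.ndarray,
               threshold: float = HIGH_R, method: str = "optimal") -> MatchTable:
    """Convenience wrapper: correlate then match two map sets."""
    r, signs = correlate_maps(set_a, set_b)
    return match_components(r, signs, threshold=threshold, method=method)
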