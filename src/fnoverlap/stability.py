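"""ICASSO-style stability assessment: cluster components across repeated
random-restart ICA runs and score each cluster's compactness.

Similarity between two components is the absolute Pearson correlation of
their source maps (sign-invariant, since ICA signs are arbitrary). The
pooled components from all runs are clustered by average-linkage
agglomeration cut at the model order; the stability index of a cluster is

    Iq = mean intra-cluster similarity - mean similarity to all
         out-of-cluster components,

so Iq near 1 marks a component recovered essentially identically in every
restart. The representative of each cluster (its centrotype — the member
with the highest mean intra-cluster similarity) becomes the final group
component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass
class StabilityReport:
    """Per final component: stability index, members, and centrotype."""

    iq: np.ndarray                 # n_ics
    clusters: list                 # per cluster: list of (run, component)
    centrotypes: list              # per cluster: (run, component)

    def to_rows(self, threshold: float = 0.8):
        return [
            {
                "ic_id": i,
                "iq": float(self.iq[i]),
                "n_members": len(self.clusters[i]),
                "stable": bool(self.iq[i] > threshold),
            }
            for i in range(len(self.iq))
        ]


def component_similarity(stacked: np.ndarray) -> np.ndarray:
    """|Pearson correlation| between all pooled component maps."""
    sim = np.abs(np.corrcoef(stacked))
    np.fill_diagonal(sim, 1.0)
    return np.clip(np.nan_to_num(sim), 0.0, 1.0)


def icasso_cluster(runs, n_ics: int):
    """Cluster pooled components from repeated runs; return the stability
    report and the representative (centrotype) map set (n_ics x voxels).

    Representatives are ordered by decreasing Iq.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs to assess stability")
    shapes = {r.shape[0] for r in runs}
    if len(shapes) != 1:
        raise ValueError(f"runs disagree on component count: {sorted(shapes)}")
    per_run = runs[0].shape[0]
    if per_run < n_ics:
        raise ValueError(f"runs have {per_run} components < n_ics={n_ics}")

    stacked = np.vstack(runs)                       # (R*K) x V
    labels_src = [(r, k) for r in range(len(runs)) for k in range(per_run)]
    sim = component_similarity(stacked)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    assign = fcluster(Z, t=n_ics, criterion="maxclust")

    iqs, clusters, centrotypes, reps = [], [], [], []
    n_total = len(assign)
    for c in np.unique(assign):
        members = np.flatnonzero(assign == c)
        inside = sim[np.ix_(members, members)]
        if len(members) > 1:
            intra = (inside.sum() - len(members)) / (len(members) * (len(members) - 1))
        else:
            intra = 1.0
        outside_idx = np.setdiff1d(np.arange(n_total), members)
        if outside_idx.size:
            extra = sim[np.ix_(members, outside_idx)].mean()
        else:
            extra = 0.0
        iqs.append(intra - extra)
        clusters.append([labels_src[m] for m in members])
        mean_intra = inside.mean(axis=1)
        centro = members[int(mean_intra.argmax())]
        centrotypes.append(labels_src[centro])
        reps.append(stacked[centro])

    order = np.argsort(iqs)[::-1][:n_ics]
    report = StabilityReport(
        iq=np.asarray(iqs)[order],
        clusters=[clusters[i] for i in order],
        centrotypes=[centrotypes[i] for i in order],
    )
    return report, np.vstack([reps[i] for i in order])
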