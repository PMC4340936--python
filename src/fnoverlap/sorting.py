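"""Temporal sorting: regress component timecourses on HRF-convolved task
regressors, average beta weights across runs, and classify each IC (hence
its sub-networks) as task-positive, task-negative, or task-neutral per
condition.

A positive beta weight significantly different from zero marks task-related
up-modulation of the IC timecourse: the IC's positive sub-network is then a
positive FN and its negative sub-network a negative FN; a significant
negative beta flips both designations; otherwise the IC and both its FNs
are neutral. Significance is a one-sample t over subjects per IC with
BH-FDR correction across ICs within each condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import hrf
from .netstats import bh_reject
from .synthio import DesignSpec


@dataclass
class RegressorMatrix:
    """HRF-convolved condition regressors plus an intercept column."""

    matrix: np.ndarray       # timepoints x (conditions + 1)
    conditions: list

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]


def hrf_convolve(design: DesignSpec) -> RegressorMatrix:
    """Build the design matrix: per-condition boxcars on a 0.1 s grid,
    convolved with the canonical double-gamma HRF, sampled at TR, plus an
    intercept. Raises on rank deficiency (empty or duplicated conditions)."""
    regs = hrf.condition_regressors(design)
    mat = np.column_stack([regs, np.ones(design.n_timepoints)])
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        bad = [c for i, c in enumerate(design.conditions)
               if np.allclose(regs[:, i], 0)]
        if bad:
            raise ValueError(f"conditions with no events give zero regressors: {bad}")
        raise ValueError("design matrix is rank deficient (collinear conditions)")
    return RegressorMatrix(matrix=mat, conditions=list(design.conditions))


def sort_timecourses(subject_timecourses, regressors: RegressorMatrix) -> pd.DataFrame:
    """OLS of each IC timecourse on the design matrix, per subject-run.

    ``subject_timecourses`` is a list over subjects; each entry is either a
    (timepoints x n_ics) array (one run) or a list of such arrays (multiple
    runs). Timecourses are standardized to unit variance before regression
    so betas are comparable across ICs. Returns a long-format BetaTable
    with columns subject, run, ic, condition, beta.
    """
    X = regressors.matrix
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("regressor matrix is rank deficient")
    rows = []
    for s, runs in enumerate(subject_timecourses):
        if isinstance(runs, np.ndarray):
            runs = [runs]
        for r, tc in enumerate(runs):
            tc = np.asarray(tc, dtype=float)
            if tc.shape[0] != X.shape[0]:
                raise ValueError(
                    f"subject {s} run {r}: {tc.shape[0]} timepoints != "
                    f"design {X.shape[0]}"
                )
            tc = tc - tc.mean(axis=0)
            sd = tc.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            tc = tc / sd
            betas = np.linalg.lstsq(X, tc, rcond=None)[0]  # (C+1) x n_ics
            for c, cond in enumerate(regressors.conditions):
                for k in range(tc.shape[1]):
                    rows.append({"subject": s, "run": r, "ic": k,
                                 "condition": cond, "beta": betas[c, k]})
    return pd.DataFrame(rows)


def subject_mean_betas(beta_table: pd.DataFrame) -> pd.DataFrame:
    """Unweighted average of each subject's betas across runs."""
    return (beta_table.groupby(["subject", "ic", "condition"], as_index=False)
            ["beta"].mean())


def classify_fns(beta_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Label each (IC, condition) positive / negative / neutral.

    Group one-sample t of run-averaged subject betas against zero per IC,
    BH-FDR across ICs within each condition at ``alpha``. Columns: ic,
    condition, mean_beta, t, p, p_fdr, label.
    """
    means = subject_mean_betas(beta_table)
    n_subj = means["subject"].nunique()
    if n_subj < 2:
        raise ValueError("classification needs at least 2 subjects")
    out = []
    for cond, grp in means.groupby("condition"):
        ics = sorted(grp["ic"].unique())
        tvals, pvals, mbetas = [], [], []
        for k in ics:
            b = grp.loc[grp["ic"] == k].sort_values("subject")["beta"].to_numpy()
            if np.allclose(b.std(ddof=1), 0.0):
                t = 0.0 if np.isclose(b.mean(), 0.0) else np.inf * np.sign(b.mean())
                p = 1.0 if t == 0.0 else 0.0
            else:
                t, p = stats.ttest_1samp(b, 0.0)
            tvals.append(float(t))
            pvals.append(float(p))
            mbetas.append(float(b.mean()))
        reject = bh_reject(np.asarray(pvals), alpha)
        p_fdr = _bh_adjust(np.asarray(pvals))
        for i, k in enumerate(ics):
            if reject[i] and mbetas[i] > 0:
                label = "positive"
            elif reject[i] and mbetas[i] < 0:
                label = "negative"
            else:
                label = "neutral"
            out.append({"ic": k, "condition": cond, "mean_beta": mbetas[i],
                        "t": tvals[i], "p": pvals[i], "p_fdr": p_fdr[i],
                        "label": label})
    return pd.DataFrame(out)


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def fn_labels(classification: pd.DataFrame) -> pd.DataFrame:
    """Expand IC labels to sub-network (FN) labels: the positive sub-network
    inherits the IC's label; the negative sub-network takes the opposite
    label; neutral ICs have two neutral FNs."""
    flip = {"positive": "negative", "negative": "positive", "neutral": "neutral"}
    rows = []
    for r in classification.itertuples():
        rows.append({"ic": r.ic, "condition": r.condition,
                     "polarity": "positive", "fn_label": r.label})
        rows.append({"ic": r.ic, "condition": r.condition,
                     "polarity": "negative", "fn_label": flip[r.label]})
    return pd.DataFrame(rows)


def compare_conditions(beta_table: pd.DataFrame, condition_a: str,
                       condition_b: str, alpha: float = 0.05) -> pd.DataFrame:
    """Paired t-test of run-averaged betas between two conditions, per IC,
    BH-FDR across ICs. Zero-variance nonzero differences are flagged as
    degenerate with p -> 0."""
    means = subject_mean_betas(beta_table)
    have = set(means["condition"])
    for c in (condition_a, condition_b):
        if c not in have:
            raise ValueError(f"condition {c!r} absent from beta table")
    wide = means.pivot_table(index=["subject", "ic"], columns="condition",
                             values="beta").reset_index()
    missing = wide[wide[[condition_a, condition_b]].isna().any(axis=1)]
    if len(missing):
        raise ValueError(
            f"subjects missing a condition: {sorted(missing['subject'].unique())}"
        )
    out = []
    ics = sorted(wide["ic"].unique())
    tvals, pvals, dmeans, degen = [], [], [], []
    for k in ics:
        sub = wide[wide["ic"] == k].sort_values("subject")
        d = (sub[condition_a] - sub[condition_b]).to_numpy()
        if np.allclose(d.std(ddof=1), 0.0):
            degen.append(True)
            if np.isclose(d.mean(), 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = np.inf * np.sign(d.mean()), 0.0
        else:
            degen.append(False)
            t, p = stats.ttest_rel(sub[condition_a], sub[condition_b])
        tvals.append(float(t))
        pvals.append(float(p))
        dmeans.append(float(d.mean()))
    reject = bh_reject(np.asarray(pvals), alpha)
    p_fdr = _bh_adjust(np.asarray(pvals))
    for i, k in enumerate(ics):
        out.append({"ic": k, "mean_diff": dmeans[i], "t": tvals[i],
                    "p": pvals[i], "p_fdr": p_fdr[i],
                    "significant": bool(reject[i]), "degenerate": degen[i]})
    return pd.DataFrame(out)
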