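"""Group spatial ICA: two-stage PCA reduction of temporally concatenated
subjects, natural-gradient Infomax unmixing with repeated restarts for
stability scoring, and dual-regression back-reconstruction of per-subject
maps and timecourses.

The generative assumption is that each voxel's BOLD signal is a linear
mixture of spatially independent source signals: concatenated data
X (time x voxels) ≈ A S with S the spatial sources (components x voxels).
Infomax maximizes the entropy of g(W Y) for whitened data Y with the
logistic nonlinearity g, which is maximum-likelihood estimation for
super-Gaussian (sparse) spatial sources — the regime fMRI networks live in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import preprocess, stability
from .formats import BrainMask


@dataclass
class ICAConfig:
    """Model order, reduction dimensions, restarts, and Infomax hyperparameters.

    Defaults follow common group-ICA practice for task fMRI: a model order
    of 75 components with 50 stability restarts; desk-scale analyses
    override both. Subject-level PCA keeps 1.5x the model order and the
    group level keeps exactly the model order.
    """

    n_ics: int = 75
    subject_pca_dims: int = None      # default ceil(1.5 * n_ics)
    group_pca_dims: int = None        # default n_ics
    n_icasso_runs: int = 50
    seed: int = 0
    learning_rate: float = None       # default 0.015 / max(ln n_ics, 1)
    block_size: int = None            # default ceil(sqrt(samples / 3))
    max_sweeps: int = 512
    tol: float = 1e-6
    anneal: float = 0.9
    variance_normalize: bool = False

    def resolved(self) -> "ICAConfig":
        cfg = ICAConfig(**self.__dict__)
        if cfg.subject_pca_dims is None:
            cfg.subject_pca_dims = int(np.ceil(1.5 * cfg.n_ics))
        if cfg.group_pca_dims is None:
            cfg.group_pca_dims = cfg.n_ics
        if cfg.n_ics > cfg.group_pca_dims:
            raise ValueError("n_ics must be <= group_pca_dims")
        if cfg.group_pca_dims > cfg.subject_pca_dims * 10**9:
            raise ValueError("group_pca_dims exceeds available dimensions")
        if cfg.n_icasso_runs < 1:
            raise ValueError("n_icasso_runs must be >= 1")
        return cfg


@dataclass
class ICResult:
    """Group decomposition plus per-subject back-reconstructions."""

    group_maps: np.ndarray            # n_ics x in-mask voxels
    subject_maps: list                # per subject: n_ics x voxels
    subject_timecourses: list         # per subject: timepoints x n_ics
    mask: BrainMask
    stability_report: object = None
    explained_variance: np.ndarray = None
    config: ICAConfig = None
    signs: np.ndarray = field(default=None)  # orientation flips applied

    @property
    def n_ics(self) -> int:
        return self.group_maps.shape[0]


def pca_reduce(X: np.ndarray, n_components: int):
    """Top principal components of X (rows reduced, columns kept).

    For an (observations x voxels) matrix this is the temporal reduction
    used at both stages of group ICA. Returns (reduced (n x voxels),
    basis (n x observations), explained variance fractions, non-increasing).
    """
    X = np.asarray(X, dtype=float)
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds matrix dimensions {X.shape}"
        )
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    rank_tol = s[0] * max(X.shape) * np.finfo(float).eps if s.size else 0.0
    if n_components > int((s > rank_tol).sum()):
        raise ValueError(f"n_components={n_components} exceeds matrix rank")
    basis = U[:, :n_components].T
    reduced = basis @ X
    explained = var[:n_components] / var.sum()
    return reduced, basis, explained


def whiten_rows(Y: np.ndarray) -> np.ndarray:
    """Whiten rows over samples: demean each row, then rotate/scale so the
    sample covariance is the identity (SVD whitening; row space preserved)."""
    Yc = Y - Y.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    if (s <= s[0] * 1e-12).any():
        raise ValueError("reduced data are rank deficient; lower group_pca_dims")
    return np.sqrt(Y.shape[1]) * Vt


def _default_rate(n_comp: int) -> float:
    return 0.015 / max(np.log(n_comp), 1.0)


def infomax(Y: np.ndarray, seed: int = 0, learning_rate: float = None,
            block_size: int = None, max_sweeps: int = 512, tol: float = 1e-6,
            anneal: float = 0.9, max_restarts: int = 5):
    """Natural-gradient Infomax with logistic nonlinearity.

    Y must be whitened (components x samples, sample covariance ≈ I;
    asserted). Learning is annealed when successive weight updates turn by
    more than 60 degrees, and stops when the relative weight change falls
    below ``tol`` or after ``max_sweeps``. On divergence the run restarts
    with a halved rate, up to ``max_restarts`` times.

    Returns (W, S): the unmixing matrix and sources S = W @ Y with rows
    scaled to unit variance and oriented so each row's largest-magnitude
    sample is positive.
    """
    Y = np.asarray(Y, dtype=float)
    n, m = Y.shape
    cov = (Y @ Y.T) / m
    if not np.allclose(cov, np.eye(n), atol=0.05):
        raise ValueError("infomax expects whitened input (sample covariance ~ I)")
    rate0 = _default_rate(n) if learning_rate is None else learning_rate
    block = int(np.ceil(np.sqrt(m / 3.0))) if block_size is None else block_size
    rng = np.random.default_rng(seed)
    W0 = np.linalg.qr(rng.standard_normal((n, n)))[0]

    for attempt in range(max_restarts + 1):
        W = W0.copy()
        lrate = rate0 * 0.5**attempt
        d_old = None
        eye = np.eye(n)
        diverged = False
        for _ in range(max_sweeps):
            W_old = W.copy()
            perm = rng.permutation(m)
            for start in range(0, m - block + 1, block):
                u = W @ Y[:, perm[start:start + block]]
                g = 1.0 / (1.0 + np.exp(-u))
                W = W + lrate * ((eye + (1.0 - 2.0 * g) @ u.T / block) @ W)
                if not np.isfinite(W).all() or np.abs(W).max() > 1e8:
                    diverged = True
                    break
            if diverged:
                break
            delta = W - W_old
            change = np.linalg.norm(delta) / max(np.linalg.norm(W_old), 1e-30)
            if d_old is not None:
                denom = np.linalg.norm(delta) * np.linalg.norm(d_old)
                if denom > 0:
                    cosang = (delta * d_old).sum() / denom
                    if cosang < 0.5:  # update turned by > 60 degrees
                        lrate *= anneal
            d_old = delta
            if change < tol:
                break
        if not diverged:
            S = W @ Y
            sd = S.std(axis=1, ddof=0)
            sd[sd == 0] = 1.0
            W = W / sd[:, None]
            S = S / sd[:, None]
            W, S = _orient_rows(W, S)
            return W, S
    raise RuntimeError(
        f"infomax diverged after {max_restarts + 1} attempts (last rate {lrate:g})"
    )


def _orient_rows(W: np.ndarray, S: np.ndarray):
    """Flip each source row so its largest-|value| sample is positive."""
    idx = np.abs(S).argmax(axis=1)
    signs = np.sign(S[np.arange(S.shape[0]), idx])
    signs[signs == 0] = 1.0
    return W * signs[:, None], S * signs[:, None]


def back_reconstruct(X: np.ndarray, group_maps: np.ndarray):
    """Dual (spatial-temporal) regression of one subject on the group maps.

    Stage 1 regresses the subject's standardized data on the group spatial
    maps across voxels, giving subject timecourses; stage 2 regresses the
    data on those timecourses across time, giving subject-specific maps.

    Returns (subject_maps (n_ics x voxels), timecourses (timepoints x n_ics)).
    """
    M = np.asarray(group_maps, dtype=float)   # K x V
    k = M.shape[0]
    if np.linalg.matrix_rank(M @ M.T) < k:
        gram = M @ M.T
        corr = gram / np.sqrt(np.outer(np.diag(gram), np.diag(gram)).clip(1e-30))
        pairs = [
            (i, j) for i in range(k) for j in range(i + 1, k)
            if abs(corr[i, j]) > 0.999
        ]
        raise np.linalg.LinAlgError(
            f"group maps are collinear; near-duplicate component pairs: {pairs}"
        )
    tc = np.linalg.lstsq(M.T, X.T, rcond=None)[0].T        # T x K
    # degenerate (e.g. constant) timecourses are legal; lstsq falls back to
    # the minimum-norm stage-2 solution
    maps = np.linalg.lstsq(tc, X, rcond=None)[0]           # K x V
    return maps, tc


def orient_components(result: ICResult) -> ICResult:
    """Resolve ICA sign ambiguity: flip each component so the voxel of
    maximum |group weight| is positive, applying the same flip to subject
    maps and timecourses (their products are unchanged). Idempotent."""
    idx = np.abs(result.group_maps).argmax(axis=1)
    signs = np.sign(result.group_maps[np.arange(result.n_ics), idx])
    signs[signs == 0] = 1.0
    result.group_maps = result.group_maps * signs[:, None]
    result.subject_maps = [m * signs[:, None] for m in result.subject_maps]
    result.subject_timecourses = [t * signs[None, :] for t in result.subject_timecourses]
    result.signs = signs if result.signs is None else result.signs * signs
    return result


def run_group_ica(volumes, mask: BrainMask, config: ICAConfig) -> ICResult:
    """Full group spatial ICA pipeline on a cohort of 4D runs.

    standardize each subject -> subject-level PCA (temporal reduction) ->
    temporal concatenation -> group PCA -> whiten -> repeated Infomax with
    ICASSO clustering (representatives become the group maps) -> orient ->
    dual-regression back-reconstruction per subject.
    """
    cfg = config.resolved()
    if len(volumes) < 2:
        raise ValueError("group ICA requires at least 2 subjects")
    Xs = []
    for i, v in enumerate(volumes):
        try:
            X, _, _ = preprocess.standardize(v, mask, cfg.variance_normalize)
        except ValueError as e:
            raise ValueError(f"standardize failed for subject {i}: {e}") from e
        Xs.append(X)
    d1 = min(cfg.subject_pca_dims, min(X.shape[0] for X in Xs))
    reduced = []
    for i, X in enumerate(Xs):
        try:
            reduced.append(pca_reduce(X, d1)[0])
        except ValueError as e:
            raise ValueError(f"subject-level PCA failed for subject {i}: {e}") from e
    concat = np.vstack(reduced)
    if cfg.group_pca_dims > concat.shape[0]:
        raise ValueError(
            f"group_pca_dims={cfg.group_pca_dims} exceeds concatenated "
            f"dimension {concat.shape[0]}"
        )
    try:
        Yg, _, explained = pca_reduce(concat, cfg.group_pca_dims)
    except ValueError as e:
        raise ValueError(f"group-level PCA failed: {e}") from e
    Y = whiten_rows(Yg)

    run_seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_icasso_runs)
    source_sets = []
    for s in run_seeds:
        _, S = infomax(
            Y, seed=int(s), learning_rate=cfg.learning_rate,
            block_size=cfg.block_size, max_sweeps=cfg.max_sweeps,
            tol=cfg.tol, anneal=cfg.anneal,
        )
        source_sets.append(S[:cfg.n_ics] if cfg.n_ics < S.shape[0] else S)

    if len(source_sets) > 1:
        report, group_maps = stability.icasso_cluster(source_sets, cfg.n_ics)
    else:
        report, group_maps = None, source_sets[0]

    subject_maps, subject_tcs = [], []
    for i, X in enumerate(Xs):
        try:
            m, tc = back_reconstruct(X, group_maps)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                f"back-reconstruction failed for subject {i}: {e}"
            ) from e
        subject_maps.append(m)
        subject_tcs.append(tc)

    result = ICResult(
        group_maps=group_maps, subject_maps=subject_maps,
        subject_timecourses=subject_tcs, mask=mask,
        stability_report=report, explained_variance=explained, config=cfg,
    )
    return orient_components(result)
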