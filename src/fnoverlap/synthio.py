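"""Synthetic multi-subject 4D BOLD data with planted overlapping networks.

Data are generated under the linear-mixture assumption that spatial ICA
relies on: the signal at voxel v and time t is a sum over networks k of
``map_k(v) * c_k(t)`` plus white Gaussian noise, where each network
timecourse ``c_k`` combines HRF-convolved task regressors weighted by
per-condition betas and a slow network-specific sinusoidal fluctuation.
Networks are sums of 3D Gaussian blobs; requested pairs get closely
offset blobs so their supports overlap above half maximum — the
configuration whose downstream signature (overlapping task-positive and
task-negative sub-networks) the analysis modules are built to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from . import hrf


@dataclass
class SpatialMap:
    """A real-valued 3D network map on the analysis grid."""

    values: np.ndarray                      # 3D, arbitrary units
    voxel_size_mm: tuple = (3.0, 3.0, 3.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("SpatialMap requires a 3D array")
        if not np.isfinite(self.values).all():
            raise ValueError("SpatialMap contains non-finite values")
        if not (self.values != 0).any():
            raise ValueError("SpatialMap is identically zero")

    @property
    def grid_dims(self):
        return self.values.shape


@dataclass
class DesignSpec:
    """Task timing for one run: conditions with (onset s, duration s) events."""

    conditions: list
    events: dict          # condition -> list of (onset, duration)
    tr: float
    n_timepoints: int

    def __post_init__(self):
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition names must be unique")
        run_len = self.tr * self.n_timepoints
        for cond in self.conditions:
            for onset, duration in self.events.get(cond, []):
                if onset < 0:
                    raise ValueError(f"negative onset in condition {cond!r}")
                if duration < 0:
                    raise ValueError(f"negative duration in condition {cond!r}")
                if onset + duration > run_len:
                    raise ValueError(
                        f"event at {onset}s (+{duration}s) in condition {cond!r} "
                        f"extends past run end ({run_len}s)"
                    )

    @property
    def run_length_s(self) -> float:
        return self.tr * self.n_timepoints


@dataclass
class GroundTruth:
    """Planted networks, their task betas, and noise parameters for a cohort.

    betas is (n_networks, n_conditions), ordered like ``conditions``.
    subject_beta_sd scales per-subject multiplicative variability of each
    network's task engagement (betas_s = betas * (1 + eta), eta ~ N(0, sd));
    slow_amp / slow_period_s parameterize the network-specific slow
    sinusoidal fluctuation that gives task-neutral networks variance.
    """

    networks: list                   # list of SpatialMap, common grid
    betas: np.ndarray
    conditions: list
    noise_sd: float = 0.0
    subject_map_jitter_sd: float = 0.0
    subject_beta_sd: float = 0.25
    slow_amp: float = 0.3
    slow_period_s: float = 60.0
    seed: int = 0

    def __post_init__(self):
        self.betas = np.atleast_2d(np.asarray(self.betas, dtype=float))
        if self.betas.shape != (len(self.networks), len(self.conditions)):
            raise ValueError(
                "betas must be (n_networks, n_conditions) = "
                f"({len(self.networks)}, {len(self.conditions)}), got {self.betas.shape}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        grids = {m.grid_dims for m in self.networks}
        if len(grids) > 1:
            raise ValueError("all networks must share one grid")

    @property
    def grid_dims(self):
        return self.networks[0].grid_dims

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["networks"] = [m.values.tolist() for m in self.networks]
        d["voxel_size_mm"] = list(self.networks[0].voxel_size_mm)
        d["betas"] = self.betas.tolist()
        return d

    @classmethod
    def from_jsonable(cls, d: dict) -> "GroundTruth":
        vox = tuple(d.get("voxel_size_mm", (3.0, 3.0, 3.0)))
        nets = [SpatialMap(np.asarray(v), vox) for v in d["networks"]]
        return cls(
            networks=nets, betas=np.asarray(d["betas"]),
            conditions=list(d["conditions"]), noise_sd=d["noise_sd"],
            subject_map_jitter_sd=d["subject_map_jitter_sd"],
            subject_beta_sd=d.get("subject_beta_sd", 0.25),
            slow_amp=d.get("slow_amp", 0.3),
            slow_period_s=d.get("slow_period_s", 60.0), seed=d["seed"],
        )


@dataclass
class Volume4D:
    """One subject-run of BOLD-like voxel time series (x, y, z, t)."""

    data: np.ndarray
    voxel_size_mm: tuple = (3.0, 3.0, 3.0)
    tr: float = 1.5
    affine: np.ndarray = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"Volume4D requires a 4D array, got {self.data.ndim}D")
        if not np.isfinite(self.data).all():
            raise ValueError("Volume4D contains non-finite values")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def grid_dims(self):
        return self.data.shape[:3]


DEFAULT_GRID = (20, 20, 12)
DEFAULT_VOXEL_MM = (3.0, 3.0, 3.0)
DEFAULT_TR = 1.5
DEFAULT_T = 150


def _gaussian_blob(grid_dims, center, sigma) -> np.ndarray:
    axes = [np.arange(n, dtype=float) for n in grid_dims]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    d2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2
    return np.exp(-d2 / (2.0 * sigma**2))


def make_network_library(
    n_networks: int,
    grid_dims=DEFAULT_GRID,
    overlap_spec=(),
    seed: int = 0,
    n_blobs: int = 2,
    sigma_range=(1.5, 2.2),
    voxel_size_mm=DEFAULT_VOXEL_MM,
) -> list:
    """Build ``n_networks`` blob maps; pairs in ``overlap_spec`` share a blob.

    Each map is a sum of ``n_blobs`` Gaussian bumps with sd drawn from
    ``sigma_range`` voxels (FWHM roughly 2-4 voxels), unit-normalized to a
    maximum of 1. Blob centers within one map are kept well separated so
    every blob center sits above half the map maximum. A pair named in
    ``overlap_spec`` gets two equal-sd blobs whose centers sit 1.8 sd apart,
    so both maps exceed half their own maximum around the midpoint (non-empty
    half-maximum intersection) while the maps stay only mildly correlated —
    fully coincident blobs would make the sources spatially dependent and
    unidentifiable for spatial ICA.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    for i, j in overlap_spec:
        if not (0 <= i < n_networks and 0 <= j < n_networks) or i == j:
            raise ValueError(f"overlap_spec pair ({i}, {j}) out of range")
    rng = np.random.default_rng(seed)
    grid_dims = tuple(int(g) for g in grid_dims)
    margin = 1.5 * max(sigma_range)
    lo = [margin] * 3
    hi = [g - 1 - margin for g in grid_dims]
    if any(h <= l for l, h in zip(lo, hi)):
        raise ValueError(f"grid {grid_dims} too small for blobs of sd {sigma_range}")
    # blobs of one network must stay well separated (each blob near its own
    # local maximum, for the half-maximum property); blobs of different
    # networks may sit closer — between-network overlap is the phenomenon
    # under study, it only must not become near-collinearity
    sep_within = 2.3 * max(sigma_range)
    sep_between = 1.5 * max(sigma_range)

    class _PlacementFull(Exception):
        pass

    def draw_center(own, others):
        for _ in range(200):
            c = np.array([rng.uniform(l, h) for l, h in zip(lo, hi)])
            if all(np.linalg.norm(c - e) >= sep_within for e in own) and all(
                    np.linalg.norm(c - e) >= sep_between for e in others):
                return c
        raise _PlacementFull

    def place():
        # overlap-pair blobs first: equal sd, centers 1.8 sd apart
        blobs = {k: [] for k in range(n_networks)}  # (center, sigma)

        def centers(ks):
            return [c for k in ks for c, _ in blobs[k]]

        every = range(n_networks)
        for i, j in overlap_spec:
            # snap the shared midpoint to a voxel center so the
            # half-maximum intersection is guaranteed to contain it
            own = centers([i, j])
            rest = centers([k for k in every if k not in (i, j)])
            c = np.round(draw_center(own, rest))
            sig = rng.uniform(*sigma_range)
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            blobs[i].append((np.clip(c - 0.9 * sig * u, lo, hi), sig))
            blobs[j].append((np.clip(c + 0.9 * sig * u, lo, hi), sig))
        for k in every:
            while len(blobs[k]) < n_blobs:
                rest = centers([q for q in every if q != k])
                blobs[k].append((draw_center(centers([k]), rest),
                                 rng.uniform(*sigma_range)))
        return blobs

    blobs = None
    for _ in range(30):  # sequential packing can dead-end; retry whole layouts
        try:
            blobs = place()
            break
        except _PlacementFull:
            continue
    if blobs is None:
        raise ValueError(
            f"grid {grid_dims} too small to place blobs {sep_within:.1f} voxels apart"
        )

    maps = []
    for k in range(n_networks):
        vol = np.zeros(grid_dims)
        for c, sig in blobs[k]:
            vol += _gaussian_blob(grid_dims, c, sig)
        vol /= np.abs(vol).max()
        maps.append(SpatialMap(vol, tuple(voxel_size_mm)))

    for i, j in overlap_spec:
        both = (maps[i].values > 0.5) & (maps[j].values > 0.5)
        if not both.any():
            raise AssertionError(f"overlap construction failed for pair ({i}, {j})")
    return maps


def make_design(
    template: str,
    n_events: int,
    tr: float = DEFAULT_TR,
    n_timepoints: int = DEFAULT_T,
    seed: int = 0,
    conditions=("task",),
    event_duration: float = 1.0,
    block_duration: float = 15.0,
) -> DesignSpec:
    """Event-related (jittered intervals) or block (fixed blocks + rest) design.

    Events are assigned to ``conditions`` round-robin, so multi-condition
    designs interleave conditions along the run.
    """
    if template not in ("event", "block"):
        raise ValueError("template must be 'event' or 'block'")
    rng = np.random.default_rng(seed)
    run_len = tr * n_timepoints
    conditions = list(conditions)
    events = {c: [] for c in conditions}
    if n_events > 0:
        duration = event_duration if template == "event" else block_duration
        lead = 4.0  # s before first onset
        slot = (run_len - lead - duration) / n_events
        if slot <= duration * (0.0 if template == "event" else 0.2) or slot <= 0:
            raise ValueError(
                f"run of {run_len:.0f}s too short for {n_events} "
                f"{template} events of {duration}s"
            )
        for i in range(n_events):
            onset = lead + i * slot
            if template == "event":
                onset += rng.uniform(0.0, max(slot - duration, 0.0))
            onset = min(onset, run_len - duration)
            events[conditions[i % len(conditions)]].append((float(onset), float(duration)))
    return DesignSpec(conditions, events, tr, n_timepoints)


def network_timecourses(truth: GroundTruth, design: DesignSpec, rng) -> np.ndarray:
    """(n_timepoints, n_networks) timecourses for one subject: task term
    (with subject-specific engagement scaling) + slow fluctuation."""
    regs = hrf.condition_regressors(design)           # T x C
    t = np.arange(design.n_timepoints) * design.tr
    n_k = len(truth.networks)
    betas = truth.betas
    if truth.subject_beta_sd > 0:
        betas = betas * (1.0 + rng.normal(0.0, truth.subject_beta_sd,
                                          size=n_k))[:, None]
    tc = regs @ betas.T                               # T x K
    if truth.slow_amp > 0:
        phases = rng.uniform(0, 2 * np.pi, size=n_k)
        # per-network periods spread around the nominal value keep the
        # fluctuations of same-beta networks temporally distinguishable
        periods = truth.slow_period_s * rng.uniform(0.75, 1.25, size=n_k)
        tc = tc + truth.slow_amp * np.sin(
            2 * np.pi * t[:, None] / periods[None, :] + phases[None, :]
        )
    return tc


def planted_timecourse_sds(truth: GroundTruth, design: DesignSpec) -> np.ndarray:
    """Per-network temporal sd of the planted timecourses (task + slow term).

    The SNR convention of this generator: at a network-core voxel (map
    value 1) the signal sd of network k is this value, so
    ``noise_sd = planted_timecourse_sds(...).min() / snr`` puts the weakest
    planted network at the requested SNR and every other network above it.
    """
    regs = hrf.condition_regressors(design)
    task = regs @ truth.betas.T
    task_var = task.var(axis=0, ddof=0)
    slow_var = truth.slow_amp**2 / 2.0  # variance of a sinusoid
    return np.sqrt(task_var + slow_var)


def _jittered_maps(truth: GroundTruth, rng) -> np.ndarray:
    """(K, x, y, z) subject-specific maps.

    Inter-subject variability is modeled as smooth multiplicative amplitude
    modulation of each network: map * (1 + field), where field is a
    spatially smoothed Gaussian field rescaled to sd ``subject_map_jitter_sd``.
    Perturbations therefore live where the network lives, mimicking
    subject-to-subject differences in regional network expression.
    """
    maps = np.stack([m.values for m in truth.networks])
    if truth.subject_map_jitter_sd > 0:
        for k in range(maps.shape[0]):
            field_ = gaussian_filter(rng.standard_normal(maps.shape[1:]), sigma=1.0)
            sd = field_.std()
            if sd > 0:
                maps[k] *= 1.0 + truth.subject_map_jitter_sd * field_ / sd
    return maps


def simulate_subject(
    truth: GroundTruth, design: DesignSpec, subject_seed: int
) -> Volume4D:
    """One subject-run: sum over networks of map x timecourse, plus noise."""
    rng = np.random.default_rng(subject_seed)
    maps = _jittered_maps(truth, rng)                # K x grid
    tc = network_timecourses(truth, design, rng)     # T x K
    data = np.tensordot(maps, tc, axes=(0, 1))       # grid x T
    if truth.noise_sd > 0:
        data = data + rng.normal(0.0, truth.noise_sd, size=data.shape)
    vox = tuple(truth.networks[0].voxel_size_mm)
    return Volume4D(data, voxel_size_mm=vox, tr=design.tr)


def simulate_cohort(
    truth: GroundTruth, design: DesignSpec, n_subjects: int, seed: int = None
) -> list:
    """Simulate ``n_subjects`` runs with per-subject seeds spawned from ``seed``.

    Group t-tests need at least two subjects, so n_subjects < 2 is an error.
    Returns a list of Volume4D; persistence to disk is handled by
    :func:`fnoverlap.formats.write_cohort`.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 (group statistics undefined)")
    if seed is None:
        seed = truth.seed
    child_seeds = np.random.SeedSequence(seed).generate_state(n_subjects)
    return [simulate_subject(truth, design, int(s)) for s in child_seeds]


def cancellation_truth(
    seed: int = 0,
    grid_dims=DEFAULT_GRID,
    beta: float = 1.0,
    sigma_range=(2.0, 2.5),
    jitter_sd: float = 0.05,
    subject_beta_sd: float = 0.4,
    snr: float = 1.0,
    balance_tol: float = 0.15,
    design: DesignSpec = None,
):
    """Two overlapping networks with equal and opposite task betas.

    Each network has one private blob plus one blob of a closely offset
    pair, so the two maps overlap above half maximum while staying mildly
    correlated and hence separable for spatial ICA.

    Returns (truth, region): region is the boolean 3D array of *balanced*
    overlap — voxels where both maps exceed half maximum and their
    amplitudes differ by at most ``balance_tol`` — where the planted
    increases and decreases are equivalent, cancel in the summed BOLD
    signal, and leave no net effect for a voxelwise GLM. Voxels where one
    network clearly dominates are excluded: there the GLM is expected to
    detect the imbalance.
    """
    nets = make_network_library(2, grid_dims, overlap_spec=((0, 1),),
                                seed=seed, n_blobs=2, sigma_range=sigma_range)
    truth = GroundTruth(
        networks=nets, betas=np.array([[beta], [-beta]]), conditions=["task"],
        subject_map_jitter_sd=jitter_sd, subject_beta_sd=subject_beta_sd,
        seed=seed,
    )
    if design is None:
        design = make_design("block", n_events=8, tr=DEFAULT_TR,
                             n_timepoints=DEFAULT_T, seed=seed,
                             conditions=["task"])
    if snr > 0:
        truth.noise_sd = float(planted_timecourse_sds(truth, design).min()) / snr
    m0, m1 = nets[0].values, nets[1].values
    region = (m0 > 0.5) & (m1 > 0.5) & (np.abs(m0 - m1) <= balance_tol)
    return truth, region


def demo_truth(
    n_networks: int = 6,
    grid_dims=DEFAULT_GRID,
    overlap_spec=((0, 1), (2, 3), (4, 5)),
    conditions=("taskA", "taskB"),
    beta_pattern=None,
    snr: float = 1.0,
    jitter_sd: float = 0.05,
    seed: int = 0,
    design: DesignSpec = None,
) -> GroundTruth:
    """Reference cohort configuration used by presets, tests, and reports.

    Six networks, three overlapping pairs, betas cycling {+1, -1, 0} across
    networks so task-positive, task-negative, and task-neutral networks all
    occur, and noise_sd set so the SNR at network-core voxels equals
    ``snr`` (default 1).
    """
    nets = make_network_library(n_networks, grid_dims, overlap_spec, seed=seed)
    n_c = len(conditions)
    if beta_pattern is None:
        # signs cycle {+, -, 0}; magnitudes differ per network so no two
        # networks have collinear task timecourses
        cycle = [1.0, -1.0, 0.0]
        beta_pattern = np.array(
            [[cycle[(k + c) % 3] * (1.0 + 0.1 * k) for c in range(n_c)]
             for k in range(n_networks)]
        )
    truth = GroundTruth(
        networks=nets, betas=np.asarray(beta_pattern, dtype=float),
        conditions=list(conditions), noise_sd=0.0,
        subject_map_jitter_sd=jitter_sd, seed=seed,
    )
    if design is None:
        design = make_design(
            "block", n_events=8, tr=DEFAULT_TR, n_timepoints=DEFAULT_T,
            seed=seed, conditions=conditions,
        )
    if snr > 0:
        truth.noise_sd = float(planted_timecourse_sds(truth, design).min()) / snr
    return truth
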