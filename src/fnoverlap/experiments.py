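"""End-to-end study drivers on synthetic cohorts.

Each function here reproduces one analysis of the pipeline under the
reference study conditions — the conditions the synthetic-data module
defines as its defaults (8 subjects, 20x20x12 grid at 3 mm, TR 1.5 s,
T = 150, six planted networks with three overlapping pairs, SNR 1 at the
weakest network) — and returns the quantities the analysis measures.
They are what `scripts/acceptance.py` and the acceptance-level tests run.
"""

from __future__ import annotations

import numpy as np

from . import glmcompare, groupica, match, netstats, preprocess, sorting, synthio


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic child seeds below 2**31."""
    return np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF


def reference_cohort(seed: int, n_subjects: int = 8, snr: float = 1.0):
    """The study cohort: planted networks, design, volumes, mask, and the
    planted maps in mask scan order."""
    truth = synthio.demo_truth(seed=seed, snr=snr)
    design = synthio.make_design("block", n_events=8, seed=seed,
                                 conditions=truth.conditions)
    volumes = synthio.simulate_cohort(truth, design, n_subjects, seed=seed)
    mask = preprocess.compute_mask(volumes)
    planted = np.stack([
        preprocess.to_matrix(m.values[..., None], mask)[0]
        for m in truth.networks
    ])
    return truth, design, volumes, mask, planted


def network_recovery(seed: int, n_subjects: int = 8, n_ics: int = 10,
                     n_icasso: int = 10) -> dict:
    """Group ICA on the reference cohort; optimal one-to-one matching of
    planted maps to recovered group maps by |spatial r|."""
    truth, design, volumes, mask, planted = reference_cohort(seed, n_subjects)
    cfg = groupica.ICAConfig(n_ics=n_ics, n_icasso_runs=n_icasso, seed=seed)
    result = groupica.run_group_ica(volumes, mask, cfg)
    table = match.match_maps(planted, result.group_maps)
    r = table.pairs["r"].to_numpy()
    signal_ids = table.pairs["ic_b"].to_numpy()
    signal_iq = result.stability_report.iq[signal_ids]
    return {
        "per_network_r": r,
        "min_r": float(r.min()),
        "mean_r": float(r.mean()),
        "signal_iq": signal_iq,
        "match": table,
        "result": result,
        "truth": truth,
        "design": design,
        "mask": mask,
        "planted": planted,
    }


def expected_label(beta: float) -> str:
    return "positive" if beta > 0 else ("negative" if beta < 0 else "neutral")


def classification_recovery(seed: int, n_subjects: int = 8,
                            alpha: float = 0.05) -> dict:
    """Temporal sorting + classification on timecourses back-reconstructed
    from the planted maps; fraction of network x condition labels correct."""
    truth, design, volumes, mask, planted = reference_cohort(seed, n_subjects)
    tcs = [
        groupica.back_reconstruct(
            preprocess.standardize(v, mask)[0], planted)[1]
        for v in volumes
    ]
    regs = sorting.hrf_convolve(design)
    cls = sorting.classify_fns(sorting.sort_timecourses(tcs, regs),
                               alpha=alpha)
    correct = total = 0
    for k in range(len(truth.networks)):
        for c, cond in enumerate(truth.conditions):
            want = expected_label(truth.betas[k, c])
            got = cls[(cls.ic == k) & (cls.condition == cond)]["label"].iloc[0]
            correct += want == got
            total += 1
    return {"accuracy": correct / total, "n_pairs": total,
            "classification": cls}


def null_label_calibration(seed: int, n_cohorts: int = 200,
                           n_subjects: int = 8, alpha: float = 0.05) -> dict:
    """All planted betas zero: fraction of non-neutral labels across
    simulated cohorts (should not exceed the FDR level)."""
    nonneutral = total = 0
    for rep_seed in _child_seeds(seed, n_cohorts):
        rep_seed = int(rep_seed)
        truth = synthio.demo_truth(
            n_networks=4, overlap_spec=((0, 1), (2, 3)),
            beta_pattern=np.zeros((4, 2)), snr=0, seed=rep_seed)
        truth.noise_sd = truth.slow_amp / np.sqrt(2)  # weakest-network SNR 1
        design = synthio.make_design("block", n_events=8, seed=rep_seed,
                                     conditions=truth.conditions)
        volumes = synthio.simulate_cohort(truth, design, n_subjects,
                                          seed=rep_seed)
        mask = preprocess.compute_mask(volumes)
        planted = np.stack([
            preprocess.to_matrix(m.values[..., None], mask)[0]
            for m in truth.networks
        ])
        tcs = [
            groupica.back_reconstruct(
                preprocess.standardize(v, mask)[0], planted)[1]
            for v in volumes
        ]
        cls = sorting.classify_fns(
            sorting.sort_timecourses(tcs, sorting.hrf_convolve(design)),
            alpha=alpha)
        nonneutral += int((cls["label"] != "neutral").sum())
        total += len(cls)
    return {"rate": nonneutral / total, "n_labels": total}


def cancellation_experiment(seed: int, n_subjects: int = 8, n_ics: int = 4,
                            n_icasso: int = 5, fdr_level: float = 0.01,
                            n_permutations: int = 256) -> dict:
    """Two equal-amplitude opposite networks overlapping in a balanced
    region R: fraction of R the GLM marks significant, and fraction of R
    where the overlap map records >= 2 masks with one positive and one
    negative FN label."""
    truth, region3d = synthio.cancellation_truth(seed=seed)
    design = synthio.make_design("block", n_events=8, seed=seed,
                                 conditions=["task"])
    volumes = synthio.simulate_cohort(truth, design, n_subjects, seed=seed)
    mask = preprocess.compute_mask(volumes)
    R = preprocess.to_matrix(region3d[..., None].astype(float), mask)[0] > 0.5
    planted = np.stack([
        preprocess.to_matrix(m.values[..., None], mask)[0]
        for m in truth.networks
    ])

    cfg = groupica.ICAConfig(n_ics=n_ics, n_icasso_runs=n_icasso, seed=seed)
    result = groupica.run_group_ica(volumes, mask, cfg)
    regs = sorting.hrf_convolve(design)
    cls = sorting.classify_fns(
        sorting.sort_timecourses(result.subject_timecourses, regs))
    labels = sorting.fn_labels(cls)
    masks = []
    for k in range(result.n_ics):
        tm = netstats.group_t_map(
            np.stack([m[k] for m in result.subject_maps]))
        pos, neg = netstats.fdr_threshold(tm, level=fdr_level, ic_id=k)
        masks.extend([pos, neg])
    overlap = netstats.overlap_map(masks)

    cmaps = []
    for v in volumes:
        X, _, _ = preprocess.standardize(v, mask)
        vol = synthio.Volume4D(
            np.stack([preprocess.unmask(X[t], mask)
                      for t in range(X.shape[0])], axis=-1),
            mask.voxel_size_mm, design.tr)
        cmaps.append(glmcompare.fit_subject_glm(vol, regs, [1.0], mask))
    glm = glmcompare.group_cluster_inference(
        cmaps, mask, n_permutations=n_permutations, seed=seed)
    sig = glm.significance_vector()

    label_of = {(r.ic, r.polarity): r.fn_label
                for r in labels[labels.condition == "task"].itertuples()}
    pos_cov = np.zeros(mask.n_voxels, dtype=bool)
    neg_cov = np.zeros(mask.n_voxels, dtype=bool)
    for m in masks:
        lab = label_of[(m.ic_id, m.polarity)]
        if lab == "positive":
            pos_cov |= m.values
        elif lab == "negative":
            neg_cov |= m.values
    detected = (overlap.counts >= 2) & pos_cov & neg_cov
    exclusive = (planted[0] > 0.7) & (planted[1] < 0.2)
    report = glmcompare.cancellation_report(
        glm, overlap, labels[labels.condition == "task"], masks)
    return {
        "n_region_voxels": int(R.sum()),
        "glm_significant_fraction": float(sig[R].mean()),
        "overlap_detected_fraction": float(detected[R].mean()),
        "glm_exclusive_fraction": float(sig[exclusive].mean()),
        "report": report,
    }


def additivity_experiment(seed: int) -> dict:
    """Noiseless cohort: GLM contrast of the summed component
    reconstruction vs the data, per planted region."""
    truth = synthio.demo_truth(seed=seed, snr=0, jitter_sd=0.0)
    truth.noise_sd = 0.0
    truth.subject_beta_sd = 0.0
    design = synthio.make_design("block", n_events=8, seed=seed,
                                 conditions=truth.conditions)
    volumes = synthio.simulate_cohort(truth, design, 3, seed=seed)
    mask = preprocess.compute_mask(volumes)
    planted = np.stack([
        preprocess.to_matrix(m.values[..., None], mask)[0]
        for m in truth.networks
    ])
    regs = sorting.hrf_convolve(design)
    contrast = np.zeros(len(truth.conditions))
    contrast[0] = 1.0
    X = preprocess.standardize(volumes[0], mask)[0]
    smaps, stcs = groupica.back_reconstruct(X, planted)
    discrepancies = []
    for k in range(len(truth.networks)):
        rep = glmcompare.additivity_check(
            X, smaps, stcs, regs, contrast, planted[k] > 0.5)
        discrepancies.append(rep["relative_discrepancy"])
    half_maps, half_tcs = groupica.back_reconstruct(X, planted[:3])
    truncated = glmcompare.additivity_check(
        X, half_maps, half_tcs, regs, contrast, planted[4] > 0.5)
    return {
        "per_region": np.asarray(discrepancies),
        "max_relative_discrepancy": float(max(discrepancies)),
        "truncated_discrepancy": truncated["relative_discrepancy"],
    }


def stability_experiment(seed: int, snr_levels=(2.0, 1.0, 0.5),
                         n_ics: int = 10, n_icasso: int = 10) -> dict:
    """Signal-component stability indices across decreasing SNR."""
    mean_iq = []
    min_iq_at_snr1 = None
    for snr in snr_levels:
        truth, design, volumes, mask, planted = reference_cohort(
            seed, snr=snr)
        cfg = groupica.ICAConfig(n_ics=n_ics, n_icasso_runs=n_icasso,
                                 seed=seed)
        result = groupica.run_group_ica(volumes, mask, cfg)
        table = match.match_maps(planted, result.group_maps)
        iq = result.stability_report.iq[table.pairs["ic_b"].to_numpy()]
        mean_iq.append(float(iq.mean()))
        if snr == 1.0:
            min_iq_at_snr1 = float(iq.min())
    return {
        "snr_levels": list(snr_levels),
        "mean_signal_iq": mean_iq,
        "min_signal_iq_at_snr1": min_iq_at_snr1,
        "monotone_decreasing": all(
            a > b for a, b in zip(mean_iq, mean_iq[1:])),
    }


def cross_cohort_experiment(seed: int, n_subjects: int = 8, n_ics: int = 10,
                            n_icasso: int = 10,
                            threshold: float = 0.5) -> dict:
    """Two independently simulated cohorts sharing one GroundTruth: for
    each planted network, the spatial r between the two cohorts'
    recovered components."""
    truth = synthio.demo_truth(seed=seed, snr=1.0)
    design = synthio.make_design("block", n_events=8, seed=seed,
                                 conditions=truth.conditions)
    cohort_seeds = _child_seeds(seed + 1, 2)
    group_maps, mask = [], None
    for cseed in cohort_seeds:
        volumes = synthio.simulate_cohort(truth, design, n_subjects,
                                          seed=int(cseed))
        mask = preprocess.compute_mask(volumes)
        cfg = groupica.ICAConfig(n_ics=n_ics, n_icasso_runs=n_icasso,
                                 seed=int(cseed))
        group_maps.append(groupica.run_group_ica(volumes, mask, cfg).group_maps)
    planted = np.stack([
        preprocess.to_matrix(m.values[..., None], mask)[0]
        for m in truth.networks
    ])
    match_a = match.match_maps(planted, group_maps[0])
    match_b = match.match_maps(planted, group_maps[1])
    r_ab, _ = match.correlate_maps(group_maps[0], group_maps[1])
    cross_r = []
    for k in range(len(truth.networks)):
        a = int(match_a.pairs.loc[match_a.pairs.ic_a == k, "ic_b"].iloc[0])
        b = int(match_b.pairs.loc[match_b.pairs.ic_a == k, "ic_b"].iloc[0])
        cross_r.append(float(r_ab[a, b]))
    cross_r = np.asarray(cross_r)
    return {
        "per_network_cross_r": cross_r,
        "fraction_matched": float((cross_r >= threshold).mean()),
        "threshold": threshold,
    }


def fwe_calibration(seed: int, n_cohorts: int = 200, n_subjects: int = 8,
                    grid=(12, 12, 8), smooth_sigma: float = 1.5,
                    cluster_alpha: float = 0.05,
                    n_permutations: int = 256) -> dict:
    """Family-wise error of the permutation cluster test on null cohorts of
    spatially smooth Gaussian subject maps (reduced grid)."""
    from scipy.ndimage import gaussian_filter

    from .formats import BrainMask

    mask = BrainMask(np.ones(grid, dtype=np.uint8))
    families_with_error = 0
    for rep_seed in _child_seeds(seed, n_cohorts):
        rng = np.random.default_rng(int(rep_seed))
        maps = []
        for _ in range(n_subjects):
            field = gaussian_filter(rng.standard_normal(grid),
                                    sigma=smooth_sigma)
            maps.append(field.ravel(order="F"))
        res = glmcompare.group_cluster_inference(
            maps, mask, cluster_alpha=cluster_alpha,
            n_permutations=n_permutations, seed=int(rep_seed))
        if any(c.significant for c in res.clusters):
            families_with_error += 1
    return {"fwe_rate": families_with_error / n_cohorts,
            "n_cohorts": n_cohorts, "cluster_alpha": cluster_alpha}
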