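# fnoverlap

Task fMRI analyses built on the general linear model (GLM) report
activation, deactivation, or no change as mutually exclusive states of
each voxel. Spatial independent component analysis (sICA) starts from a
different premise — the BOLD signal at a voxel is a linear mixture of
source signals — and routinely finds that *functional networks* (FNs)
with different task modulation overlap in the same voxels: one source in
a region can increase with the task while another, co-localized source
decreases, and their sum shows the GLM nothing at all.

`fnoverlap` is a tested, reusable pipeline for studying exactly this
phenomenon: group spatial ICA with stability assessment, temporal sorting
of component timecourses into task-positive / task-negative /
task-neutral FNs, voxelwise overlap accounting, a voxelwise-GLM
comparison arm with permutation cluster inference, and cross-dataset
component matching. Because real multi-subject fMRI is large and slow,
every stage is exercised end-to-end on *synthetic* 4D cohorts with known
planted networks, so each claim the pipeline makes can be checked against
ground truth. It is aimed at methods researchers who want a transparent,
fully seeded reference implementation of the sICA-overlap analysis.

## The model

Simulated (and assumed) data follow the linear mixture

```
x(v, t) = Σ_k  m_k(v) · c_k(t)  +  ε(v, t),        ε ~ N(0, σ²)
c_k(t)  = Σ_j  β_kj(s) · r_j(t)  +  slow_k(t)
```

where `m_k` are spatial network maps (sums of 3D Gaussian blobs, pairs of
which overlap), `r_j` are task-condition regressors (boxcars convolved
with the canonical double-gamma HRF, peak-normalized), `β_kj(s)` are
per-condition network betas with per-subject engagement variability, and
`slow_k` is a slow sinusoidal fluctuation that gives task-neutral
networks variance for ICA to find.

The analysis inverts the mixture: per-subject standardization → subject
and group PCA of the temporally concatenated cohort → natural-gradient
Infomax ICA (spatial sources, logistic nonlinearity) repeated with random
restarts and clustered ICASSO-style (stability index
Iq = mean intra-cluster − mean extra-cluster |r|) → dual-regression
back-reconstruction of subject maps and timecourses → one-sample t-maps
per component, thresholded by Benjamini–Hochberg FDR and split by sign
into positive/negative sub-network masks → mask summation into overlap
maps (counts ≥ 2 mark FN overlap) → temporal sorting: OLS of each IC
timecourse on the design matrix, one-sample t of run-averaged betas over
subjects with BH across ICs, labelling each IC (and hence its
sub-networks) positive / negative / neutral per condition. The GLM arm
fits the same design voxelwise and performs group inference by sign-flip
permutation of subject contrast maps with a max-cluster-extent null.

## Worked example

Recover six planted, partially overlapping networks from a synthetic
8-subject cohort (20×20×12 grid, TR 1.5 s, 150 volumes, SNR 1 at the
weakest network), then classify their task modulation:

```python
import numpy as np
from fnoverlap import experiments

out = experiments.network_recovery(seed=1, n_ics=10, n_icasso=10)
print("per-network |r|:", np.round(out["per_network_r"], 3))
print("signal-component Iq:", np.round(out["signal_iq"], 3))

cls = experiments.classification_recovery(seed=1)
print(cls["classification"].head(6).to_string(index=False))
```

prints

```
per-network |r|: [0.924 0.891 0.896 0.909 0.933 0.94 ]
signal-component Iq: [0.993 0.991 0.987 0.989 0.991 0.986]
 ic condition  mean_beta          t            p        p_fdr    label
  0     taskA   1.436795  29.756893 1.247447e-08 1.871170e-08 positive
  1     taskA  -2.287191 -46.307096 5.725834e-10 1.717750e-09 negative
  2     taskA  -0.180903  -2.814148 2.599065e-02 3.118879e-02 negative
  3     taskA   1.468893  83.343827 9.425409e-12 5.655245e-11 positive
  4     taskA  -2.398927 -41.951199 1.140777e-09 2.281554e-09 negative
  5     taskA   0.146322   1.135494 2.935466e-01 2.935466e-01  neutral
```

Every planted map is matched by a recovered group component at spatial
|r| ≈ 0.9 under optimal one-to-one assignment, and the matched
components are highly stable across Infomax restarts (Iq ≈ 0.99). The
classification table gives each component's group-mean beta weight for
condition `taskA`, the one-sample t over the 8 subjects, raw and
FDR-adjusted p, and the resulting FN label; here 11 of the 12
network × condition labels match the planted pattern.

The same analyses are available from the shell:

```
fnoverlap simulate --preset attention-mini --seed 1 --out cohort/
fnoverlap ica --cohort cohort/manifest.json --n-ics 10 --icasso 10 --seed 1 --out ica/
fnoverlap sort --ica ica/ --events cohort/events.tsv --alpha 0.05 --out sort/
fnoverlap report --preset attention-mini --seed 1 --out report/
```

`report` writes classification, volume-summary, maximum-overlap and GLM
cluster tables, the cancellation report, the overlap map as NIfTI, and a
JSON-lines run log recording every seed and threshold.

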