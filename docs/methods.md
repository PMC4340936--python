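# Methods

## Generative model of the synthetic cohorts

A cohort is a set of subject-runs on a common voxel grid (default
20×20×12 voxels at 3 mm isotropic, TR 1.5 s, 150 volumes — small enough
for minutes-scale group ICA while keeping the proportions of a typical
EPI acquisition). Each run is

    x_s(v, t) = Σ_k m_{sk}(v) · c_{sk}(t) + ε_s(v, t)

with K planted networks. All parameters live in `GroundTruth`; every
random quantity is drawn from an explicit seed and per-subject seeds are
spawned deterministically from the cohort seed, so cohorts are
bit-reproducible.

**Spatial maps.** Each network map is a sum of 3D Gaussian blobs with sd
drawn from 1.5–2.2 voxels (half-width at half maximum about 2–3.5
voxels), unit-normalized to max 1. Blobs of one network are kept ≥ 2.3 sd
apart so each blob is a local maximum above half max; blobs of different
networks may sit closer — between-network overlap is the phenomenon under
study. A pair listed in the overlap specification receives two equal-sd
blobs whose centers sit 1.8 sd apart with the midpoint snapped to a voxel
center, guaranteeing a non-empty half-maximum intersection while keeping
the pair's spatial correlation near 0.2–0.4. Fully coincident blobs were
rejected deliberately: they make the sources spatially dependent, and a
spatially dependent "pair" is not identifiable by spatial ICA — its
independent decomposition is {shared part, private parts}, which is what
ICA then correctly returns.

**Timecourses.** Condition regressors are built by placing unit boxcars
on a 0.1 s grid, convolving with the canonical double-gamma HRF (response
peak 6 s, undershoot 16 s, peak/undershoot ratio 6), sampling at TR, and
peak-normalizing to 1 so betas read as response amplitudes. Network k's
timecourse for subject s is `Σ_j β_kj (1 + η_sk) r_j(t) + slow`, where
η_sk ~ N(0, subject_beta_sd²) models between-subject differences in task
engagement (default sd 0.25; without it, betas identical across subjects
let the random-effects group t detect arbitrarily small systematic
effects, which no real cohort does). The slow term is a sinusoid of
amplitude 0.3 with per-network random phase and period drawn in
45–75 s; it gives task-neutral networks variance for ICA to find and
keeps networks sharing a beta-sign pattern temporally distinguishable.
The reference beta pattern cycles {+1, −1, 0} across network × condition
with per-network magnitudes 1.0 + 0.1k, so positive, negative, and
neutral labels all occur and no two networks have collinear task
timecourses.

**Subject variability and noise.** Subject maps are the group maps under
smooth multiplicative amplitude modulation, `m·(1 + field)`, with the
field a σ=1-voxel-smoothed Gaussian field rescaled to sd
`subject_map_jitter_sd` (default 0.05). Multiplicative (not additive)
modulation keeps the perturbation where the network lives; an additive
whole-grid field of the same sd carries ~40% of a map's norm and behaves
like global structured noise rather than inter-subject variability.
Voxel noise is iid Gaussian. **SNR convention:** `noise_sd` is set so
that at a network-core voxel (map value 1) the *weakest* planted
network's timecourse sd equals `snr × noise_sd`; every other network then
sits at or above the stated SNR. The default study condition is SNR 1.

**What the generator does not emulate:** physiological (cardiac /
respiratory) noise, head motion, scanner drift beyond the slow sinusoid,
spatial autocorrelation of the noise, field inhomogeneity, and
anatomical tissue classes. Passing tests therefore demonstrate that the
pipeline's inference machinery is correct under the linear-mixture model
with white noise — not that it is robust to every artifact of real
acquisitions.

## Group spatial ICA

Per subject, in-mask voxel time series are demeaned (variance
normalization is available but off by default: dividing each voxel by its
total sd — signal included — flattens the spatial contrast of source
maps enough to cap achievable map recovery around r ≈ 0.8 on these
cohorts). Temporal reduction is two-stage PCA: each subject is reduced to
1.5 × (model order) dimensions by SVD, subjects are concatenated along
the reduced temporal axis, and a group PCA keeps exactly the model order.
The retained rows are whitened by SVD (identity sample covariance over
voxels).

Infomax maximizes the entropy of `g(W Y)` with the logistic nonlinearity
— maximum likelihood for super-Gaussian (sparse) spatial sources.
Implementation: natural-gradient updates on randomly permuted blocks of
voxels per sweep, block size ⌈√(V/3)⌉, initial learning rate
0.015 / max(ln K, 1) (the max guards the K=1 edge case), rate annealed by
0.9 whenever successive weight updates turn by more than 60°,
convergence when the relative weight change per sweep falls below 1e-6,
at most 512 sweeps; on divergence (non-finite or exploding weights) the
run restarts from the same initialization with a halved rate, up to five
times. Sources are scaled to unit variance and oriented so each
component's largest-|weight| voxel is positive — the convention that
makes "positive sub-network" well defined; orientation is applied
jointly to maps and timecourses, leaving their product invariant.

**Stability (ICASSO).** The decomposition is repeated from
`n_icasso_runs` random orthogonal initializations (default 50; desk-scale
runs use 10 — restarts, not bootstrap resampling, are what the repeat
count controls here). Pooled components are clustered by average-linkage
agglomeration on distance 1 − |Pearson r| cut at the model order, and
each cluster gets the stability index

    Iq = mean within-cluster |r| − mean |r| to all out-of-cluster components,

taken as normative for this package. The cluster centrotype (member with
the highest mean within-cluster similarity) becomes the final group
component, so reported maps are actual ICA solutions, not averages.
Components are ordered by decreasing Iq.

**Back-reconstruction** is spatial–temporal (dual) regression: subject
timecourses from regressing the subject's data on the group maps across
voxels, subject maps from regressing the data on those timecourses across
time. The PCA-based reconstruction variant is not implemented; dual
regression is fully specified from first principles and makes the
additivity identity below exact on noiseless data. Degenerate (e.g.
constant) timecourses fall back to the minimum-norm stage-2 solution;
collinear group maps are an error naming the offending pairs.

## Sub-networks, overlap, and temporal sorting

Per component, a voxelwise one-sample t over subject maps is thresholded
by Benjamini–Hochberg FDR over in-mask voxels (zero-variance voxels are
excluded from the pool and reported t=0, p=1). "Voxel p < .001
FDR-corrected" is read as BH at q = 0.001; q is a config knob, and the
desk-scale experiments use q = 0.01 because at 8 subjects (df 7) the
q = 0.001 threshold corresponds to t ≈ 7.5 and erases moderate-weight
voxels — the stricter default presumes cohorts of dozens of subjects.
Surviving voxels split by t sign into the positive and negative
sub-network masks (the two FNs of the IC); masks sum voxelwise into
integer overlap maps whose counts ≥ 2 mark FN overlap, with integer
conservation guaranteed by construction.

Temporal sorting regresses each IC timecourse (standardized to unit
variance so betas are comparable across ICs) on the HRF design matrix
with intercept, averages betas across runs within subject (unweighted),
tests the group mean beta against zero per IC, and corrects BH across ICs
within each condition at α = .05. A significantly positive beta makes
the IC's positive sub-network a positive FN and its negative sub-network
a negative FN; a significant negative beta flips both; otherwise both
FNs are neutral. Labels are kept per condition — an IC may be positive
in one condition and neutral in another — and are never collapsed to a
single per-IC label. Paired t-tests compare conditions within task, BH
across ICs; zero-variance nonzero differences are flagged degenerate
with p → 0.

Spectral artifact indicators follow common sICA practice: the ratio of
integrated periodogram power below 0.10 Hz to power in 0.15–0.25 Hz
(Hann window, mean over subject runs; band truncated at Nyquist with a
warning when TR is long), the dynamic range of the lightly smoothed
spectrum, and — when tissue masks are supplied — whether the peak |t|
voxel falls in white matter or CSF. Flags are advisory; components are
never deleted automatically.

## GLM comparison arm

Subject-level analysis is voxelwise OLS on the same design matrix;
contrast maps are c'β̂. Group inference is a one-sample t over subject
contrast maps with voxel height threshold p < 0.01 (two-sided),
26-connected clusters formed separately for positive and negative t, and
cluster-extent FWE by sign-flip permutation: under the null the subject
maps are sign-symmetric, so the maximum supra-threshold cluster extent
over random sign flips gives the corrected p for each observed cluster.
When the requested permutation count reaches 2^n subjects the null is
enumerated exhaustively and the result is deterministic. Random-field
theory is deliberately replaced by this permutation scheme: it is exact
under exchangeability and fully specifiable. No autocorrelation
prewhitening is implemented — the synthetic noise is iid by
construction.

Calibration note: with *iid* null subject maps the supra-threshold
clusters at df 7 are near-singletons, the integer max-extent null is
heavily tied, and the test is conservative (empirical FWE ≈ 0.005 at
nominal 0.05) — valid but below nominal. With spatially smooth null maps
(σ = 1.5 voxels), the realistic case for fMRI contrast maps, empirical
FWE is 0.035–0.045. The calibration experiment therefore uses smooth
nulls.

**Cancellation.** The experiment plants two networks with equal and
opposite betas whose maps overlap above half maximum via closely offset
equal-sd blobs, with between-subject engagement sd 0.4. The interrogated
region R is the *balanced* overlap — voxels where both maps exceed half
maximum and differ by at most 0.15 — which operationalizes "concurrent
increases and decreases that are equivalent and cancel". Where one
network clearly dominates (the lens edges and the private blobs) the GLM
is expected to, and does, detect the imbalance; inside R it detects
nothing while the overlap map records ≥ 2 sub-network masks with one
positive and one negative FN label.

**Additivity.** On noiseless data the dual-regression reconstruction
Σ_k map_k ⊗ timecourse_k equals the data, so the GLM contrast of the
reconstruction matches the GLM contrast of the data to numerical
precision in every planted region; truncating the component set breaks
the identity monotonically. This is the decomposition-level counterpart
of "component-wise task effects sum to the voxelwise task effect".

## Cross-dataset matching

Goodness of fit between two decompositions is the Pearson correlation of
component maps over in-mask voxels, with ICA's sign ambiguity resolved
per pair by taking the orientation that maximizes r (the chosen sign is
recorded). Matching is a globally optimal one-to-one assignment
maximizing total |r| (Hungarian algorithm; a greedy mode exists for
parity with ad-hoc practice), and pairs with r ≥ 0.5 are flagged "highly
correlated" — the conventional criterion for calling two components the
same network. The cross-cohort experiment simulates two cohorts from one
GroundTruth with independent cohort seeds and asks how many planted
networks are matched across the two decompositions at that criterion.

## Reference experiment sizes

The experiments module fixes the study conditions: 8 subjects, six
networks with three overlapping pairs, 10 ICs, 10 ICASSO restarts, SNR 1
(criteria-style analyses); 200 cohorts for the null-label calibration
(4 networks, all betas 0) and for FWE calibration (12×12×8 grid, 256
sign flips); 3 SNR levels (2, 1, 0.5) for the stability-degradation
check. These sizes keep a full recomputation at a few minutes on one CPU
while leaving each statistic enough replicates for binomial error bars.

## Known limitations

- The noise model is white; autocorrelated or structured noise would
  require prewhitening in the sorting and GLM stages and is out of scope.
- Model order is user-chosen; there is no automatic order selection, and
  the stability report is the intended diagnostic for over-splitting.
- Exact co-location of opposite-beta networks is unidentifiable for
  spatial ICA by construction; the pipeline detects overlap of
  *distinct-but-overlapping* networks, which is also the configuration
  the analysis is scientifically about.
- Artifact flagging reproduces spectral indicators only; the visual
  inspection used alongside them in practice has no automated stand-in
  here.
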