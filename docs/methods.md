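# Methods

## The problem

Seed-based resting-state functional connectivity places a small region of
interest (ROI) at each node of a functional brain network, extracts the
mean BOLD time series per ROI, and correlates the series pairwise.  Almost
universally the same ROI coordinates are used for every subject — taken
from published coordinates ("literature ROIs") or from the peaks of a group
ICA map ("group ROIs").  Because the true location of a network node varies
across individuals, a standardized ROI misses the node for some subjects,
and the extracted series is then mostly noise: calculated connectivity
drops and its spread across subjects grows, and downstream graph-theoretic
comparisons (e.g. between age groups) can report "effects" that are really
changes in spatial organization, not in coupling.

`roifc` implements the individualized alternative together with everything
needed to demonstrate the contrast on synthetic data with known ground
truth.  The subject-specific route reconstructs each subject's network by
regressing the network's group-ICA *time course* (that subject's segment of
the concatenated mixing matrix) voxelwise in that subject's own data,
converts the slope t statistics to z, and centres a 6 mm cubic ROI on the
peak z inside each node's search region.  The battery therefore differs
across subjects and follows each individual's spatial layout.

## Synthetic cohorts

Each subject's 4D volume is

    y(v, t) = sum_j w_j(v) x_j(t) + sigma_n eps(v, t) [+ nuisance],

where node `j` has an isotropic Gaussian footprint `w_j` (FWHM
`blob_fwhm_mm`) centred on that subject's realized node position, `x_j` are
node signals with unit SD, and `eps` is white noise.  Realized positions
are canonical positions plus i.i.d. per-axis Gaussian jitter
(`jitter_sd_mm`); draws are rejection-resampled to 4 SDs per component so a
compliant battery (canonical centres at least 4 SD inside the grid) can
never fall off the grid.  Node signals are band-limited (0.01–0.1 Hz)
Gaussian processes, empirically whitened and mixed through the Cholesky
factor of the target correlation matrix, so each subject's *sample* node
correlation equals the target exactly — the planted truth is exact, not
asymptotic.  The target matrix has `within_corr` inside networks,
`between_corr` across them, with per-pair overrides; the default couples
the two default-mode sub-networks (aDMN–pDMN) at r = 0.6, all other
cross-network pairs at 0.1.  Optional structured nuisance adds a CSF-like
core field and a WM-like shell field with their own band-limited time
courses; the default pipeline runs without nuisance regression, and the
partial-correlation path is an opt-in validation route.

Key defaults and why:

| parameter | default | rationale |
|---|---|---|
| voxel size | 2 mm isotropic | template-space resolution of registered data |
| TR | 3 s | typical long-TR resting acquisition |
| timepoints | 100 | ≈ 5 min run at TR 3 s |
| `within_corr` | 0.8 | strong within-network coherence of clean node signals |
| aDMN–pDMN coupling | 0.6 | the two sub-systems behave as one fractionated network |
| `between_corr` | 0.1 | weak background coupling between distinct systems |
| `jitter_sd_mm` | 6 | per-axis SD; mean 3D displacement ≈ 9.6 mm, a plausible scale for functional variability (no quantitative literature value exists; this is a modeling choice) |
| `noise_sd` | 1.0 | voxel SNR ≈ 1 at a blob centre |
| `blob_fwhm_mm` | 14 (default battery) | node extent comparable to cortical hubs; see geometry notes |
| grid | 58×98×58 @ 2 mm | fits the 30-node battery with 4·8 mm jitter margins |

### Default battery geometry

The default battery plants five networks (aDMN, pDMN, FPNL, FPNR, SAL) of
six nodes each — a 30-seed battery, matching the convention that a
five-network seed analysis uses 30 seeds and an edgewise family of
C(30,2) = 435 pairs.  (A separate `named_battery()` provides the
conventional printed label set — aDMN 6, pDMN 4, FPNL 7, FPNR 7, SAL 5 —
which totals 29 labels; the 29-vs-30 mismatch is a known quirk of that
convention and is surfaced, not resolved.)  Placement is deliberate:

* same-network nodes are ≥ 33 mm apart, so a peak-search sphere (24 mm in
  the packaged study) can never reach a sibling node and collapse two ROIs
  onto one blob;
* the coupled aDMN/pDMN pair sits at opposite ends of the long axis
  (≥ 85 mm), because a subject map of one sub-network also shows the
  other's blobs (their time courses correlate 0.6) and proximity would let
  peaks jump between them;
* uncoupled neighbours are ~23 mm apart — overlapping gently like adjacent
  cortical systems but far outside each other's search spheres.

## Analysis pipeline

Preprocessing follows the minimal convention for registered resting-state
data: temporal high-pass by subtracting a Gaussian-weighted running-line
fit (sigma 100 s), implemented literally as a per-timepoint weighted
least-squares line (not an FFT approximation) and validated against a
brute-force oracle; spatial smoothing with a 4 mm FWHM Gaussian,
zero-padded and renormalized by the smoothed mask so constants are
preserved and mask edges do not darken; framewise displacement in the
Power form (|Δtranslations| + 50 mm · |Δrotations|) for motion QC.

Group ICA concatenates variance-normalized in-mask subject data in time,
reduces by eigendecomposition of the temporal covariance to `n_components`
(default 30), and unmixes spatially by fixed-point negentropy maximization
with a logcosh contrast.  Maps are z-scored over in-mask voxels with the
sign convention that the peak-|z| voxel is positive; the mixing matrix is
recomputed by least squares against the final maps so subject segments are
exact.  Components are matched to network templates by spatial correlation
of |z| maps (floor 0.2, ties to the lower index) — the selection criterion
among components is not standardized in the field, and template matching
is the implemented proxy.

ROI batteries: *literature* cubes at fixed a-priori mm coordinates
(nearest voxel, lexicographic tie-break at midpoints); *group* cubes at
the peak z of the matched group map inside each node's search sphere;
*subject-specific* cubes at the peak z of the subject's own reconstructed
map.  All cubes are 6 mm, containing 27 voxels at 2 mm resolution (voxel
centres in the half-open cube, inclusive on the low side, so counts are
deterministic).  Per-subject time courses are the subject's segment of the
group mixing column, demeaned to unit variance; the spatial-regression
(dual-regression stage-1) alternative is deliberately not the default —
the method regresses the time course, not the spatial map.

Connectivity is plain Pearson correlation of ROI mean series (partial
correlation when nuisance regressors are supplied); matrices are averaged
across subjects without Fisher transform by default (a Fisher option
exists).  Graphs binarize at r > 0.35 strictly; metrics are mean
clustering coefficient, global efficiency, degree assortativity and
Louvain modularity (best of 20 seeded restarts).  Group contrasts use
classic pooled-variance unpaired t tests per node pair with Bonferroni
correction over all C(n,2) pairs (α/435 for 30 nodes); method contrasts
use paired t tests.  Undefined values (constant series, regular-graph
assortativity, zero-variance paired differences) are NaN-flagged with a
warning and excluded from summaries — never silently zeroed.

## The packaged studies

`roifc.study.run_roi_method_study` generates one 20-subject cohort
(jitter SD 6 mm, SNR ≈ 1), runs the full pipeline and compares the three
ROI methods: per-subject mean within-network connectivity, its
across-subject variance, paired t tests between methods, the pooled
relation between a ROI's mean z on the subject's reconstructed aDMN and
that node's connectivity, and the fraction of ROIs inside the z > 2.3
cluster.  `run_aging_study` adds a second, reorganization-only cohort
(jitter SD raised to 8 mm, couplings unchanged) and compares the cohorts
edgewise under the first cohort's group ROIs and under subject-specific
ROIs; it also scores Louvain partitions of the group graphs against the
planted module structure (the thresholded target matrix's connected
components, i.e. aDMN+pDMN merged and the other networks separate).
`null_calibration` draws two groups from one node-level generator
(45 nodes, 990 pairs) and checks the edgewise uncorrected significance
rate against α.

Problem sizes (20 subjects per cohort, 100 timepoints, 58×98×58 grid,
~140k in-mask voxels, 30 components) are chosen so the whole two-cohort
study runs in minutes on a single CPU within a few GB of memory; cohorts
are generated and preprocessed one subject at a time and only in-mask
matrices are retained.

The study's search radius is 24 mm (NodeSpec's general default is 16 mm):
the aged cohort jitters nodes with SD 8 mm, and P(|displacement| ≤ 24 mm)
≈ 0.97 at that SD, so subject-specific peaks are rarely clipped at the
sphere boundary — clipping would degrade the aged cohort's ROIs
asymmetrically and itself mimic an aging effect.  Same-network nodes are
far outside any sphere, and a sphere that grazes an uncoupled neighbour's
blob is harmless because that blob is nearly flat in the network's own z
map.

## Numerical choices

* t→z via the t tail probability mapped through the standard normal
  quantile, |z| capped at 38 (beyond double-precision tail resolution);
  zero-variance voxels get z = 0; a constant regressor is an error.
* Peak and nearest-voxel ties break toward the lexicographically smallest
  index; cube membership uses half-open bounds inclusive on the low side.
* FastICA runs with a fixed seed (deterministic); non-converged noise
  components are tolerated — matching only consumes the well-converged
  structured maps.
* The rank check in the PCA reduction rejects `n_components` above the
  data rank (relative eigenvalue floor 1e-6).
* Exact-correlation mixing needs more timepoints than nodes *and* at
  least (n_nodes+1)/2 FFT bins in the passband; both are validated with
  informative errors.
* Gzipped NIfTI is written with a zeroed timestamp and fixed compression
  level, so identical configurations produce byte-identical files.

## What the synthetic cohorts do and do not show

The generator reproduces the *mechanism* under study — inter-subject
spatial variability of network nodes with shared coupling structure — with
exact planted correlations and known centres, which is what makes the
method comparison decidable.  It does not emulate scanner artifacts, head
motion image effects, physiological noise spectra, spatially varying
hemodynamics, non-Gaussian node shapes, or registration error; passing
tests therefore demonstrate correctness of the pipeline and the
qualitative logic of the ROI-selection contrast, not performance on real
scans.

Known limitations:

* With a network-level regressor the z plateau over a blob's top is flat
  relative to estimation noise, so the subject-specific peak wanders 1–3
  voxels (median placement error ~4–6 mm at SNR 1); placement reaches
  voxel-level accuracy only as the regressor approaches the node's own
  signal (verified in tests with the planted signal as regressor).
  Subject-specific ROIs remain far more accurate than standardized ones,
  whose effective mis-seeding scale is the mean jitter displacement
  (~9.6 mm at SD 6).
* The Bonferroni-corrected count of spurious within-network "aging"
  decreases under standardized ROIs is small (a few edges) because
  per-edge t statistics sit near the corrected threshold at n = 20 per
  group; the uncorrected directional contrast (standardized ≫
  subject-specific) is the robust signature, and both counts are reported.
* With 30 ICA components and five planted networks the decomposition
  splits networks into node-level components and mixes coupled ones; the
  matched component's time course correlates ~0.7–0.9 with the network's
  node signals.  This mirrors the real-data situation in which component
  selection is itself an approximation.
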