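# Methods

## The problem and the pipeline

`voxelfc` discriminates two cohorts (e.g. Alzheimer's-disease patients vs
healthy controls) from preprocessed resting-state fMRI, using the functional
connectivity (FC) between *activity voxels* rather than between atlas
regions or whole networks. The pipeline is:

1. **Mask.** A brain mask is built automatically from the data: a voxel is
   in-mask iff its time series has strictly positive variance in every
   subject (intersected with an explicit mask if one is supplied). This
   guarantees Pearson correlations are defined at every in-mask voxel. All
   stages share one canonical voxel order — (x, y, z) with x fastest,
   z slowest — so column j means the same location in every subject.
2. **Per-subject spatial ICA.** Each subject's T×V matrix X is decomposed
   as X = M S with N independent spatial maps (rows of S) and time courses
   (columns of M). N is chosen by the minimum-description-length criterion
   (Wax–Kailath form on the eigenvalues of the temporal covariance of the
   voxel-demeaned data, T channels / V samples — the standard convention in
   fMRI ICA). Estimation is fixed-point ICA (logcosh contrast, symmetric
   decorrelation, tolerance 1e-4, ≤1000 iterations) after PCA whitening,
   deterministic given a seed. Optional stability selection reruns ICA
   (randomized initialisation, optional bootstrap over timepoints), pools
   maps, clusters them by average linkage on 1−|r| and keeps each cluster's
   centrotype; the time courses of centrotype maps are refitted to the
   original data by least squares. The per-cluster stability index is the
   mean within-cluster |r| minus the mean between-cluster |r|.
3. **Activity voxels.** Each spatial map is z-scored over in-mask voxels
   (population SD). A voxel is active for a subject if |z| ≥ θ in at least
   one component (θ = 2 by default, inclusive comparison). Cohort common
   sets are the intersections of the subject sets; the joint set of both
   cohorts (size N12) is the FC feature support.
4. **FC features.** Per subject, the Pearson correlation of every unordered
   pair of joint-set voxels, enumerated lexicographically over positions in
   the sorted joint set: N12(N12−1)/2 features. Correlations are computed
   on the (optionally detrended/band-passed) input series, not on ICA
   reconstructions, and no Fisher transform is applied — the raw r is the
   feature.
5. **Differential selection.** Each edge gets a two-sided pooled-variance
   Student t-test between cohorts (Welch available), Benjamini–Hochberg
   adjustment over the full edge family, and edges with adjusted p strictly
   below α = 0.05 form the selected set. An empty selection is a typed
   outcome, not an error: downstream evaluation falls back to the full
   FC feature set and says so.
6. **Classification.** Soft-margin SVM (C = 1, linear kernel) on many
   random stratified 80/20 train/test splits (1000 by default), metrics
   averaged over splits. Features are z-scored with training-split
   statistics only. Feature sets (all FC vs selected DFC) and competing
   algorithms (decision tree, LDA, logistic regression, 5-NN, Gaussian
   SVM) are always evaluated on identical split sequences so comparisons
   are paired.

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| θ | 2.0 | activation threshold on z-scored maps (sweep grid 1.5:0.1:2.5) |
| α | 0.05 | significance level for BH-adjusted edge selection |
| ICA order | MDL | components per subject; a fixed integer may be forced |
| stability runs | 20 | ICA reruns pooled for centrotype selection (1 = plain ICA) |
| C | 1.0 | SVM regularization |
| train fraction / splits | 0.8 / 1000 | repeated hold-out protocol |
| band-pass | off | optional 0.01–0.08 Hz Butterworth (order 4, zero phase) after linear detrend |

Design points that were genuinely open and the choices made:

- **Positive class.** Sensitivity counts correctly recognized patients;
  the patient cohort must be named via `EvalProtocol.positive_label`
  (synthetic runs default to the second cohort label).
- **Stratified splits** are the default so both cohorts appear in every
  test set under mild imbalance; a non-stratified mode exists.
- **Selection scope.** Differential selection is computed once on all
  subjects by default (matching the replicated protocol); computing it
  inside training splits only is the statistically conservative variant and
  can be done by composing `select_dfc` with `make_splits` directly.
- **Atlas restriction.** Region filtering (> 10 active voxels and > 1 % of
  the region) affects reporting only; optionally the joint set itself can
  be restricted to atlas-labelled voxels before feature extraction
  (`restrict_to_atlas`), since gray-matter restriction is ambiguous between
  reporting and feature construction in practice.
- **Degenerate edges.** Zero pooled variance with equal means gives
  t = 0, p = 1; with unequal means p = 0 and the edge is flagged.

## The synthetic generator

The generator emulates the study conditions at desk scale: a 12×12×12 grid
(1728 voxels), T = 130 volumes at TR = 3 s, four spherical activation blobs
(radius 2, 33 voxels each) driven by band-limited (0.01–0.08 Hz) unit-
variance time courses with 10 % per-subject amplitude jitter, white
Gaussian noise at SD 0.05 relative to source amplitude, and 20 subjects per
cohort. Ten differential edges are planted across blob pairs with cohort
correlations 0.55 vs 0.15 (Δr = 0.4).

Planting is done so that ground truth is exact and leakage-free: each
planted voxel receives a fixed extra variance budget
E = r_max/(1−r_max)·(A² + σ²) split between a component shared with its
partner voxel and a private component. The shared fraction sets the pair's
correlation to the cohort target, while the budget itself is identical in
both cohorts — so the voxel's total variance and its correlation to every
*other* voxel are cohort-invariant, and the only true cohort difference is
at the planted pairs. (Scaling the shared component alone would leak group
differences into every edge touching a planted voxel.)

What the generator does *not* emulate: hemodynamic response shapes, motion
and physiological artifacts, scanner drift, spatial autocorrelation of
noise, registration error, and realistic anatomy. Passing tests therefore
demonstrate the pipeline's statistical correctness and calibration under
its own model assumptions, not performance on clinical data.

## Calibration and recovery experiments

The canned experiments in `voxelfc.experiments` (used by
`scripts/acceptance.py` and the acceptance tests) run at these problem
sizes, chosen to keep a full run in minutes on one CPU while leaving the
generator's study conditions untouched:

- **Null calibration:** 20 replicates of identical cohorts (10 + 10
  subjects, no planted edges), plain ICA (1 stability run). Expected: the
  FDR contract — an empty selection in ≥ 90 % of replicates and a mean
  false-selection fraction ≤ α.
- **Recovery:** 10 replicates of the default planted configuration
  (20 + 20 subjects). Expected: joint-set voxel sensitivity ≥ 0.9 with
  false-positive fraction ≤ 0.05; planted-edge sensitivity and precision
  ≥ 0.8.
- **Feature contrast and threshold sweep:** one default dataset, paired
  evaluation at 200 splits; the DFC features should dominate all-FC on all
  three metrics, and remain dominant across the θ grid, in particular for
  θ ≥ 2.

MDL on planted datasets estimates orders above the four blob sources
because each planted voxel's shared/private components are themselves weak
independent sources; this is correct behaviour, and activity detection is
unaffected because those components live inside blob voxels.

## Numerical notes and limitations

- Correlations are clipped to [−1, 1] after computation to absorb float
  rounding.
- FastICA component sign and permutation are free; everything downstream
  uses absolute values or is permutation-invariant, and components are
  ordered by explained mixing variance for reproducibility of exports.
- The MDL eigenvalue tail is clipped at the smallest positive float before
  logs; non-finite eigenvalues raise a typed numerical error.
- Band-pass uses forward–backward filtering; a tone above the sampling
  Nyquist cannot be represented and is evaluated at its aliased frequency.
- Repeated hold-out on a *fixed* small dataset estimates that dataset's own
  expected accuracy, which under a random labeling deviates from 0.5 by
  O(n^−1/2); chance-level checks therefore average over label permutations.
- Intersection-based common-activity sets can empty out at high θ or large
  cohorts; this surfaces as a typed error (joint set < 2 voxels) or a
  flagged degenerate sweep row, never a silent continuation.
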