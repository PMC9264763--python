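# Methods

## Signal model and estimator

The diffusion-weighted signal in each voxel is modeled as a fixed-spectrum
tri-exponential decay,

    S(b) = C1 + C2·exp(−b·D2) + C3·exp(−b·D3),

with diffusivities fixed at D = (0, 1.5×10⁻³, 10.8×10⁻³) mm²/s. The three
regimes correspond to restricted (intracellular-like), hindered
(extracellular-like) and pseudo-diffusion (flow-like) water. Fixing the
diffusivities makes the inverse problem linear: the non-negative signal
contributions C = (C1, C2, C3) are estimated per voxel by non-negative
least squares (Lawson–Hanson active set via `scipy.optimize.nnls`), which
returns the exact constrained optimum deterministically — preferred here
over iterative solvers for bit-reproducibility. With the four shells
b = {0, 500, 1500, 4000} s/mm² the design matrix `exp(−b_j·D_i)` has full
column rank, so noiseless signals are inverted exactly; all-zero
(background) voxels short-circuit to C = 0.

Derived maps: the product C1·C2, its square root (same scale as the
individual maps), and a conventional mono-exponential ADC. ADC is the
ordinary least-squares slope of −ln S versus b over shells with
b ≤ 1500 s/mm², computed on shell-averaged data *without* noise-floor
correction; a two-point mode (b = 0 and b = 1500 only) is available
behind `adc_mode="two_point"` since the published convention does not pin
the choice. Voxels with non-positive signal on a used shell or a negative
fitted slope are flagged invalid and excluded from ADC ROI statistics
only.

## Preprocessing

Order is fixed: distortion hook → noise-floor subtraction → eddy hook →
per-shell averaging → normalization.

- **Noise floor.** Magnitude MRI has Rician noise, so air background has a
  positive mean ≈ σ√(π/2). The floor is estimated as the mean of the mean
  b = 0 volume over background voxels, where background is everything
  below the first local minimum after the low-intensity mode of a 256-bin
  histogram (the published recipe specifies only "a histogram"; volume
  choice and bin count are our documented defaults). A user-supplied
  background mask overrides detection. Subtraction clips at zero:
  magnitude data and NNLS both assume non-negative signal.
- **Averaging.** All acquisitions (diffusion directions) within a shell
  are voxel-wise averaged; output shells are sorted ascending in b.
- **Normalization.** Every shell volume is divided by the 98th percentile
  (linear-interpolation definition) of the full b = 0 volume. This
  preserves T2 information, avoids normalizing by an arbitrarily high
  noise voxel, and is idempotent. Normalization rescales all compartment
  estimates by a common per-volume factor; rank-based cohort statistics
  are invariant to it, and exact-recovery tests operate on un-normalized
  data.
- Reverse-polarity-gradient distortion correction and eddy-current
  correction are identity hooks: real-data users substitute external
  tools; the phantoms simulate neither artifact.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes: a
paired cohort (default 12 patients) in which every patient carries one
malignant lesion, ≥ 1 benign lesion (the first two patients carry a
second, giving 14 benign lesions in the default cohort) and healthy
background, all imaged with the default protocol — shells 0/500/1500/4000
s/mm² with 2/6/6/15 acquisitions (the dual b = 0 volumes are simulated as
two identical-statistics acquisitions), TE 82 ms, TR 9000 ms, δ 29.34 ms,
Δ 37.67 ms, voxel 2.5×2.5×5.0 mm³.

- **Tissue distributions.** Each compartment fraction is log-normal,
  parameterized by target median m and IQR q with
  σ = asinh(q/(2m))/z₀.₇₅, which reproduces the target median and IQR
  exactly and guarantees non-negativity. Defaults (median (IQR)):
  malignant C = (0.32 (0.18), 2.6 (1.7), 0.13 (0.40)); benign
  (0.05 (0.12), 1.6 (1.5), 0.34 (0.70)); healthy (0.08 (0.13),
  0.90 (0.73), 0.34 (0.43)). Components are drawn independently within
  and across tissues.
- **Hierarchy.** Between-patient variability carries √(1 − f²) of the
  total log-σ and within-lesion voxel heterogeneity the remaining
  fraction f = 0.3 (a free realism parameter: published tables constrain
  across-patient spread, not within-lesion texture). Voxel marginals keep
  the configured median exactly.
- **Geometry.** The breast is an ellipsoid filling ~44/41/44% of the grid
  half-axes on a default 64×64×16 grid (a scaled stand-in for a 128×128
  reconstruction matrix; every operation is grid-agnostic). Lesions are
  ellipsoids placed in the low-x (ipsilateral) half with axis lengths
  drawn uniformly from published size ranges (malignant 21–50 × 19–40 ×
  10–25 mm; benign 8–35 × 5–14 × 5–14 mm), intersected with the breast
  and mutually disjoint.
- **Noise.** Rician: s → √((s+g₁)² + g₂²), g₁,g₂ ~ N(0, σ²), default
  σ = 0.02 in normalized-truth units (healthy b = 0 SNR ≈ 65, in the
  range of clinical breast EPI). The noise floor arises naturally from
  the Rician background; no separate offset is added.
- **Seeding.** One master seed feeds `numpy.random.SeedSequence`; each
  patient gets one spawned child, so cohorts are reproducible and
  patients independent.

What the phantoms do *not* emulate: geometric distortion, eddy currents,
fat suppression failure, coil sensitivity, anisotropic diffusion, and
spatial autocorrelation of tissue texture. Passing tests therefore
demonstrate correctness of the estimator and statistics under the modeled
conditions, not robustness to scanner artifacts.

## ROI rules

One data point per patient × tissue × metric: the ROI median (even counts
use the midpoint convention). Multiple benign lesions are pooled before
the median (a `median_of_medians` alternative is available). The healthy
control ROI is a box grown in the contralateral half of the grid (the
x-half not containing the malignant centroid), intersected with breast
tissue and with all lesion and user-supplied exclusion voxels removed,
trimmed to exactly 500 voxels nearest the box centre (500 voxels ×
31.25 mm³ = 15.625 cm³). The construction is deterministic. Exclusion
regions (axilla, large cysts, susceptibility artifacts) are user-supplied
masks; no automatic detection is attempted.

## Statistics

- **Diagnostics.** Shapiro–Wilk per tissue × metric (requires 3 ≤ n ≤
  5000, non-constant) and Levene/Brown–Forsythe (median-centred by
  default) across tissues.
- **Ranked RM-ANOVA.** All medians in the (sub)table are jointly
  rank-transformed (mid-ranks for ties, Conover style), then a
  repeated-measures ANOVA on ranks with patient as the repeated unit
  (`pingouin.rm_anova`): two within factors (tissue, metric) plus their
  interaction for the omnibus analysis, one factor for the per-metric and
  per-tissue marginal analyses (each marginal analysis re-ranks its own
  sub-table). Uncorrected p-values are reported. An all-tie table returns
  the degenerate no-effect result (F = 0, p = 1) instead of crashing.
- **Post hoc.** Paired Wilcoxon signed-rank for the three tissue pairs in
  each metric. Zero differences are dropped before ranking (Pratt's
  method available), absolute differences are mid-ranked, and for n ≤ 25
  retained pairs the exact two-sided p is computed by dynamic programming
  over doubled ranks (tail doubling, capped at 1); above the cutoff a
  normal approximation with continuity and tie correction is used. The
  n = 12 cohort always takes the exact path. Bonferroni adjustment uses
  family size 3 (the pairs within one metric); the family size is
  configurable. The discreteness of the exact null at n = 12 gives an
  attained two-sided level of ≈ 0.042 at nominal α = 0.05.

## Numerical choices and degenerate inputs

Percentiles use linear interpolation; histograms use 256 bins; NNLS
tolerances are scipy defaults (residuals of exactly representable
solutions are ≤ 1e-10); empty ROIs, all-zero b = 0 volumes, constant
samples, unbalanced tables and infeasible lesion placements raise typed
errors naming the offending entity. Maps outside the fitted mask hold
NaN (encoded as −1 in exported NIfTI).

## Problem sizes

Defaults were chosen so the full test suite (including 20 end-to-end
cohort replicates and 500 null replicates of the signed-rank stage) runs
in well under a minute of compute on one core: cohort-level Monte-Carlo
uses the patient-median layer of the generator where only the paired
statistics are exercised, and image-level runs restrict NNLS to the ROI
voxels that enter the statistics (`fit_scope="rois"`; set `"full"` for
whole-volume maps).

## Known limitations

- The fitted compartment medians are reported in normalization units; no
  attempt is made to undo the b = 0 percentile scale, since every
  downstream statistic is scale-invariant.
- With independent log-normal tissue distributions carrying the full
  configured across-patient IQRs, the paired exact signed-rank test at
  n = 12 with Bonferroni correction demands near-perfect sign consistency
  (W⁻ ≤ 9) to reject; per-pair detection probability for the
  malignant-vs-benign C1 contrast is therefore ≈ 0.5–0.6, and moderate
  benign-vs-healthy median ratios in C2 and C1·C2 are detected in a
  non-negligible fraction of cohorts. Qualitative significance-pattern
  recovery across seeds is consequently partial under these defaults;
  reproducing a near-deterministic pattern would require within-patient
  correlation structure stronger than any marginal-matching generator can
  produce. See the acceptance suite for the measured rate.
- C3 is poorly conditioned at this shell scheme: its column decays to
  ~0.005 by b = 500, so C3 estimates are noise-sensitive; this mirrors
  the weak identifiability of pseudo-diffusion at sparse low-b sampling.
- The ADC of a tri-exponential voxel is a model-mismatch summary; its
  absolute value depends on the shell weighting and should not be read as
  a tissue ADC.
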