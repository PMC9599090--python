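# Methods

## The statistic and its pipeline

For each subject, parcellated regional time series (T timepoints × N
regions, region order fixed by the atlas table) give an N × N Pearson
association matrix; the Fisher transform z = arctanh(r) is applied
off-diagonal to stabilise variance. The diagonal is stored as 0 and never
enters any sum: a node is not its own neighbour, and arctanh(1) is
infinite. Node strength (weighted degree) is μᵢ = Σ_{j≠i}|z_ij|; negative
associations contribute through the absolute value and no threshold or
sparsification is applied.

The baseline reference σ is derived from the normal-control (NC) group's
mean strength vector, and the proportional loss of functional connectivity
strength of node i is Lossᵢ = (μᵢ − σ)/σ. Group-level curves are means of
subject-level vectors; a subject's "global PLFCS" is the node-mean of their
vector.

Downstream: NC vs pooled cognitive-impairment (CI = MCI + AD) node
selection region by region; Pearson correlations between connectivity
metrics and regional tau SUVR within each diagnostic group, restricted to
the selected regions; hub-vulnerability correlation across regions between
NC mean strength (un-transformed Pearson scale) and disease mean loss;
Pearson correlations against clinical scales; one-way ANOVA with
Bonferroni-corrected pairwise post hocs on global summaries.

## Variant choices the literature leaves open

Two aspects of the statistic are ambiguous in published usage, so both are
implemented, with the choice recorded in every output (`baseline.json`,
`config.json`, the hub-vulnerability table):

* **Baseline granularity.** The printed definition makes σ a single scalar
  (the node-mean of NC strengths, `global_scalar`, the default). Under this
  convention Lossᵢ is an affine function of the node's own strength, so its
  correlation with NC strength across nodes is positive whenever hubs
  remain hubs — it cannot express "hubs lose proportionally more". The
  `per_node` variant (σᵢ = NC mean strength of node i) measures each node's
  own proportional change and is the quantity for which the
  hub-vulnerability analysis is meaningful; the pipeline therefore uses
  `per_node` loss for that analysis (configurable via `hub_plfcs_variant`)
  while keeping `global_scalar` as the default everywhere else. Per-region
  cross-subject correlations (node selection, cross-modal tables) are
  unaffected by the choice, since within a region either variant is an
  affine map of μᵢ.
* **Sign.** As printed, a node *above* baseline has positive "loss". The
  default follows the printed formula; `sign="inverted"` computes
  (σ − μᵢ)/σ so that loss of strength reads positive. Reported disease
  cohorts show *higher* PLFCS with the printed sign, which is internally
  consistent (higher strength ⇒ higher (μ−σ)/σ) but at odds with the word
  "loss"; both conventions ship and the discrepancy is deliberately left
  visible rather than resolved.

Strength is computed on the Fisher-z matrix by default with a documented
`pearson_r` option; the hub-vulnerability analysis correlates against the
un-transformed NC strengths, and every strength/loss vector carries its
scale provenance so the two are never silently mixed.

## Statistical procedures

* **t-test**: two-sample, pooled variance by default (Welch by flag),
  two-sided. Zero pooled variance with equal means reports t = 0, p = 1;
  with unequal means the region is flagged `degenerate` — never a silent
  NaN. Selection is at uncorrected p < α (α = 0.05 default), matching the
  field convention of this analysis; Benjamini–Hochberg q-values are
  reported in an extra column as a clearly-labelled extension and are not
  used for selection.
* **Permutation test**: statistic |Δ group mean| per region, subject labels
  permuted; Monte-Carlo p uses the add-one estimator
  (1 + #exceedances)/(1 + n_permutations) so p is never 0; ties count as
  exceedances (within 1e-12). When C(n_a+n_b, n_a) ≤ n_permutations the
  relabelings are enumerated exhaustively and the exact enumeration p is
  returned.
* **ANOVA / post hoc**: scipy one-way ANOVA; pairwise p values multiplied
  by the number of pairs (3) and capped at 1.
* **Selection-then-correlation**: cross-modal correlations are computed
  within MCI and AD separately over regions selected on the NC-vs-CI
  contrast. The selection and correlation samples overlap (the CI pool
  contains the correlated groups); this circularity mirrors the two-stage
  design the package implements and is surfaced here rather than altered.

## Synthetic cohort generator

The generator exists to make every downstream stage testable and to verify
that the pipeline recovers a known ground truth; its defaults are the study
conditions, not tuning knobs.

* **Network**: covariance Σ = aaᵀ + BBᵀ + 0.5·I with a dominant positive
  factor a whose loadings are u^hub_exponent (u ~ U(0.5, 1.5), normalised)
  and two weak texture factors (loadings ~ N(0, 0.22²)). `hubness` is the
  node strength of the implied correlation matrix. hub_exponent = 0 gives
  near-homogeneous strengths; the default 2 gives a strong hub hierarchy.
* **Disease attenuation**: off-diagonal Σᵢⱼ is scaled by fᵢfⱼ with
  fᵢ = max(0, 1 − β·ĥᵢ), ĥ the hubness normalised by its maximum, and the
  diagonal kept. This equals FΣF + (I−F²)·diag Σ with 0 ≤ f ≤ 1, hence PSD
  by construction; an eigenvalue check (λ_min ≥ −1e-10·λ_max) runs on every
  covariance regardless. Hub-proportional attenuation is the minimal
  mechanism that produces the hub-vulnerability signature and is a
  modelling choice of this package, not an empirical claim.
* **Subjects**: disease subjects get a severity multiplier
  s = max(0, N(1, 0.25²)) on the group β, so designed loss varies across
  subjects; time series are T i.i.d. multivariate-normal rows from the
  subject's covariance plus white noise (sd 0.2 by default). Eigen-based
  sampling tolerates rank-deficient covariances, and T < N is allowed.
* **Tau SUVR**: regionally flat group baseline (NC 1.1 / MCI 1.25 /
  AD 1.6 SUVR units, typical for second-generation tau tracers) plus
  ρ_region · gain · (subject's designed per-node proportional loss) plus
  N(0, 0.05²) measurement noise. ρ_region ∈ [−1, 1] sets the designed sign
  of the within-region loss↔tau association; the default (+1 for the first
  half of regions, −1 for the second, mimicking opposite frontal vs
  parieto-occipital coupling directions) is arbitrary and deliberately
  user-visible. The gain default of 1 puts the coupled SUVR variation on
  the same scale as the proportional loss (~0.1–0.4), comparable to
  reported disease effect sizes. The spatial tau profile within a group is
  otherwise flat, so designed loss and designed tau mean are exactly
  monotone in each other when ρ is uniform.
* **Clinical scores**: MMSE-like = 29 − 22·β·s + N(0,1) clipped to [0, 30];
  CDR-SB-like = 0.2 + 15·β·s + N(0, 0.5²) clipped to [0, 18] — linear in
  effective disease burden with realistic group means (≈29/24/20 MMSE).
* **Rendering**: cohorts can be written as NIfTI-1 volumes on a small
  synthetic block grid (one block per region plus a disjoint
  reference-region block; float64 voxels), which exercises the
  atlas-extraction and SUVR path end to end; zero voxel noise round-trips
  to ≤1e-6. The grid is not anatomical space — registration, smoothing,
  hemodynamics, and motion are explicitly not emulated.

What passing tests on these cohorts shows: the implementation correctly
recovers structure of exactly the kind the analysis assumes (Gaussian
stationary signals, group-shared networks, linear tau coupling). It does
not certify behaviour under real-data violations — hemodynamic and motion
artefacts, non-stationarity, registration error, partial-volume effects.

## Numerical and degenerate-case conventions

* Pearson matrices are symmetrised and clipped to [−1, 1] before the zero
  diagonal is imposed; |r| = 1 off-diagonal raises in the Fisher transform,
  naming the offending pair.
* Zero-variance signals, all-zero baselines, σᵢ = 0 nodes, non-positive
  reference uptake, label/scale mismatches all raise named errors rather
  than propagate NaN or inf.
* ROI means are unweighted voxel means; NaN voxels are excluded, an
  entirely-NaN region raises. Functional/PET grids must be congruent with
  the atlas grid — no resampling is performed.
* Temporal band-pass filtering (optional; typical 0.01–0.08 Hz) is an
  exact zero-phase frequency-domain mask keeping low ≤ f ≤ high.
* Default problem sizes in tests and the acceptance script (20–60 regions,
  5–20 subjects/group, 120–200 timepoints) are chosen to make the designed
  effects detectable at desk scale while keeping the full suite fast;
  generator defaults mirror a 246-region, 22/26/36-subject, ~180-volume
  study.

## Known limitations

* No covariate adjustment (age, sex, education) in any comparison.
* Region-wise tests within one cohort are strongly positively correlated
  (regions share subjects and the generating network), so the *count* of
  selected regions under the null is far more variable than a binomial
  model would suggest, even though the per-region level is calibrated;
  interpret selection counts accordingly.
* The uncorrected-α selection convention is reproduced deliberately; the
  q-value column is the place to look for multiplicity-aware inference.
* Baseline is always a reference group, never a prior scan; longitudinal
  loss is out of scope, as are graph metrics beyond strength, sliding-window
  connectivity, kinetic PET modelling, and partial-volume correction.
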