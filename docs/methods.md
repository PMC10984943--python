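# Methods

This note documents the models and procedures implemented in
`ectcraft`, the parameters that matter, the design choices made where
several reasonable options existed, and what the synthetic benchmarks
do and do not demonstrate.

## Input model

The pipeline consumes the *output* of spatial deconvolution, never the
expression data themselves: per section, a spot table (id, x/y in µm,
section id) and a spot × cell-type matrix of non-negative real
abundances shaped like a posterior-quantile export (e.g.
cell2location's `q05_cell_abundance_w_sf`). Coordinates are
micrometres in the image frame (y grows downward), the convention of
image-registered Visium exports; this is recorded in every run
manifest. Abundance matrices may be dense TSV or Matrix Market with
row/column sidecar files. Validation rejects (rather than coerces)
NaN, negative values, duplicate ids and misaligned rows.

## Pseudo-single-cell maps

Counts are obtained by rounding each abundance up per cell type and
down for cancer cells. The asymmetric rule prevents systematic
inflation of the cancer compartment, whose cells are large,
histologically recognizable and easily over-counted; exact integers are
fixed points of both roundings, so zeros stay zero. The original
procedure additionally allowed a pathologist to adjust the
discretisation against the H&E image; that manual, non-algorithmic step
is deliberately not reproduced — the pure rounding rule is the
documented, testable contract.

Each counted cell is placed at its spot center plus a uniform draw from
a disc of radius 40 µm (default; at most the spot diameter). Uniform-
over-a-disc was chosen over per-axis uniform jitter because it is
isotropic and keeps all points inside the spot footprint; its mean
offset is 2r/3, which the tests verify. Placement is seeded and
deterministic.

## Distances, diversity, annotations, enrichment

*Distances.* For every pseudo-cell and every other cell type present in
the same section, the Euclidean distance to the nearest pseudo-cell of
that type is kept (kd-tree per target type). Sections are never
pooled when computing distances; rankings around an anchor type pool
the per-cell rows of all sections unweighted and rank reference types
by median.

*Shannon index.* H = −Σ p·ln p over positive renormalised fractions,
natural log.

*Annotation transfer.* Spots are modeled as discs of the declared spot
diameter (Visium spots are circular; the geometric model is otherwise
unstated in such exports). Per spot, the area fraction covered by each
compartment's polygons is computed with exact polygon–disc
intersection. The cancer label is assigned whenever its coverage
exceeds 30% — this exception is checked *before* the majority rule —
otherwise the largest-coverage label wins, ties broken by the
lexicographically smallest label; uncovered spots are "unassigned".
Only labeled area competes in the majority (uncovered area does not
vote).

*Enrichment.* Per compartment, the per-section proportion of each cell
state among its parent type's pseudo-cells is compared one-versus-all
(that state vs the pooled per-section proportions of the other states)
with a two-sided Wilcoxon rank-sum test: exhaustive enumeration of
group assignments (midranks for ties) when the pooled sample size is
≤ 20, otherwise the normal approximation with tie-corrected variance
and no continuity correction. Direction is called by median
comparison. A pooled 2×2 Fisher's exact test (state vs rest ×
compartment vs rest, sections pooled) accompanies each row, and a
Benjamini–Hochberg column is provided for convenience although the
primary p values are reported raw.

## Niche identification

1. **ILR transform.** Each abundance row gets a pseudocount of
   10⁻³ × its row-mean abundance (ILR is undefined at zero and the
   inputs are posterior quantiles that can be exactly zero; the
   relative pseudocount keeps rows with different sequencing depth
   comparable), is closed to proportions, and is projected on a fixed
   Helmert-type orthonormal contrast basis in the declared cell-type
   order. Any orthonormal basis gives an isometric embedding, so
   downstream clustering is basis-invariant; fixing one specific basis
   makes runs reproducible. The embedding satisfies two checked
   identities: ILR distance = Aitchison distance, and elementwise
   multiplicative perturbation = constant translation.

2. **Batch-balanced kNN.** Every spot is connected to its k nearest
   neighbours (Euclidean in ILR space) within *each* section, its own
   included; the directed edges are symmetrised by union. Default
   k = 3 per batch, the default of the common batch-balanced kNN
   implementation. Because per-section multiplicative shifts are
   translations in ILR space, forcing cross-section edges stitches the
   per-section clouds of the same niche together. Batches smaller than
   k contribute all their members, with a warning.

3. **Leiden.** Communities of the graph are found by Leiden
   optimisation of RBConfiguration modularity at resolution 0.6
   (default). Ten seeded restarts are run and the best-quality
   partition kept, making the result deterministic under the seed;
   labels are renumbered by descending community size. Whether the
   original analysis used modularity or CPM is not recoverable from its
   description; RBConfiguration is the common default and is recorded
   in the run manifest.

The literature is ambiguous on whether ILR was applied to proportions
or raw abundances; proportions are used here because the ILR is defined
on compositions.

*Reference mapping.* New sections are ILR-transformed with the model's
basis and pseudocount rule and assigned the nearest niche centroid
(Euclidean), with the assignment distance reported as a confidence
proxy. This deliberately replaces latent-variable label transfer
(scANVI-style), which requires a trained deep generative model that is
out of scope; the simplification is validated against synthetic ground
truth only (holdout agreement ≥ 0.85 in the tests).

## EcoCellTypes

The niche × cell-type matrix holds, per niche, the mean spot proportion
of each type, spots pooled across sections unweighted. Each cell
type's profile across niches is centered and scaled to unit sample
standard deviation (constant profiles become all-zero with a warning).
Cell-type profiles are clustered agglomeratively with Euclidean
distance and Ward linkage (Ward.D2 semantics — squared distances inside
the merge criterion, as in `scipy`'s `ward`). The dendrogram is cut
either at an explicit k or, by default, at the k ∈ [2, min(15, D−1)]
maximising the mean silhouette — the original group count was a fixed
cut whose selection rule is not documented, so both modes are exposed.
ECT ids follow dendrogram leaf order. ECT fractions of a bulk cohort
are sums of member cell-type columns, which preserves row sums exactly.

## Cohort analysis

*Stratification.* Pairwise sample distance = 1 − Pearson correlation of
ECT-fraction vectors (the default "correlation distance" of the common
heatmap tools; Spearman was not intended), Ward linkage, cut at k
(default 4). Constant rows, whose correlation is undefined, are held
out and assigned to the nearest subgroup centroid post hoc with a
warning. Subgroup ids are ordered by size.

*Median and risk splits.* "low" = strictly below the median, ties go
"high" — the convention is symmetric across all analyses. The
two-marker rule labels a sample low-risk iff its protective fraction is
at or above that marker's median and its adverse fraction is below its
own median; the original cutoffs are not explicitly stated to be
medians, so this reading (consistent with the surrounding analyses) is
an assumption.

*Log-rank.* Implemented directly — per distinct event time, observed
minus expected deaths per group with the hypergeometric
variance–covariance, chi-square on k−1 components (pseudo-inverse for
safety) — so the statistic is auditable line by line; the tests
cross-check it against `lifelines`. Kaplan–Meier curves come from
`lifelines`. A cohort with no events returns an explicit "no-events"
result rather than a statistic.

*Cox.* Proportional-hazards fits are delegated to
`lifelines.CoxPHFitter` (Efron tie handling); this stage is supporting
plumbing, not the package's own contribution. Single-level covariates
and under-determined fits (fewer events than parameters) are rejected
up front; non-convergence raises with the fitter's diagnostics.

## The synthetic generator

The generator emulates the study design the pipeline targets, not its
raw data: defaults are 17 sections × 2,000 spots on a hexagonal lattice
(100 µm pitch, 55 µm spots), 37 cell types named after breast-tumor
microenvironment populations, 11 niches, 10 co-occurrence blocks, and
~15 expected cells per spot.

- **Spatial layout.** Per section, one Voronoi seed per niche; spot
  coordinates are perturbed by a smooth Gaussian-kernel random
  displacement field (correlation length `spatial_smoothness`, default
  400 µm; fixed 150 µm amplitude) before nearest-seed assignment, so
  domains are contiguous with irregular boundaries. No estimate of the
  real niches' spatial autocorrelation exists; the smoothness is a free
  knob, not a fitted quantity.
- **Compositions.** Cell types are assigned round-robin (after a
  seeded shuffle) to blocks; each niche draws one enrichment value per
  block (s.d. 1.25 in log-abundance units) plus a small per-type wiggle
  (s.d. 0.15), exponentiates and closes. Spot compositions are
  Dirichlet around the niche center with concentration
  `niche_center_concentration` (default 150) — the single scalar that
  controls compositional separation.
- **Abundances.** Composition × Gamma total (mean
  `total_cells_per_spot`, variance equal to the mean — a non-negative
  real mimicking a posterior-quantile export, not an integer count) ×
  a per-section log-normal factor per cell type (`batch_shift_sd`,
  default 0.3), normalised to mean one so spot totals stay on target.
  The multiplicative batch factor is exactly an Aitchison perturbation:
  each section translates rigidly in ILR space, which is the error mode
  batch-balanced kNN is designed to absorb.
- **Annotations.** Mapped compartments are unions of the spots'
  Voronoi hexagons, so the true compartment of interior spots is
  exactly recoverable by the transfer rule — the round-trip check is a
  validity floor, not a hard task.
- **Cohort.** Samples draw an archetype (Dirichlet center over
  blocks), ECT fractions around it, and split each block's fraction
  Dirichlet-uniformly among member types. Survival is exponential with
  log-hazard linear in the ECT fractions, independent exponential
  censoring truncated at 120 months — the minimal model supporting Cox
  parameter-recovery and log-rank calibration tests.

Everything is drawn from one `numpy` Generator seeded by the config, so
identical configs give byte-identical outputs.

**What the generator does not emulate:** gene-level counts and
deconvolution error (abundances are drawn directly, so there is no
model misspecification noise), within-niche spatial expression
gradients, section-to-section differences in niche prevalence beyond
Voronoi geometry, correlated censoring, and real cluster shapes in
composition space (real niches need not be Dirichlet-convex). Passing
recovery benchmarks therefore shows the pipeline is correct and
well-calibrated under its own assumptions — not that it would recover
the same structures from any particular real dataset.

## Benchmarks and problem sizes

The test suite exercises most components on a scaled-down study
(3 sections × 400 spots, 12 types, 5 niches, 4 blocks) chosen to keep
the default run fast; the two headline recovery benchmarks and the
acceptance script run the full 17 × 2,000-spot design. There, the
niche pipeline recovers exactly the 11 planted communities with
ARI ≥ 0.8 across clustering seeds, and the automatic dendrogram cut
returns the 10 planted blocks with perfect membership in the large
majority of generator seeds; log-rank type-I error over 200 null
cohorts sits at the nominal level, and a planted HR = 2 is recovered
within two standard errors at n = 500.

## Known limitations

- Niche counts at a fixed Leiden resolution depend on cluster
  separation; very diffuse compositional structure can merge or split
  communities, and the resolution default should be treated as a
  starting point on real data.
- The silhouette-based ECT cut assumes compact, roughly balanced
  blocks; nested or strongly unbalanced co-occurrence structure may
  favour a different k than the visually natural one.
- Annotation transfer is exact polygon geometry; heavily self-
  intersecting hand-drawn polygons are repaired with `make_valid`,
  which can reassign slivers near boundaries.
- The exact Wilcoxon enumeration is combinatorial; above a pooled
  n = 20 it switches to the tie-corrected normal approximation, whose
  p values are approximate in small unbalanced designs.
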