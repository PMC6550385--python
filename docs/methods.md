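# Methods

This note records the procedures `tmespat` implements, the conventions and
parameter defaults it commits to, what the synthetic generator does and
does not emulate, and the design choices made where the design was
genuinely open.

## Input model and QC

The unit of analysis is a per-cell table: centroid x/y, per-marker
fluorescence intensities (optionally per subcellular compartment), QC
metrics, and FOV/sample identifiers. Coordinates carry an explicit unit
flag (`px` or `um`); conversion multiplies by `pixel_size_um` and flips the
flag, making double conversion impossible. There is no default pixel size —
it is acquisition-specific and must be supplied.

QC retention is inclusive at the boundaries: nuclear alignment ≥ 0.85,
every compartment (nucleus, membrane, cytoplasm) ≥ 10 pixels, ≤ 2 nuclei
per cell. These are the acquisition platform's recommended filters for
removing poorly registered, poorly segmented, or artifactual cells. Cells
with missing QC fields are rejected by default (`on_missing="pass"`
overrides), so unvalidated cells never slip through silently. The filter is
per-cell independent, hence order-invariant; the report counts exclusions
per rule (a cell can fail several) and uniquely. A second alignment metric
(alignment through all staining rounds) has no established cutoff and is
exposed as an optional threshold, disabled by default.

FOV windows default to the tight bounding box of the FOV's cells,
expandable by a margin; analyses that need a declared study area (the grid
algorithm) accept an explicit window.

## Phenotyping

Phenotypes are explicit threshold rules rather than a trained classifier:
reproducible, auditable, and adequate for well-separated MxIF marker
distributions. A rule matches when all required markers are strictly above
threshold; rules carry exclusions (CD3 and CD20 are biologically mutually
exclusive, so double positives are labelled `ambiguous` and excluded from
every downstream count) and priorities (CD8⁺PD1⁺ and CD4⁺FOXP3⁺ outrank
plain CD3, since those cells are CD3⁺ too; a priority tie between distinct
matching labels is `ambiguous`). Unmatched cells are `unclassified`. The
tumor label is driven by the tumor segmentation-mask marker (S100 in the
melanoma panel). Thresholds default to whole-cell intensity; per-compartment
columns (`marker_compartment`) can be addressed per rule.

**HLA-1 calling.** CD3⁺ cells ubiquitously express HLA-1 and serve as the
internal control: the positivity threshold is fraction × statistic of the
control cells' HLA-1 intensity, default 0.10 × median pooled over all
regions. A tumor cell strictly above threshold is `HLA1pos`. "10% of the
CD3⁺ HLA-1 intensity" admits two readings; the fraction-of-median rule is
the default, with mean pooling, per-FOV pooling, and a 10th-percentile mode
(`method="percentile"`) as alternatives. The calibrated threshold is
recorded in the table's provenance metadata. The call is scale-equivariant:
rescaling all HLA-1 intensities leaves the calls unchanged.

## Cell aggregation algorithm

Given an FOV window and square side *s*:

1. bin cells into a grid by half-open intervals `[edge, next)` with the
   final row/column closed (interior-edge cells go right/up; far-edge cells
   are kept);
2. per-square counts per class;
3. seed squares: count strictly above the `seed_percentile` quantile
   (linear-interpolation quantile over **all** squares, zeros included);
4. grow each seed layer by layer, absorbing adjacent squares (8- or
   4-connectivity) with count ≥ `growth_cutoff`; seeds are always retained
   even below the cutoff (they define the aggregate center);
5. merge aggregates that meet; the result equals the connected components
   of {count ≥ cutoff} ∪ seeds containing at least one seed, so it is
   independent of seed processing order and terminates in at most
   `n_squares` steps;
6. the polygon of an aggregate is the planar union of its member squares
   (multi-part when squares touch only at corners, under 8-connectivity, or
   not at all); its area is exactly `n_squares × s²`.

The "one layer of squares at a time" walk is read as the full surrounding
ring, hence 8-connectivity by default. Defaults: *s* = 50 μm (a few cell
diameters — small enough to resolve nest boundaries, large enough for
stable counts), seed percentile 95. `growth_cutoff="auto"` uses the median
of the class's nonzero per-square counts; analyses at declared densities
should pin an explicit integer (the recovery experiments below use 5).

**Infiltration areas.** The IA of an FOV is the intersection of the tumor
and CD3 aggregate unions. Both live on the same grid, so the intersection
is computed on square sets: areas are exact multiples of *s*², the bound
IA ≤ min(tumor, CD3) holds identically, and the infiltration fraction
IA/tumor is grid-exact. A zero tumor aggregate leaves the fraction
undefined (missing, never infinite). Point-in-polygon membership is
boundary-inclusive, so inside/outside partitions are exhaustive.

## Cell neighborhood analysis algorithm

Each center-class cell anchors a circle of radius `radius_um`; membership
is d ≤ R excluding the center itself. The 12 μm default radius is the
optimum reported from scanning neighborhood sizes 2–50 μm on melanoma MxIF
data; because figure captions elsewhere quote neighborhood *diameters*, the
parameter is explicitly named `radius_um` and recorded in every output.
Per-neighborhood outputs are class counts and NNDs for declared
(center, target) pairs. NNDs are neighborhood-bounded — missing beyond R —
matching the algorithm's definition; an unbounded diagnostic mode exists.
NND is directional: NND(A→B) ≠ NND(B→A) in general.

Queries run on a per-FOV k-d tree with distances computed as
√(Δx² + Δy²); the test suite requires exact agreement with an O(n²)
all-pairs oracle on random FOVs. Counts are monotone non-decreasing in R,
and at R → ∞ count + 1 equals the FOV's cell total.

Summaries are two-stage: per-FOV mean of per-cell NNDs, then the unweighted
mean across FOVs (each FOV one vote, matching how per-FOV averages are
conventionally displayed); a cell-weighted pooled mean is emitted alongside
because the weighting convention of published pooled values is often
unstated. FOVs with all-missing NNDs for a pair are excluded from that
pair's cross-FOV mean and flagged.

## Quantification layer

Per-FOV ratios (HLA-1⁺ tumor/all tumor, CD3/tumor, CD8PD1/tumor,
CD20/all immune, CD4FOXP3/all immune; denominators configurable) with
zero-denominator cells missing, never infinite; optional region restriction
(e.g. IA-only counts). Correlograms: pairwise Pearson r over complete-case
FOV rows within a sample, two-sided p, flags
significant / not-significant (p > α = 0.05) / insufficient data
(complete n < 3); the matrix is symmetric with unit diagonal. Coefficient
of variation uses the sample (n−1) standard deviation over the mean,
missing when the mean is 0 or fewer than 2 values remain.

Group comparisons: Cochran–Mantel–Haenszel chi-square over user-declared
binary outcome/group/stratum vectors (statsmodels `StratifiedTable`,
continuity correction off by default; strata missing a group are dropped
with a warning; a single stratum reduces to (n−1)/n × the Pearson 2×2
chi-square), and Welch's unequal-variance t test with Satterthwaite df
(degenerate both-groups-constant case: equal means → t = 0, p = 1).
"Compare median expression levels by Welch t test" is internally
contradictory; the implementation is Welch on per-cell intensities.
For the brisk/non-brisk contrast the reproduction script binarises per-FOV
infiltration fractions at the cohort median and stratifies by FOV index
within sample — group labels are sample-level, so the sample itself cannot
serve as a stratum.

## Synthetic data generator

The generator emulates the TME structure the algorithms target: disc-shaped
tumor nests (uniform density) with a per-cluster HLA-1⁺ Bernoulli mixture;
immune cells uniform over the window; and CD3 attraction to HLA-1⁺ tumor
cells as a displacement-kernel mixture — with probability
attraction/(1+attraction) a CD3 cell is planted at a Gaussian offset
(default σ = 8 μm, about one cell diameter, i.e. near-contact) from a
random HLA-1⁺ tumor cell, else uniformly. attraction = 0 is complete
spatial randomness (verified by chi-square uniformity over grid squares).
The kernel mixture was chosen over a Gibbs/Strauss process: exactly
seedable, trivially reproducible, and sufficient to induce the NND ordering
the analyses must detect. Marker intensities are lognormal with separated
positive (ln 100) and background (ln 5) locations and σ = 0.3, so the
default threshold 30 yields a small, known phenotyping error (~1%
HLA-1⁻-tumor false positives at the HLA threshold). A configurable cell
fraction receives failing QC values; exactly those cells are removed by the
default QC filter. All randomness flows from one integer seed (cohorts
spawn child seeds via a SeedSequence).

Defaults describe one 1000×1000 μm FOV with three 120 μm-radius nests of
300 tumor cells (≈ 6.6×10⁻³ cells/μm² nest density) and 300/100/100/80
CD3/CD20/CD8PD1/CD4FOXP3 cells. Brisk-sample templates use attraction 6
with 400 CD3 cells; non-brisk 0.5 with 80.

What the generator does **not** emulate: irregular (non-disc) nest shapes,
stromal architecture and tissue tears, cell-size exclusion effects,
spatially varying staining background, segmentation errors beyond the QC
flags, and absolute cell densities of real acquisitions (unpublished).
Passing recovery tests therefore demonstrates algorithmic correctness and
statistical sensitivity under a clean point-process model, not robustness
to every real-tissue artifact.

## Recovery experiments (declared conditions)

* **Cluster recovery**: default FOV geometry, 50 μm squares, growth cutoff
  5 (≈ 30% of a full nest square's expected count, keeping boundary squares
  whose centers fall inside a nest while rejecting grazing squares);
  ground truth = squares whose centers lie in a planted disc; score =
  Jaccard of square sets; requirement: median ≥ 0.8 over 20 seeds.
* **Attraction recovery**: balanced HLA mixture (`hla1pos_fraction=0.5`) so
  the class-density confound (the denser class trivially has the smaller
  NND) cannot imitate attraction; kernel σ = 4 μm to place attracted cells
  well inside the 12 μm horizon; attraction grid {0, 0.5, 4}; 30 paired
  replicates per level; requirement: mean NND(CD3→HLA1pos) −
  NND(CD3→HLA1neg) negative at positive attraction and monotone decreasing
  in the planted strength, with separation beyond Monte-Carlo error.
* **Cohort contrast**: 2 brisk + 2 non-brisk samples × 5 FOVs; brisk mean
  infiltration fraction must exceed non-brisk.

Problem sizes (200 grids, 100 random FOVs of 200–1000 cells, 20–30
replicates) were chosen as the smallest giving stable medians/means across
seeds.

## Numerical conventions and degenerate inputs

Quantiles: linear interpolation (`numpy.percentile` default), pinned in
tests. Seeding uses strict ">", HLA calling strict ">", marker positivity
strict ">"; QC retention inclusive. Polygon areas are exact because square
corners are exact float multiples of *s* from the window origin. Empty
classes yield zero count matrices, empty seed sets, empty aggregate lists,
and empty (not failing) IAs; an all-equal count grid has no seeds (nothing
is strictly above its own quantile). CSV round-trips preserve reals to
better than 1e-9 relative.

## Known limitations

* Grid-based delineation quantises aggregate boundaries to square
  resolution; areas are faithful to the algorithm's own definition, not to
  any sub-square contour.
* The auto growth cutoff (median of nonzero counts) is a heuristic; for
  cross-study comparability pin it explicitly.
* Rule-based phenotyping assumes separated intensity distributions; heavily
  overlapping marker distributions need per-marker threshold tuning or an
  external classifier upstream.
* The HLA-1 threshold inherits any bias in CD3⁺ segmentation spillover.
* NND summaries are bounded at R by construction; they estimate conditional
  distances given a neighbor within R, not unconditional NND.
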