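# Methods

This note documents the models and procedures atlasfuse implements, the
parameters that matter, what the synthetic fixtures emulate (and do
not), and the numerical choices made where the design was open.

## Reference space, ontology and VOIs

All data live on a single 3D voxel grid with per-axis voxel size in mm.
Coordinates are 0-based voxel indices; the physical position of a voxel
center is `(index + 0.5) * voxel_size`, which makes nearest-neighbor
logic unambiguous.  Label 0 is reserved for background and is never a
region id.

The brain-region ontology is a tree (unique ids, one root, no cycles);
the parcellation assigns each voxel one region id.  A region's voxel set
is the union over its reflexive-transitive descendants, so parents
always spatially contain their children.  Partial-volume voxels at
region borders are treated as exact labels — the source atlases give no
sub-voxel information to do better.

Nearest-neighbor resampling between grids compares voxel-center
positions with a shared physical origin.  Equidistant ties go to the
lower source index per axis, which also minimizes the linearized source
index; the choice is arbitrary but deterministic.  Volumes are stored in
numpy's C order throughout (last axis fastest), including VOI linear
indices.

## Sample selection and the four queries

A region-annotated sample belongs to a VOI when its annotation region's
voxel set intersects the VOI, unweighted.  This rule has two important
consequences.  First, hierarchical invariance: any VOI that is a
nonempty subset of an annotated region's voxels selects the same samples
as the region itself, so queries at finer anatomical levels than the
annotation reproduce the annotation-level result rather than silently
returning nothing.  Second, coarse annotations bleed into neighboring
sub-regions by design; the coverage table therefore reports the original
region annotations per cell so the provenance is visible.  Weighting
samples by fractional voxel overlap was considered and rejected: it
would break the invariance and imply sub-annotation information the data
do not carry.

The four scores (mean expression, region specificity, cell-type
specificity, enrichment) are ratios of means over the sample subsets
V ∩ C ∩ F, C ∩ F, V ∩ F and V as given in the README.  Notes:

- The region-specificity denominator is the mean over **all** of C ∩ F
  (whole brain including the VOI), not "brain minus VOI".  For small
  VOIs the two differ negligibly; the inclusive form keeps the identity
  "whole-brain VOI ⇒ score 1" exact.
- Ratios with zero denominator are *undefined* (NaN), excluded from
  ranking — never coerced to 0 or ∞, which would corrupt rank order.
- An empty V ∩ C ∩ F yields an explicitly empty result object, not NaN
  propagation.
- Queries operate on whatever normalization state the dataset carries
  (typically log2-CPM/TPM for sequencing data, unit-interval sigmoid for
  microarray); the query layer never re-normalizes, so scores are only
  comparable within a dataset.  Gene ranks (descending, average on
  ties) are the cross-dataset-robust output.

## Preprocessing and normalization

QC for count matrices removes samples with unique-gene counts below 50
or above 5000 (empty droplets / doublets), then samples whose
unique-gene count deviates from the median by more than 5 × MAD (median
absolute deviation).  The MAD rule is the standard robust outlier test;
with identical samples MAD = 0 and nothing is removed.

CPM rescales each sample to a total of 10⁶; RPKM→TPM divides each
sample by its RPKM sum and rescales to 10⁶ (the two differ only by the
within-sample sum used); log2(x+1) handles zeros.  Microarray values are
normalized per gene with a scaled outlier-robust sigmoid,
`y = expit((x − median) / (IQR/1.349))` rescaled to [0, 1].  The scale
IQR/1.349 is the normal-consistent robust spread estimate; a constant
gene (IQR = 0) maps to zero with a warning.  Gene identifiers resolve to
canonical ids with precedence symbol > Ensembl > Entrez; unmatched genes
are dropped and duplicate canonical hits collapse to the row with the
largest total signal, avoiding double-counting after CPM.

## Connectome assembly

Each tracer injection record contributes its target-strength image to
every voxel of its injection volume.  Voxels covered by multiple
injections take the per-target maximum — a union-of-evidence rule that
is insensitive to how many overlapping injections exist.  Optional
mirroring reflects every record about the mid-plane of a configurable
axis (default 0, `index → shape−1−index`) before assembly, doubling the
effective injection sites; mirrored and original records combine by the
same max rule.  Finally all weights strictly below 10⁻⁴·⁵ are zeroed —
the established false-positive threshold for tracer projection data —
so no assembled weight lies in (0, 10⁻⁴·⁵) and thresholding is
idempotent.

VOI aggregation over sources is the arithmetic mean of covered rows
(sources without data are excluded, not treated as zero); a maximum
variant is available behind a flag.  The mean matches the group-average
framing of the upstream connectivity resources and is linear in the
weights.  Strongest-target extraction takes the top k (or top fraction)
positive target voxels, breaking ties by Morton key so results are
deterministic.  Grayordinate matrices are brought to voxel space by
assigning every voxel the nearest grayordinate coordinate (Euclidean,
ties to the lowest grayordinate index).

## Spatial indexing

Items (connectome rows/columns, per-voxel image stacks, located
samples) are ordered by Morton z-order keys on a power-of-two padded
grid, x least significant within each bit triplet.  The sort is stable,
so co-located items keep their input order.  A VOI query merges the
VOI's keys into maximal consecutive runs and fetches each run as one
contiguous slice; because the key map is a bijection, a run contains no
foreign key and the result is exactly the naive-scan multiset.  Stores
round-trip through zarr.  Pre-aggregates hold per-(metadata-group,
region) per-gene means and counts; any mean query whose filters align
with group boundaries is answered by a count-weighted average of group
means, and filters that cross group boundaries fall back to the raw
path (correctness over speed).

## Cross-species statistics

Per gene, the Spearman rank correlation (average ranks on ties) is
computed between its per-region expression score and a per-region
connectivity profile; at least 3 regions are required and constant
vectors are undefined.  Gene-level p-values are deliberately not
computed — the workflow selects genes by coefficient quantile (default
top/bottom 1%, set sizes ⌈q·n⌉, cutoff ties broken by gene id).  The
regional expression entering the correlation can be the mean-expression
or a specificity query score; the package's own cross-species workflow
uses the mean-expression query restricted to one cell class, which
keeps the per-region estimate free of the ratio saturation that the
specificity score exhibits for strongly enriched genes.  Cross-species
overlap maps one species' extreme sets through the homolog table into
the other's.  Distribution shifts between gene groups use the
two-sample Kolmogorov–Smirnov test; directionality of a coefficient
sample is tested with a one-sample t-test against zero.  Inter-dataset
concordance computes Spearman correlations between per-cell-type mean
expression vectors over shared genes and compares matched vs unmatched
cell-type pairs with a one-sided Wilcoxon rank-sum test.

## Synthetic fixtures

The generator emulates the input side of the pipeline with fully
deterministic, seedable constructions:

- **Atlases**: balanced trees (default depth 3, fanout 2) whose leaves
  tile the grid as contiguous near-equal blocks of the flattened index
  range — every voxel labelled exactly once.
- **Count matrices**: per-gene baselines ~ lognormal(3, 1) (median ≈ 20
  counts), multiplicative planted fold-changes per (gene, cell type) or
  (gene, region), lognormal sample noise with σ = 0.5 (a mid-range
  per-sample dispersion), rounded half-even to integer counts.  Default
  20 samples per leaf region and cell type.  Lognormal-then-round is
  used instead of Poisson/NB because it makes planted fold-change
  recovery analytically transparent; it does not emulate dropout,
  library-size gradients or mean-variance coupling, so passing tests
  demonstrate correctness of the pipeline, not robustness to real
  scRNA-seq artifacts.
- **Injection records**: per planted projection, a small injection
  volume inside the source region and a target image carrying the
  projection weight (±3% jitter) on the target region over uniform
  background noise drawn strictly below 10⁻⁴·⁵, so thresholding behavior
  is deterministic by construction.
- **Two-species bundles**: each species gets a flat atlas with one seed
  area plus 10 consensus regions (mirroring the cross-species consensus
  set size), an excitatory/inhibitory dataset of 500 genes, and
  injection records projecting from the seed area onto the consensus
  regions with distinct well-separated weights.  Half the genes are
  inhibitory-class (4× enriched in inhibitory cells), half excitatory.
  Inhibitory genes receive a regional log-effect `β·u + ε` where `u` is
  the negated z-scored connectivity rank, β ~ N(0.4, 0.2) clipped at 0
  drawn independently per species, and ε is region-level pattern noise
  (σ = 0.5) — shifting the inhibitory correlation distribution negative
  without pinning individual genes to −1.  The first `n_conserved`
  (default 5) genes are the planted conserved correlates: β = 2.0, no
  pattern noise, and a high fixed baseline (e⁵ ≈ 150 counts) so the
  monotone regional pattern stays clear of count rounding at its low
  end.  Their per-species Spearman coefficient is −1 up to sampling
  flips whose probability is negligible at these settings.

## Self-checks and problem sizes

The acceptance script and `tests/test_acceptance.py` verify, at the
stated sizes:

- the mirrored assembly of 2173 random injection records reports 4346
  effective sites;
- the four queries match independent brute-force evaluation (100 random
  fixtures, 10⁻⁹ relative) and the degenerate ratio identities hold
  exactly;
- hierarchical invariance holds exactly on 20 random fixtures;
- indexed range queries equal naive scans on 100 random VOIs, and the
  pre-aggregate path equals the raw path to 10⁻⁹ for aligned filters;
- connectome assembly matches brute force on 10 random record sets,
  with mirror symmetry and no weight in the forbidden band;
- planted-truth recovery: an 8× marker ranks in the top 1% of
  cell-type-specificity ranks (100 fixtures, 500 samples/group), the
  strongest-targets VOI lies inside the planted target region (50
  fixtures), and all 5 planted conserved correlates appear in the
  bottom-1% cross-species overlap with the excitatory-vs-inhibitory KS
  test rejecting at p ≤ 10⁻⁴ (100 seeds);
- the direction test's type-I error under a N(0,1) null (n = 30, 1000
  replicates) lies in [0.03, 0.07] at α = 0.05.

Fixture grids are 4³–8³ voxels and datasets a few hundred samples —
sizes chosen so the whole self-check battery runs in well under a
minute on one CPU while every code path (ontology closure, VOI
intersection, assembly, indexing, statistics) is exercised end to end.

## Known limitations

- No batch-effect correction or cross-dataset normalization: scores are
  within-dataset quantities; ranks are the cross-dataset currency.
- No image registration: volumes must already be aligned to the
  reference grid (only nearest-neighbor resolution changes are
  provided).
- Region-annotation VOI membership is binary; fractional-overlap
  weighting is not implemented (see above).
- The connectome store is dense in memory; the ~10⁵×10⁵ matrices of
  full-scale atlas resources would need the chunked on-disk path end to
  end rather than the in-memory arrays the fixtures use.
- Query scores report no dispersion; homogeneity of expression within a
  selection must be assessed by other means.
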