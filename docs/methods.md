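# Methods

This note documents the models, parameters and design choices behind
`energymaps`: what each stage computes, why its defaults are what they
are, what the synthetic data do and do not emulate, and the known
limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Gene-set curation

Pathway gene sets are the intersection of two independent annotation
exports (a GO-biological-process-style and a Reactome-style table); a
gene enters a set only when both sources annotate it to the pathway.
Symbols are uppercased and stripped; no alias resolution is attempted —
probe-to-gene reannotation is assumed to have happened upstream, and
alias mapping would make the curation output depend on an external
synonym table. Manual exclusions live in a YAML config seeded with the
hexokinase rule: hexokinase catalyzes the committed first step of
glucose metabolism and therefore gates entry into both glycolysis and
the pentose phosphate pathway, so it is removed from both sets to keep
each map specific to its pathway proper.

Annotation sources distinguish direct from propagated (child-term)
annotations; the curation operates on whatever rows the export contains
and therefore effectively uses direct annotations only. The packaged
final gene sets are a synthetic reconstruction (see the fixture
filenames): they are built from standard pathway membership and
constrained to the documented overlap structure — the three succinate
dehydrogenase complex genes shared between the TCA and OXPHOS sets,
PFKFB2 shared between glycolysis and lactate, all other pairs disjoint,
and an OXPHOS set dominated by mitochondrial complex I subunits.

## Donor microarray processing

The assembly chain, in order, with its parameters:

1. **Background filter** (`max_below_fraction`, default 0.5): a probe is
   discarded when it falls below background intensity in ≥50% of
   samples, pooled across all donors. The boundary is inclusive
   (exactly half ⇒ discarded).
2. **Probe selection**: among a gene's retained probes, the one with the
   highest differential stability — the mean pairwise Spearman
   correlation of its regional profile across donor pairs, computed
   pairwise-complete over parcels sampled in both donors. Ties break to
   the lexicographically smaller probe id. Donor pairs with zero rank
   variance are excluded from the mean with a warning.
3. **Bilateral mirroring**: every sample is duplicated with its
   x-coordinate negated. This doubles spatial coverage under the
   assumption of hemispherically symmetric expression; midline samples
   produce a coincident duplicate, which is kept (it carries no extra
   information but keeps the count contract trivial).
4. **Parcel assignment** (`tol_mm`, default 2.0): each sample maps to
   the nearest parcel representative point within 2 mm, respecting the
   hemisphere of the (possibly mirrored) coordinate; equidistant
   candidates resolve to the earliest parcel in parcellation order.
   Parcels are represented by centroids. This is a deliberate
   simplification of voxel-level assignment: the package is atlas-file-
   free, so the 2-mm rule is evaluated against centroids (or a supplied
   point cloud) rather than voxel membership. The rule's logic —
   tolerance, hemisphere closure, deterministic ties — is preserved;
   absolute assignment rates differ from a voxel implementation.
5. **Normalization**: a robust sigmoid with scale IQR/1.35 (the
   IQR-to-σ conversion for a normal distribution; the normalization
   family is specified up to this constant), followed by a unit-interval
   rescale, applied across genes within each sample and then across
   samples within each gene. Sample-level normalization precedes
   within-parcel averaging. The rescale is per normalization pass (per
   vector). Zero-IQR vectors map to a constant 0.5 and are flagged.
6. **Interpolation**: a parcel with no samples receives the
   inverse-distance-weighted mean of the donor's k = 10 nearest
   normalized samples (weights 1/d, normalized; d floored at 0.1 mm) —
   a bounded, deterministic parcel-level counterpart of voxel-wise
   nearest-sample interpolation.
7. **Donor averaging and the stability filter** (`ds_threshold`,
   default 0.1): donor matrices are averaged parcel-wise; genes are
   retained when DS > 0.1 (strict). With a single donor DS is undefined
   and the filter is skipped.

## Pathway maps

The pathway map is the per-parcel unweighted mean over the set's
available gene columns; missing genes are logged, and a pathway with no
genes present is an error. Maps are z-scored with the population SD.
The PC1 alternative is computed on column-standardized genes
(correlation PCA): genes are already on a common [0, 1] scale after
assembly but have heterogeneous variances, and standardization stops
high-variance genes from dominating the component. The PC1 sign is
fixed by non-negative correlation with the mean map so the two
summaries are comparable. z-scoring is applied to the final
donor-averaged map, not per donor.

## Spin-based inference

Null maps must preserve spatial autocorrelation; the package uses
rotation-based ("spin") permutations built from parcel centroids:

- Centroids are projected to a unit sphere per hemisphere (about the
  hemisphere centroid mean). Rotations are Haar-uniform (QR of a
  standard-normal matrix with sign correction); the right hemisphere
  receives the x-mirrored rotation M·R·M so the two hemispheres spin
  mirror-consistently.
- Each original parcel is matched to a distinct rotated parcel by
  greedy ascending-distance assignment without replacement, per
  hemisphere — every null row is a hemisphere-closed bijection, so a
  spun map is an exact permutation of the original values.
- The ensemble (default n_rot = 10 000; the calibration experiments use
  1000) is generated once from a seed and shared by all tests in a run,
  and can be serialized, so every reported p_spin refers to one fixed
  null family.
- p-values use +1 smoothing and are two-sided: |rho| for correlations,
  deviation from the null median for class enrichment (the sign of that
  deviation is reported as the direction). Two-sided is the
  conservative default; one-sided variants would halve the p-values.
  Whether enrichment p-values within an atlas are then FDR-corrected is
  exposed as a flag (`enrichment_fdr`), since both conventions are
  defensible; the pipeline default applies Benjamini–Hochberg across
  all pathway × class pairs.

The type-I error of the spin correlation test, and the inflation of the
naive i.i.d. permutation test it replaces, are measured by
`energymaps.validation.spin_calibration` on independent pairs of
Gaussian fields (below); enrichment power and null rejection under a
planted class effect by `enrichment_power` / `enrichment_type_i`. The
power experiment plants a 1-SD effect on a randomly drawn class of 30
parcels (of 400), redrawn per seed; nothing constrains the planted
class to one contiguous patch, and under strong autocorrelation a
single contiguous patch is intrinsically harder to distinguish from a
chance fluctuation of the field.

Degree (count of nonzero edges) and strength (row sum) of a symmetric
zero-diagonal adjacency matrix are provided as network covariates.

## Lifespan trajectories

Cleanup filters, in order: regions must have ≥1 sample in every one of
the eight developmental stages; duplicate gene symbols collapse to
their first occurrence; a gene is retained only if RPKM ≥ 1 in at
least 80% of the samples of *every* retained region × stage cell (the
strictest reading of a per-spatiotemporal-point filter — a gene failing
any one cell is dropped everywhere; the boundary is inclusive). A
microarray variant (log2 signal ≥ 6) is available as a config switch.
The log2 transform uses an offset of +1 so zero maps to zero and the
transform is total (the retention filter guarantees most but not all
entries ≥ 1). Upper-quartile normalization scales each donor by its
75th percentile (linear-interpolation quantile over all the donor's
entries) times the mean q75 across donors; afterwards every donor's
q75 equals the pre-normalization mean exactly.

Trajectories are per-sample pathway means, then per-stage medians
(robust to the small per-stage sample counts typical of developmental
cohorts). The packaged stage table bins post-conception age into eight
conventional stages (early/mid/late fetal, infancy, early/late
childhood, adolescence, adulthood) with contiguous intervals in
post-conception days; birth is taken as 266 days. LOESS smoothing is
locally linear with a tricube kernel against log10 age, evaluated on a
100-point grid, with span 0.75 by default and the bandwidth at each
grid point set by the ⌈span·n⌉-th nearest design point. The smoother is
implemented in-package because its contract (grid evaluation, exact
reproduction of inputs linear in log10 age, specified kernel and
degree) is part of the procedure; a library smoother serves as an
independent cross-check in the tests.

## Synthetic data: what it emulates, and what it does not

The generator is a pure function of (spec, seed). Its defaults define
the study conditions used throughout the tests:

- **Geometry**: each hemisphere is its own near-spherical surface — a
  jittered Fibonacci lattice of 100 parcels (200 for the calibration
  experiments) on a 30 mm sphere offset ±35 mm from the midline, the
  right hemisphere an exact mirror image. Spin rotations map a sphere
  onto itself, so per-hemisphere spheres are both the geometrically
  correct setting for the null model and the standard way cortical
  hemispheres are treated in surface space. Class annotations are k = 7
  contiguous spatial clusters, mirrored across hemispheres.
- **Expression patterns**: zero-mean Gaussian fields with covariance
  exp(−d/λ) on within-hemisphere geodesic distance (λ default 0.3 rad;
  diagonal jitter 1e−8; hemispheres are independent blocks). Planted
  patterns are mirror-symmetric across hemispheres, because bilateral
  mirroring presumes hemispheric symmetry — with asymmetric truth the
  documented pipeline could not recover it even in principle. Class
  effects add a constant (in field-SD units) to a gene set's planted
  pattern within one class.
- **Donors**: six donors; samples at jittered parcel centroids
  (SD 0.5 mm); 15% of parcels unsampled per donor; right hemisphere
  sampled in two donors only (mirroring the left-dominant sampling of
  real multi-donor atlases); within-donor noise SD 0.5 on the log2
  scale; intensities 2^(6 + value); 10% of probe-sample pairs flagged
  below background at random; 30% of genes carry a decoy probe whose
  regional profile is shuffled per donor, exercising stability-based
  probe selection.
- **Lifespan**: ten samples per region × stage over six regions and
  eight stages; each (stage, replicate) is one donor with a log-uniform
  age within the stage interval; log2(RPKM+1) = baseline U(3, 6) +
  planted stage effect + N(0, 0.5). Baselines sit above the RPKM ≥ 1
  detection floor because trajectories are only defined for genes that
  pass the retention filter — planting a trajectory on genes the filter
  removes would test the filter, not the trajectory machinery. The
  dataset includes stage-stable background genes up to `n_genes` (the
  upper-quartile scaling must be anchored by genes outside the planted
  pathways, as it is in genome-wide data), one always-low gene to
  exercise the retention filter, and one duplicated gene symbol to
  exercise deduplication.

Not emulated: realistic cortical geometry and parcel shapes, probe
counts and intensity distributions of real microarray platforms,
donor-specific batch effects beyond what the normalization addresses,
shared transcriptome-wide gradients (each gene's field is independent,
so synthetic pathway maps are mutually uncorrelated unless an effect is
planted — real pathway maps share a dominant expression gradient), and
cross-hemisphere covariance beyond exact symmetry. Passing tests
therefore demonstrate that the procedures are correctly implemented and
well-calibrated under controlled conditions, not that any particular
biological result generalizes.

## Numerical choices and degenerate inputs

- Tie-breaks are deterministic everywhere: lexicographic probe ids,
  lowest parcel index in assignment, stable sorts in greedy matching.
- Quantiles use linear interpolation (numpy default, R type-7).
- Spearman correlations use average ranks for ties; zero rank variance
  is an error (or a flagged exclusion inside differential stability).
- p-values never reach zero (+1 smoothing); the attainable floor is
  1/(n_rot + 1).
- Benjamini–Hochberg is delegated to statsmodels behind the module
  surface and verified against an independently coded step-up
  definition in the tests; p-values outside (0, 1] are rejected.
- A constant map cannot be z-scored (error); a constant vector inside
  the robust sigmoid yields 0.5 with a warning; a LOESS fit at a grid
  point with a degenerate local design falls back to the local weighted
  mean.
- All generators and the pipeline driver are seeded; the manifest
  records a config hash and per-artifact SHA-256 checksums, floats are
  written with a fixed format, and no output embeds a timestamp, so
  identical (config, seed) runs are byte-identical.

## Problem sizes

The validation experiments run at: 400 parcels, λ = 0.3, 1000-rotation
ensembles, 1000 map pairs for correlation calibration, 100 seeds for
enrichment power and 1000 runs for its null rate, 20 seeds for decoy
selection accuracy, and 50 seeds for trajectory recovery — sizes chosen
so the complete suite and the acceptance script each finish in about
half a minute to a minute on a single CPU while leaving the Monte-Carlo
intervals tight enough to be meaningful.

## Known limitations

- Centroid-based assignment and interpolation are parcel-level
  simplifications of voxel-level rules; with very irregular parcels a
  centroid under-represents the parcel's extent.
- The greedy spin matching is the deterministic, duplicate-free variant
  of centroid-based spinning; it does not minimize total displacement
  (an optimal assignment would), and like all centroid spins it
  slightly degrades autocorrelation preservation relative to
  vertex-level spins.
- Differential stability uses pairwise-complete parcels; donors with
  very sparse sampling contribute noisier pairs rather than being
  reweighted.
- The within-sample normalization pass couples genes: planted single-
  gene patterns are recovered up to a small distortion (the noiseless
  end-to-end check bounds it) rather than exactly.
- LOESS confidence bands are not computed; the smoother reports the
  fit only.
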