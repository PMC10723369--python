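# Methods

`trace3d` analyzes cell-type-resolved chromatin-tracing data: per-cell 3D
coordinates of a genome-spanning panel of genomic loci, decoded upstream
from multiplexed DNA-FISH imaging, together with cell-type and genotype
labels and per-locus annotation tracks. This note documents the models,
estimators, numerical choices and the synthetic-data generator, in enough
detail to judge what a green test does and does not establish.

## Data model

Genomic coordinates are 0-based half-open (BED convention); genomic
distances are midpoint-to-midpoint. All spatial quantities are micrometers
(the proximity threshold of 750 nm is carried as 0.75 µm). Missing locus
detections are absent rows, never zero coordinates. Homolog indices come
from the tracing output as-is; the two homologs of a chromosome are treated
as independent polymers and are never merged except where an operation
explicitly pools "per cell". Real-valued table output uses 12 significant
digits, which round-trips below 1e-9 absolute error for any coordinate
under a millimeter and makes write→read→write byte-stable (the basis of the
determinism guarantees).

## Nuclear geometry

The nuclear boundary is the convex hull of all decoded loci of the cell and
the nuclear centroid is the arithmetic mean of the locus positions — no
membrane stain exists in the data model, and defining volume, centroid and
boundary from the same point cloud keeps the radial normalization
self-consistent. The normalized radial position of a locus is
`|p − c| / t*`, where `t*` is the distance from the centroid `c` to the
hull surface along the ray through `p`; the ray is intersected with the
hull facet planes with a 1e-9 µm tolerance and numerical overshoot is
clipped to 1. Cells with fewer than 4 non-coplanar loci are flagged
degenerate and excluded from volume statistics.

Hull normalization is biased relative to an idealized spherical nucleus:
for points uniform in a ball the true mean of r/R is 3/4, but the sampled
hull lies inside the sphere, inflating normalized values (genome-wide means
around 0.72–0.85 at realistic locus counts). All radial comparisons in the
package are therefore within-estimator comparisons; absolute radial values
should not be read as fractions of a physical nuclear radius.

Territory intermixing is k-NN chromosome purity: for each locus, the
fraction of its k (default 10) spatial nearest neighbors — excluding the
locus's own chromosome-homolog — that belong to a different chromosome,
averaged per homolog. It is bounded in [0, 1] and exactly reproducible by
exhaustive enumeration, which is how it is tested.

## Pairwise structure

Cis statistics pool same-homolog pairs only. The median-distance and
proximity-frequency matrices are computed over all homolog instances of a
cell type; entries backed by fewer than `min_pair_observations` (default
20) instances are masked absent, a stability gate for medians. Proximity is
strict (`d < 0.75 µm`). Differential matrices mask locus pairs closer than
2 Mb, where the short-range distance decay dominates and obscures
long-range differences.

Insulation is computed on the proximity-frequency matrix: IS(i) is the mean
of present entries in the off-diagonal window block upstream × downstream
of locus i, normalized by the chromosome mean so the score is scale-free
across cell types; the interquartile range of the normalized score
summarizes how prominent domain structure is. The default window is 4 loci
(~10 Mb at 2.5 Mb spacing). Quantifying chromosome-half-scale megadomains
requires a window at the scale of the structure — the quartiles of the
score distribution cannot register a single boundary dip that covers only
~15% of loci — so the megadomain acceptance analysis uses a quarter-
chromosome window (15 loci at the default 60-locus chromosomes). The window
is a parameter of `insulation_scores` and is recorded in output metadata.

## Compartment calling

Per cell type and chromosome: (1) the summary matrix is divided by its
expected value at each genomic distance (log-spaced bins, 8 per decade,
linear interpolation in log-distance, clamped at the terminal bins;
zero-mean bins, which arise when no contacts are observed in a distance
band, are skipped); (2) the Pearson correlation of matrix rows i and j is
taken over columns excluding i and j, requiring ≥10 mutually present
columns; (3) the correlation matrix (absent entries imputed 0, diagonal 1)
is eigendecomposed, and among the top 5 eigenvectors the one with the
largest |Pearson r| against the cell type's chromatin-accessibility track
is selected and oriented so the correlation is non-negative. Positive
loadings are A (active), negative B, exact zeros unassigned; loci with more
than half their correlation entries absent are unassigned. Accessibility-
guided selection is what makes calling robust in cell types whose leading
eigenvector reflects megadomain halves rather than compartments.

Two matrix sources are supported: the proximity-frequency matrix (default)
and the median-distance matrix, whose O/E is negated before correlation so
sign conventions align. Compartment switching between two cell types
classifies each locus A→A/A→B/B→A/B→B over loci assigned in both calls;
the associated expression analysis uses log2 fold changes with a
pseudocount (default 1) and one-way ANOVA with Tukey HSD.

## Local chromatin environment

The local A/B density ratio of an observation is the ratio of Gaussian-
kernel-weighted sums (`σ` default 1.0 µm, comparable to inter-locus
spacing; the kernel and bandwidth are package choices, exposed in config)
over trans-chromosomal observations labeled A versus B. Same-chromosome
observations of either homolog are excluded (treated as cis); unassigned
loci contribute to neither density. Ratios are absent when the total
kernel weight falls below `min_total_weight` (default 0.5) or the B density
is zero — absence rather than pseudocounts, so unbounded ratios cannot
distort medians. Cell-type profiles are medians over cells with a minimum
cell count (default 10).

Association heatmaps report, for a reference set of loci (those near a cell
type's differentially expressed genes within 100 kb, or its super-enhancer
loci), the median fractional change of the ratio in every other cell type
relative to the reference type; the super-enhancer analysis carries a
seeded randomization control drawing equal-size SE sets regardless of
origin type.

## Transcription coupling

Gene-to-locus mapping takes the nearest panel locus by |TSS − midpoint| on
the same chromosome (ties to the lower start coordinate; an optional
distance cap leaves far genes unmapped). DE scores are Welch two-sample t
statistics on counts normalized to 10,000 per cell and log1p-transformed
(a bypass accepts pre-normalized values), oriented KO − WT. "Equal bins"
are equal-count (quantile) bins — sizes differing by at most one, ties
broken by stable input order — because radial distributions are strongly
non-uniform and equal-width bins produce unusable per-bin confidence
intervals; equal-width binning is available by flag. Per-bin confidence
intervals are the normal approximation (1.96·sd/√n). Group tests follow
the stated enums: pairwise Mann-Whitney U with Benjamini-Hochberg,
pairwise Welch t with Bonferroni, or one-way ANOVA with Tukey HSD; a
separate one-sample helper tests per-group shifts against zero with
Bonferroni correction.

Two estimator cautions, both enforced in the acceptance analyses:

- Binning KO−WT radial deltas by the same noisy WT profile that enters the
  delta induces regression-to-the-mean at the bin extremes; the bin axis
  should come from a held-out half of the WT cells.
- Per-locus profile deltas share cell samples, so they are cluster-
  correlated across loci: dispersion-based effect sizes that assume
  independent loci (and single-run correlations between two profile-level
  quantities) understate null variability. Profile-to-DE correlations are
  averaged over independent replicates, and DE scores are computed on an
  expression cohort simulated independently of the imaging cohort —
  mirroring a study design where sequencing and imaging come from
  different animals.

## Synthetic data

The generator is a test instrument, not a biophysical model: it produces
data with the statistical structure the analyses assume, with planted,
recoverable ground truth.

Panel: `n_chrom × loci_per_chrom` loci at exact 2.5 Mb spacing (the
genome-wide panel design it emulates), plus optional super-enhancer loci
interleaved at one-third spacing with round-robin origin cell types.
Compartments: alternating A/B blocks of 10 loci for a reference cell type;
other types flip an independent seeded subset with expected fraction 0.15;
SE loci are A in their origin type and B elsewhere.

Cells: spherical nucleus of cell-type radius; per chromosome homolog a
territory center is drawn in the nucleus with a radial preference set by
the chromosome's B fraction and ρ; loci follow an order-1 autoregressive
chain (α = 0.6, stationary spread 0.5× the territory radius) confined to
the territory sphere, producing spatial-distance decay with genomic
distance. Twenty synchronous relaxation iterations then apply: a pull of
each locus toward the nucleus-wide centroid of its compartment label (step
0.05·λ per iteration), a radial push of B outward / A inward (step
0.04·ρ·R), and a pull toward the chromosome-half centroid (step 0.15·µ)
for megadomains, followed by radial re-projection into the nucleus. The
phase step is deliberately moderate: λ = 1 contracts compartment spread to
~0.36 of its initial value, enough for unambiguous compartment recovery
but not enough to collapse the nucleus into two point clusters, which
would empty the interior and destroy hull-normalized radial structure.
Radial A/B polarization is carried by ρ. Localization noise is isotropic
Gaussian (σ = 0.05 µm, typical of FISH localization precision) and
detections drop independently with probability 1 − detection_rate
(default 0.8). KO cells multiply λ and ρ by 1 − δ (default δ = 0.8).

Defaults are the acceptance scale: 5 chromosomes × 60 loci, two cell types
("neuron": R = 5 µm, λ = 0.8, ρ = 0.3, µ = 0; "glia": R = 3.5 µm, λ = 0.8,
ρ = 0.2, µ = 0.4), 300 cells per type. Expression is one gene per genome
locus, `count ~ Poisson(base_rate · ratio^β_AB · exp(β_R (0.5 − radial)))`
with the ratio and radial position computed on noiseless truth positions
(base rate 5, β_AB = β_R = 1); the ATAC track is the WT mean latent rate
plus 10% seeded noise, so accessibility genuinely correlates with the
planted A compartment without being a copy of it. All randomness flows
from one root seed through named per-stage streams, so stages regenerate
independently and identical configurations are byte-identical.

What the generator does not emulate: polymer dynamics or calibrated
contact physics, barcode decoding errors, segmentation errors, anisotropic
z-resolution, doublets, or cell-type misassignment. A green recovery test
establishes that the estimators invert this generative structure at
realistic noise and dropout — not that they would recover biology from
real images.

## Numerical and degenerate-input conventions

Absent values are NaN throughout and propagate as absence, never as zero.
Correlations on constant vectors are reported absent rather than raised.
Eigendecomposition uses the symmetric solver; PC selection ties break
toward the larger eigenvalue. Ray casting rejects facets within 1e-9 µm of
parallelism. The QC gate removing cells below a detected-locus threshold
(default 10) is configurable and reported, as the upstream study does not
state per-cell retention thresholds.

## Known limitations

- Compartment calls on chromosomes shorter than ~20 loci are fragile: the
  correlation matrix has too few informative columns.
- The insulation IQR conflates megadomain prominence with any other
  domain-scale structure (including strong A/B blocks); comparisons should
  fix the other structure axes, as the acceptance analysis does.
- The local-ratio estimator is bandwidth-dependent; σ far from the
  inter-locus spacing scale degrades discrimination in both directions.
- Radial profiles from hull normalization are estimator-biased (see above)
  and only comparable within the same panel density.
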