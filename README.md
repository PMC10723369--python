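# trace3d

Cell-type-resolved 3D-genome analysis of multiplexed chromatin-tracing
data.

Genome-scale DNA-FISH imaging yields, for each cell in a tissue, the 3D
positions of hundreds of genomic loci on every chromosome homolog,
together with a transcriptomic cell-type label. `trace3d` turns those
decoded coordinates into the quantities used to compare chromatin
organization across cell types and genotypes:

- **Nuclear geometry** — convex-hull nuclear and chromosome-territory
  volumes, normalized radial positions (distance to the nuclear centroid
  over the centroid-to-boundary distance in the same direction, 0 =
  center, 1 = periphery), and a k-nearest-neighbor territory-intermixing
  score.
- **Pairwise structure** — per-cell-type median cis-chromosomal distance
  matrices, proximity frequencies (strict d < 0.75 µm), differential
  matrices with short-range masking, and normalized insulation scores
  whose interquartile range quantifies megadomain prominence.
- **A/B compartments** — observed/expected normalization of the summary
  matrix, row-wise Pearson correlation, eigendecomposition, and selection
  of the principal component best correlated with chromatin accessibility
  (PC1 is not always the compartment axis: megadomains can dominate it).
  Loci with positive oriented loadings are A (active), negative are B.
- **Local chromatin environment** — the per-locus ratio of Gaussian-
  kernel densities of trans-chromosomal A versus B loci, a proxy for how
  active a locus's nuclear neighborhood is; association of differentially
  expressed genes and super-enhancers with changes in this ratio across
  cell types.
- **Transcription coupling** — radial-position/activity correlations,
  gene-to-locus mapping, Welch-t differential-expression scores, binned
  profiles, and wild-type versus knockout deltas with Mann-Whitney/BH,
  Student-t/Bonferroni, or ANOVA/Tukey testing.
- **Synthetic data** — a seeded generator that plants A/B blocks,
  compartment switching, megadomains, radial bias, expression coupling
  and a knockout genotype with attenuated segregation, plus ground-truth
  sidecars, so every estimator can be validated against known structure.

See `docs/methods.md` for models, estimator choices and limitations.

## Worked example

Simulate a two-chromosome dataset with planted compartments and call them
back from the proximity matrix:

```python
import trace3d as t3
from trace3d import matrices as mat, compartments as comp

params = t3.SimParams(n_chrom=2, loci_per_chrom=30, n_cells_per_type=100, seed=7)
panel, truth, ds, expr, tracks = t3.simulate(params)

prox = mat.pairwise_proximity_matrix(ds, "neuron", "chr1")
call = comp.call_compartments_from_summary(
    prox, panel, tracks["atac"].for_cell_type("neuron"))

print("selected PC:", call.selected_pc)
print("corr with accessibility: %.3f" % call.corr_with_accessibility)
print("label counts:", call.labels.value_counts().to_dict())
planted = truth.labels_for("neuron").reindex(call.assigned().index)
print("agreement with planted labels: %.3f" % (call.assigned() == planted).mean())
```

prints

```
selected PC: 1
corr with accessibility: 0.990
label counts: {'A': 20, 'B': 10}
agreement with planted labels: 1.000
```

The accessibility-guided selection picked PC1 (this simulated type has no
megadomain structure), the eigenvector correlates 0.99 with the ATAC
track, and every called locus matches its planted compartment. The A/B
imbalance on chr1 reflects the planted block layout, not an artifact.

## Command line

```sh
trace3d simulate --out sim/ --seed 1 --ko-cells-per-type 100
trace3d run --in sim/ --out results/       # all stages + manifest
trace3d matrices --in sim/ --out m/ --cell-type neuron --chrom chr1 --kind proximity
trace3d compartments --in sim/ --out c/ --cell-type neuron --accessibility sim/tracks/atac.tsv
```

`trace3d run` executes geometry → matrices → compartments → local
environment → coupling and writes a `manifest.json` recording the config,
package version and SHA-256 checksums of all inputs and outputs; a rerun
with the same config and seed is bit-identical.

## Acceptance script

`scripts/acceptance.py` regenerates a synthetic dataset from scratch at
the given seed, runs every pipeline stage end to end, and writes its JSON
output:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
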