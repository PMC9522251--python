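# cisgrn

Toolkit for predicting enhancer-like regions in stem-cell chromatin data and
building transcription-factor regulatory networks on top of them:

- **Enhancer calling** — H3K27ac peaks within a configurable gap
  (default 500 bp) of an H3K4me1 peak become enhancer-like regions; signal
  at regions is summarised as the mean of a track sampled every 10 bp
  across ±1000 bp of the region center and compared against random genomic
  background with the Wilcoxon rank-sum test.
- **Expression profiling** — per-gene proportional expression across the
  X1/X2/Xins FACS compartments, an information-content scalar for
  compartment specificity, and a seven-way enrichment classification.
- **Motif tools** — PWM Shannon entropy / information content and a
  many-to-many motif→TF map used to expand footprint calls per TF.
- **GRN construction** — enhancers assigned to the nearest TSS; footprints
  of a TF's motif inside an enhancer create TF→target links (bound and
  unbound classes kept separate); an X1-restricted subnetwork is exported
  with expression attributes.
- **GRN validation** — observed vs expected regulatory links against
  knockdown differential-expression sets, with the closed-form expectation
  `ndge·ncisTF/nge` under independence and a DE-resampling permutation
  test.
- **Synthetic data** — a fully deterministic simulator that emits every
  pipeline input as plain text with known ground truth (planted enhancers,
  planted TF→target adjacency, planted compartment classes, planted DE
  enrichment), used throughout the test suite.

## CLI

```sh
# generate a synthetic dataset with ground truth
cisgrn simulate --seed 1 --out data/

# run the full pipeline (enhancers, profiles, links, GRN, validation)
cisgrn run-all --in data/ --out results/ --seed 1

# just call enhancer-like regions from two BED peak files
cisgrn call-enhancers --ac ac.bed --me1 me1.bed --out enhancers.bed
```

A dataset directory contains: `genome.sizes`, `genes.gtf`, `expr.tsv`,
`ac.bed`, `me1.bed`, five bedGraph tracks (`h3k27ac`, `h3k4me1`,
`lpt_lfc`, `atac`, `fpscore`), `footprints.tsv` (chrom, start, end,
motif_id, score, bound), `motifs.jaspar`, `motif_tf_map.tsv`,
`rnai_de.tsv`, and `truth.json`.

`run-all` writes `enhancers.bed`, `signal_tests.tsv`, `profiles.tsv`,
`links.tsv`, `grn_nodes.tsv`/`grn_edges.tsv`, `validation.tsv`, and
`validation_summary.tsv`. All outputs are byte-deterministic given the
seed.

## Conventions

All internal coordinates are 0-based half-open (BED convention); GTF
import/export is the only place 1-based inclusive coordinates appear.
bedGraph gaps read back as signal 0. Peaks and footprints may be
strandless; genes must be stranded (the TSS is undefined otherwise).
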