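# mitochar

Characterization toolkit for circular mitochondrial genomes:

- **genome model** — 1-based inclusive, wrap-aware coordinates on a circle;
  annotation TSV and FASTA I/O; gene-organization accounting (lengths,
  intergenic spacers, overlaps, strand census, protein-coding-gene interval
  union). Printed length columns in annotation tables are treated as
  checksums and always recomputed from coordinates.
- **composition** — per-region base counts, A+T%, AT/GC skews
  ((A−T)/(A+T), (G−C)/(G+C); zero denominators reported as *undefined*),
  vertebrate-mitochondrial translation (NCBI table 2) with
  complete/incomplete (T / TA) stop classification, codon usage, RSCU and
  amino-acid distributions.
- **repeats** — tandem-repeat copy counting (maximal run of non-overlapping
  motif windows, optional per-copy mismatch budget) and exact motif
  occurrence scans in the control region.
- **variation** — alignment-based polymorphic-site census (gaps/N are
  missing data, not alleles), reference-directed amino-acid substitution
  mapping, and a parameterizable diagnostic-site haplotype classifier
  (default: the 4-site cytochrome-b E1/E2/A1/A2/A3 scheme).
- **phylo** — TN93 pairwise distances (pairwise deletion, pooled empirical
  frequencies, saturation reported as *inapplicable*), deterministic
  neighbor joining, seeded nonparametric bootstrap supports, outgroup
  rooting and Newick I/O.
- **synth** — synthetic pig-like mitogenomes built on a packaged 37-gene +
  control-region coordinate skeleton, with tunable base composition,
  control-region tandem repeats, per-sample variant injection, haplotype
  panels, and TN93 alignment simulation down a tree — every stage is
  testable without downloading anything.

## CLI

```sh
# make synthetic inputs
mitochar synth genome --seed 1 --out genome.fasta --annot annot.tsv

# individual stages
mitochar organize    --genome genome.fasta --annot annot.tsv --outdir out/
mitochar composition --genome genome.fasta --annot annot.tsv --outdir out/
mitochar rscu        --genome genome.fasta --annot annot.tsv --outdir out/
mitochar repeats     --genome genome.fasta --annot annot.tsv --outdir out/ \
    --motif CGTACACGTG

# alignment-based stages
mitochar synth alignment --tree tree.nwk --length 5000 --seed 1 --out aln.fasta
mitochar variation --aln aln.fasta --out variation.tsv
mitochar haplotype --aln aln.fasta --out haplotypes.tsv
mitochar phylo --aln aln.fasta --outgroup out --replicates 1000 --seed 42 \
    --out tree.nwk

# everything from one YAML config (flags override config values)
mitochar all --config run.yaml
```

Example `run.yaml`:

```yaml
genome_fasta: genome.fasta
annotation_tsv: annot.tsv
alignment_fasta: aln.fasta      # only needed for variation/haplotype/phylo
outdir: out
stages: [organize, composition, rscu, repeats, variation, haplotype, phylo]
outgroup: out
replicates: 1000
seed: 42
```

Outputs are a pure function of inputs + config + seeds; every report header
carries the package version and a configuration hash, and reruns are
byte-identical.

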