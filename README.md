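# zdep

Desk-scale analysis of histone-variant (H2A.Z) genic deposition and its
coupling to transcription: broad-island calling from windowed ChIP
coverage, differential islands between conditions, TSS/gene-body
partitioned peak-to-gene assignment, metagene profiling with expression
quintiles and k-means deposition-pattern clusters, a simplified
negative-binomial differential-expression test, bootstrap
overlap-enrichment of DEG sets among differential-deposition gene
categories, hypergeometric term enrichment, and fuzzy k-means interaction
clustering — plus a synthetic-data module that generates every input with
planted structure so the whole pipeline is testable offline.

## Layout

| module | what it does |
| --- | --- |
| `zdep.simulate` | synthetic annotation, coverage, RNA counts, terms, truth table |
| `zdep.io` | GFF3 / bedGraph / BED6+ / TSV readers and writers, coordinate conventions |
| `zdep.islands` | SICER-style island calling and differential islands |
| `zdep.regions` | TSS (−250..+500) / gene-body (+500..TTS+250) partition, island→gene assignment, differential categories |
| `zdep.metaprofile` | metagene matrices (50/100/50 bins), quintiles, pattern clusters, replicate QC |
| `zdep.expression` | size factors, FPKM, rlog-like transform, NB Wald DE test, fuzzy c-means |
| `zdep.enrichment` | bootstrap overlap statistic with binomial test, SEA-style term enrichment |
| `zdep.pipeline` | `run-all` orchestration with deterministic manifest |

## CLI

Every stage is a subcommand of `zdep`:

```sh
# generate a synthetic fixture bundle
zdep simulate --seed 1 --out bundle/

# island calling and differential islands
zdep call --chip bundle/coverage/control_chip_r1.bedgraph \
          --control bundle/coverage/control_input_r1.bedgraph \
          --window 200 --gap 200 --fdr 0.01 --out islands.bed
zdep diff --chip-a ... --chip-b ... --control-a ... --control-b ... --out diff.bed

# gene assignment, metaprofiles, DE, enrichment, clustering
zdep assign --diff-islands diff.bed --gff bundle/annotation.gff3 --out calls.tsv
zdep profile --chip ... --control ... --gff ... --clusters 3 --out profile.tsv
zdep de --counts bundle/rna_counts.tsv --design bundle/samples.tsv --out de.tsv
zdep cluster --counts bundle/rna_counts.tsv --k 14 --out memberships.tsv

# the whole pipeline from a YAML config (simulate block or real paths)
zdep run-all --config run.yaml --out results/
```

A minimal `run.yaml`:

```yaml
simulate:
  n_genes: 400
  seed: 7
seed: 7
island_fdr: 0.01
de_fdr: 0.001
```

`run-all` writes BED/TSV artifacts plus `manifest.json` with a parameter
echo and sha256 checksums; re-running with the same seed reproduces every
byte.

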