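# kqdist

Quality-weighted alignment-free comparison of sequencing read sets.

`kqdist` compares genomes and metagenomes directly from their FASTQ reads —
no assembly, no reference — using k-mer count statistics. Besides the
classic `D2` / `D2*` family it implements quality-weighted variants
(`D2^q`, `D2^q*` and their normalized `d`-forms) in which every k-mer
occurrence contributes its probability of having been sequenced correctly,
derived from the per-base phred scores. The package also ships the two
evaluation pipelines these measures are typically scored with:

* **phylogeny reconstruction from reads** — simulate a family of diverged
  sequences, sample noisy reads with calibrated qualities, build UPGMA/NJ
  trees from the dissimilarity matrices, and score them with the
  Robinson–Foulds distance against the true tree;
* **metagenome clustering** — simulate metagenome mixtures, cluster the
  `d2^q*` matrix, and report assignment accuracy plus the height of the
  dendrogram node that separates the two sample types.

## Layout

| module | contents |
| --- | --- |
| `kqdist.io_readsets` | strict 4-line FASTQ reader/writer (phred+33/+64), sample lists, phred↔probability |
| `kqdist.kmer_core` | strand-symmetric plain & quality-weighted k-mer counting (dense 2-bit arrays for k ≤ 12, sparse above), order-0 background model |
| `kqdist.measures` | the eight statistics `D2, D2*, D2^q, D2^q*, d2, d2*, d2^q, d2^q*`; all-pairs matrices; PHYLIP/TSV matrix I/O |
| `kqdist.phylo` | UPGMA, neighbor joining, Robinson–Foulds, Newick round-trip, discriminating-node height, clustering accuracy |
| `kqdist.simulate` | sequence-family evolution, read simulation with exactly phred-calibrated errors, metagenome mixtures, both benchmark pipelines |
| `kqdist.cli` | `kqdist` command-line tool |

## CLI

Compare n FASTQ samples (one file per sample, listed one path per line,
optionally `path<TAB>label`) and write one matrix per measure in PHYLIP and
TSV dialects:

```sh
kqdist compare --input samples.txt --k 7 --measures all --out results/run
kqdist tree --matrix results/run.d2qstar.7.phylip --method upgma --out tree.nwk
kqdist rf tree.nwk other.nwk
```

Useful flags: `--phred-offset 64`, `--background pooled|global`,
`--literal-d2-formula` (emit the ½·ratio form instead of the default
½·(1−ratio) dissimilarity), `--relaxed-phylip`. Exit codes: 0 success,
2 usage, 3 input error, 4 numerical failure; logs go to stderr only.

Synthetic data and benchmarks:

```sh
kqdist simulate family --n-sequences 10 --relatedness 70 --seed 1 --out fam
kqdist simulate metagenome --seed 1 --out meta
kqdist benchmark phylo --replicates 10 --seed 1 --out rf.tsv
kqdist benchmark meta --k 8 --seed 1 --out meta.tsv
```

`quality_spread` (CLI: `--quality-spread`) draws each base's true error
rate from a range of phred values around the base error rate and emits the
matching integer quality, so qualities are exactly calibrated *and*
informative per base — the regime in which the quality-weighted measures
pay off.

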