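# pedna

Tools for analysing **protected extracellular DNA (peDNA)** — the DNA
recovered from size-filtered (<0.22 µm), DNase-treated environmental
samples. What is traditionally sequenced as a "virome" is really a
mixture of virus genomes and host DNA travelling inside virions
(transduction), gene transfer agents (GTAs) and extracellular vesicles
(EVs). `pedna` implements the bioinformatic side of that reframing for
microbial ecologists:

* **split** — partition peDNA read pairs into viral (vpeDNA) and
  non-viral (nvpeDNA) fractions: contigs ≥2 kb are classified
  viral/non-viral (translated-ORF hallmark homology, optionally a
  composition score or external classifier labels), reads are mapped
  back, and the non-viral ratio
  `nv = n_nonviral / (n_viral + n_nonviral)` is reported over mapped
  pairs.
* **mechanism** — attribute nvpeDNA to source MAGs (≥100 kb) and label
  each top-recruiting MAG *EV producer*, *GTA producer* or *transducer*:
  a MAG with an active provirus (region depth ≥ 3× the background of its
  coverage profile) transduces; a MAG with a functional RcGTA-like
  cluster (>10 genes hit at E ≤ 1e-5, pident > 50, all core genes
  present) produces GTAs; with neither, the DNA is attributed to EVs;
  contradictory evidence is *unclear*.
* **ssu** — a descriptive SSU (16S/18S) rRNA alignment-rate screen.
  Because EVs and GTAs package rRNA genes like any other locus, the rate
  neither proves nor disproves contamination; the microbial-metagenome
  average (0.078%) is attached as context only.
* **profile** — per-mechanism COG-category profiles with signed fold
  changes against the matching metagenome
  (`fc = f_label/f_microbial` if ≥1, else `−(f_microbial/f_label)`; no
  value can fall in (−1, 1)), plus the transposase share of the Mobilome
  category.
* **simulate** — a synthetic marine community generator (genomes with
  planted SSU genes, COG genes, transposases, RcGTA-like clusters and
  integrated proviruses; paired reads drawn under explicit carrier
  models with per-read truth tables), which is the package's test bed.

The supporting primitives (FASTA/FASTQ I/O, 6-frame ORF finding,
Smith–Waterman protein search with Karlin–Altschul E-values, a k-mer
seed-and-vote read mapper) are desk-scale stand-ins for prodigal,
diamond and bbmap; see `docs/methods.md` for contracts, thresholds and
limitations.

## Worked example

Simulate a small community (one EV producer, one GTA producer, one
transducer) and label its MAGs:

```sh
pedna simulate --n-hosts 3 --n-viruses 0 --ev 1 --gta 1 --transducers 1 \
      --n-pairs 1500 --seed 4 --outdir sim
pedna mechanism --mags sim/genomes.fasta --reads sim/pedna \
      --hallmarks sim/hallmark.faa --gta-refs sim/gta.faa \
      --top-k 3 --outdir mech
```

which prints

```
host_000	EV_producer	provirus=none_found	gta_genes=1	pairs=600
host_002	transducer	provirus=active	gta_genes=0	pairs=473
host_001	GTA_producer	provirus=none_found	gta_genes=14	pairs=427
```

Reading the columns: `host_002` carries a provirus whose region recruits
peDNA far above its flanks (an actively transducing phage), `host_001`
carries the full 14-gene RcGTA-like cluster, and `host_000`, recruiting
600 read pairs with neither signal, is attributed to EV production — all
three matching the simulator's planted truth. The per-MAG evidence
(depth ratio, core-gene set, recruitment) is written to
`mech/mechanism_calls.tsv` so a label can be audited the way the
original manual curation was. Continuing with
`pedna profile --mags sim/genomes.fasta --labels mech/mechanism_calls.tsv --pedna-reads sim/pedna --meta-reads sim/metagenome --cog-refs sim/cog.faa --outdir prof`
prints `Mobilome transposase share: 83.3%` — the fraction of
Mobilome-category reads assigned to transposase clusters.

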