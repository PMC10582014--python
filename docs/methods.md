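# Methods

`pedna` re-implements, at desk scale, a two-part bioinformatic pipeline for
protected extracellular DNA (peDNA) — the DNA recovered from size-filtered
(<0.22 µm), DNase-treated water samples, which is a mixture of virus
genomes and host DNA packaged in virions (transduction), gene transfer
agents (GTAs) and extracellular vesicles (EVs):

1. **split** — partition peDNA read pairs into a viral and a non-viral
   fraction by classifying assembly contigs and mapping reads back to them;
   the headline statistic is the non-viral/viral read-pair ratio
   `nv = n_nonviral / (n_viral + n_nonviral)` (unmapped pairs excluded).
2. **mechanism** — attribute peDNA to source MAGs and label each
   top-recruiting MAG an *EV producer*, *GTA producer* or *transducer*
   from two pieces of evidence: provirus activity in the coverage profile
   and the presence of an RcGTA-like gene cluster.

Everything runs against a synthetic community generator with per-read
truth, so no external data or databases are required.

## Primitives and their stand-ins

The production pipeline this package models is normally assembled from
external tools. Each is replaced by a compact, contract-equivalent
primitive:

| stage | stand-in |
|---|---|
| gene calling (prodigal) | exhaustive 6-frame maximal start→stop ORF finder; starts {ATG, GTG, TTG}, stops {TAA, TAG, TGA}, ≥50 codons; alternative starts translate as M |
| protein homology (diamond blastp) | Smith–Waterman, BLOSUM62, affine gaps (open 11, extend 1), Karlin–Altschul E-values `E = K·m·n·e^(−λS)` with λ=0.267, K=0.041 (gapped BLOSUM62 defaults); unknown residues score 0 (wildcard X) |
| read mapping (bbmap) | k-mer seed-and-vote mapper: k=21 seeds sampled every 4 bp, single best target per mate by vote (ties → lexicographically smaller id), ungapped extension identity; a pair counts only when both mates place on the same target at ≥ the identity threshold |
| viral prediction (VirSorter2/CheckV) | classifier A: ≥1 translated-ORF hit to the hallmark protein set at E ≤ 1e-5 and pident > 50 |
| viral prediction (DeepVirFinder) | classifier B: tetranucleotide-composition similarity to the hallmark-bearing contigs — a declared, replaceable stand-in, **off by default** (merge rule `a_only`) because 4-mer composition carries no signal on i.i.d. synthetic DNA; real classifier output can be supplied as an external label TSV which bypasses both classifiers |
| SSU screen (ViromeQC) | fraction of pairs with ≥1 mate mapping to an SSU reference at ≥0.8 identity over ≥50 bp |
| read ORFs (FragGeneScan) | longest stop-free frame ≥20 codons per mate, both strands |

The Smith–Waterman engine is `Bio.Align.PairwiseAligner`; an independent
full-matrix Gotoh DP in the test suite checks score equality on random
instances. The mapper models substitutions only (the generator emits no
indels); ambiguous bases count as mismatches.

Coordinates are 0-based, half-open, forward-strand anchored throughout;
ORF intervals include the stop codon, protein lengths do not.

## Synthetic community generator

Reference sets (6 viral hallmark proteins — major capsid, large terminase,
portal, two variants each; the 14-gene RcGTA-like set with 10 core genes
TG, TAP, TTP, MTP, HTJ, GP6, MCP, Prot, PPP, MBP; 36 COG clusters over 12
categories; a 1.5 kb SSU rRNA gene) are synthetic random sequences fixed
by an internal seed. Planted genes are back-translated from these same
references with uniformly random synonymous codons, so every homology
search downstream is closed over the bundled sets. Hosts carry one SSU
gene (2% diverged from the reference), 12 COG genes spanning all
categories, and 2 transposase genes; all planted genes sit on the forward
strand at uniformly random non-overlapping positions.

* **Hosts** default to 120–180 kb (above the 100 kb MAG filter), viruses
  to 35–45 kb.
* **GTA producers** carry the full 14-gene cluster contiguously (20–60 bp
  spacers); a dispersed (Tateyamaria-style) layout with three subclusters
  ≥25 kb apart is available per host.
* **Transducers** get one dedicated virus genome integrated at a random
  inter-genic point. Virus genomes carry 4–6 hallmark genes spaced nearly
  evenly (±10% jitter) with the outermost genes within 2 kb of the
  termini. This placement is a deliberate generator choice: the provirus
  detector links hallmark hits within 15 kb and pads by 5 kb, so the
  hallmark chain must tile the genome for the detected region to recover
  the full integrated boundaries, the role VirSorter2's whole-region
  scoring plays on real data.
* **Abundances**: per-genome cell abundance and peDNA output are
  independent log-normal draws (σ=0.5), reflecting the observed
  decoupling of peDNA recruitment from metagenome abundance.

### Carrier model

Each peDNA read pair draws a carrier from the mix weights, a source
genome from the carrier-eligible pool (∝ peDNA abundance), a carrier
fragment, and a sequencing insert (N(400, 80), ≥ read length) uniformly
inside the fragment; mates are the 2×150 bp insert ends with independent
substitution errors (default 0.5%). Library preparation shears all
carriers alike, which is why reads derive from an insert rather than the
raw fragment ends; depth and abundance expectations are unchanged (every
pair contributes 2×read_len bases from its source).

Fragment rules per carrier: virion → the packaged virus genome or a
transducer's provirus interval; generalized transduction → a
viral-genome-length (40 kb) window anywhere on a transducer host;
specialized transduction → a 10 kb window adjacent to the provirus; GTA →
N(4.5 kb, 1 kb) window (RcGTA-like packaging length; the capsid is far
too small for anything larger); EV → log-normal cargo, median 2 kb,
σ_log=0.6 (no published distribution exists; this matches small-vesicle
cargo scales). `free_dna` and `cell` carriers exist but default to
weight 0 — the in-silico analogue of DNase treatment plus filtration.

**Provirus induction.** A transducer's provirus enters the virion source
pool with weight `a_pedna · I · L_prov/L_genome`, where `I` is the
induction factor (default 10). `default_pedna_mix` sets the virion:
transduction weight ratio to `Z_v/Z_t` (the two pools' normalizers),
which makes the expected provirus/flank depth ratio exactly `I` from
virion particles, plus one background unit from generalized transduction
— so the realized ratio is `I+1` ≈ 11 at defaults, comfortably above the
activity threshold.

## Decision thresholds

* Contig length filter ≥2000 bp; MAG length filter ≥100 000 bp (both
  inclusive).
* Provirus activity: a candidate region is **active** when its mean depth
  is ≥ α = 3 times the background (10%-trimmed mean over non-candidate
  1 kb windows), **absent** when its depth is ≤ ε = 0.05 of a background
  that is itself ≥ 1×, otherwise **inactive**. The thresholds are
  declared stand-ins — the source analyses state only "increased
  coverage" and "recruited no reads" — and are configurable on the CLI.
  Note that the 5 kb detection pads recruit at background level, so a
  padded region of a truly silent provirus scores *inactive* rather than
  *absent* unless the provirus dominates the region; scoring the unpadded
  provirus interval directly yields *absent*. Either way the final label
  is EV producer.
* GTA call: **functional** ⇔ >10 distinct reference genes hit (E ≤ 1e-5,
  pident > 50) and all 10 core genes present; **dispersed** when hits
  span >2 loci ≥20 kb apart.
* Decision rule (pure function of the two calls): active ∧ ¬functional →
  transducer; functional ∧ ¬active → GTA producer; active ∧ functional →
  unclear; a no-signal coverage flag on a recruiting MAG → unclear;
  otherwise EV producer.
* Mechanism read partition at ≥95% identity; general mapping at ≥90%.

## Functional profiling

Reads inherit their best MAG's mechanism label, per-mate protein
fragments are assigned to COG clusters (best hit, E ≤ 1e-5, query cover
≥80%, subject cover ≥10%; no identity floor, so the E-value threshold
admits the occasional low-identity chance hit, as it does for diamond).
A gene is *high-coverage* when its peDNA recruitment (pairs/kb) exceeds
the mean by 2 population SDs across the MAG set; genes exactly on the
cutoff count as high, zero variance or <3 genes flags nothing.

The published per-category frequency is `freq = n_hc / n_tot` (share of
high-coverage reads among the category's reads). Because the printed
formulas are ambiguous about whether frequencies are coverage shares or
plain composition, both readings are computed and emitted (`freq_hc` and
`freq_raw = n_tot/Σn_tot`); fold changes are reported for both. Signed
fold change: `f_l/f_m` when ≥1, else `−(f_m/f_l)`, so no value falls in
(−1, 1); a single zero frequency is replaced by half the smallest nonzero
frequency of the pair, double zeros are missing. The transposable-element
regex `IS\d\+*|Tn\d\+*|attTn\d\+*|transposase|Transposase` is applied
verbatim as published (the `\+*` literal included).

## What the tests do and do not show

The generator produces i.i.d. random backbones with planted genes,
substitution-only errors, fixed read length and a closed reference world.
Passing tests therefore demonstrate that the pipeline's logic — the
partition arithmetic, the carrier accounting, the coverage/homology
evidence and the decision rule — recovers planted truth under the stated
noise model. They do not certify performance on real data, where
classifier error, assembly fragmentation, strain microdiversity, indels,
diverged homologs and database incompleteness dominate. In particular,
classifier A's near-perfect contig labels reflect the closed reference
world, not VirSorter2-level accuracy.

Problem sizes used by the test and acceptance runs: purification
controls 5 genomes × 20 000 pairs; mixture recovery 8 genomes × 50 000
pairs; mechanism recovery 30 MAGs (10 per mechanism) × 100 000 pairs at
induction 10×. These sizes give binomial standard errors well inside the
asserted tolerances while keeping a full run of suite plus acceptance
script within a few minutes on one CPU.

## Known limitations

* All reference proteins are synthetic; no claim of biological sequence
  realism, only of pipeline-contract realism.
* The mapper has no indel model and reports at most one target per pair;
  multi-mapping reads (e.g. between near-identical strains) are resolved
  by vote and tie-break, not reported as secondary hits.
* The composition classifier (B) is a placeholder; with synthetic
  backbones its score is uninformative, which is why the default merge
  rule ignores it.
* Provirus boundary precision is limited by hallmark placement plus the
  5 kb pad; there is no CheckV-style boundary refinement.
* Specialized transduction and contamination carriers are implemented but
  not exercised by the default scenarios.
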