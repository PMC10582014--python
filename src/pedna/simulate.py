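"""Synthetic marine-community generator with per-read truth.

Builds host and virus genomes carrying coordinate-anchored planted features
(SSU rRNA genes, COG-labelled genes, transposases, RcGTA-like gene
clusters, integrated proviruses with viral hallmark genes), then draws
paired-end read sets under explicit particle carrier models (virion,
generalized/specialized transduction, GTA particle, extracellular vesicle)
together with machine-readable truth tables.  Everything is deterministic
under a fixed seed.

The bundled reference sets (hallmark proteins, GTA gene set, COG clusters,
SSU rRNA) are synthetic sequences generated from a fixed internal seed;
the simulator back-translates genes from these same references, so the
homology searches downstream are closed over them.
"""

from __future__ import annotations

import functools
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    _CODON_MAP,
    ReadPair,
    SeqRecord,
    encode_dna,
    read_fastq,
    write_fasta,
    write_fastq,
)

# ---------------------------------------------------------------------------
# bundled synthetic reference sets
# ---------------------------------------------------------------------------

_REF_SEED = 731_001  # fixed: references are stable package constants
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: carrier channels of the peDNA particle model
CARRIERS = (
    "virion",
    "transduction_general",
    "transduction_specialized",
    "gta_particle",
    "ev",
    "free_dna",
    "cell",
)

MECHANISMS = ("EV_producer", "GTA_producer", "transducer", "none")

#: RcGTA-like gene set: (name, core, protein length).  Core genes follow the
#: canonical RcGTA cluster nomenclature.
GTA_GENE_SPECS = (
    ("AT", False, 170),
    ("MBP", True, 180),
    ("TG", True, 290),
    ("Pept", False, 200),
    ("TMP", False, 150),
    ("Hyp", False, 120),
    ("TAP", True, 240),
    ("TTP", True, 160),
    ("MTP", True, 230),
    ("HTJ", True, 140),
    ("GP6", True, 330),
    ("MCP", True, 360),
    ("Prot", True, 210),
    ("PPP", True, 420),
)

GTA_CORE_GENES = frozenset(n for n, c, _ in GTA_GENE_SPECS if c)

HALLMARK_SPECS = (
    ("major_capsid_1", 380),
    ("major_capsid_2", 350),
    ("terminase_large_1", 430),
    ("terminase_large_2", 410),
    ("portal_1", 470),
    ("portal_2", 450),
)

#: one-letter COG categories covered by the synthetic reference
COG_CATEGORIES = {
    "C": "Energy production and conversion",
    "E": "Amino acid transport and metabolism",
    "G": "Carbohydrate transport and metabolism",
    "J": "Translation and ribosome biogenesis",
    "K": "Transcription",
    "L": "Replication, recombination and repair",
    "M": "Cell wall/membrane/envelope biogenesis",
    "N": "Cell motility",
    "T": "Signal transduction mechanisms",
    "U": "Intracellular trafficking and secretion",
    "V": "Defense mechanisms",
    "X": "Mobilome: prophages, transposons",
}

#: cluster names; category X mixes transposase and non-transposase clusters
_COG_CLUSTER_NAMES = {
    "X": (
        "IS5 family transposase",
        "Tn3 family transposase",
        "prophage integrase",
    ),
}


def _random_protein(rng: np.random.Generator, length: int) -> str:
    aas = rng.integers(0, 20, size=length - 1)
    return "M" + "".join(_AA20[i] for i in aas)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@functools.cache
def hallmark_reference() -> list[SeqRecord]:
    """Synthetic viral hallmark proteins (major capsid, large terminase,
    portal); stand-ins generated from a fixed seed."""
    rng = np.random.default_rng(_REF_SEED)
    return [
        SeqRecord(name, _random_protein(rng, ln), f"hallmark={name.rsplit('_', 1)[0]}")
        for name, ln in HALLMARK_SPECS
    ]


@functools.cache
def gta_reference() -> list[SeqRecord]:
    """Synthetic RcGTA-like protein set with ``gene=`` and ``core=`` tags."""
    rng = np.random.default_rng(_REF_SEED + 1)
    return [
        SeqRecord(f"rcgta_{name}", _random_protein(rng, ln), f"gene={name} core={int(core)}")
        for name, core, ln in GTA_GENE_SPECS
    ]


@functools.cache
def cog_reference() -> list[SeqRecord]:
    """Synthetic COG-style protein clusters with ``cluster=``, ``cat=`` and
    ``name=`` tags (three clusters per category)."""
    rng = np.random.default_rng(_REF_SEED + 2)
    records = []
    for cat in COG_CATEGORIES:
        names = _COG_CLUSTER_NAMES.get(
            cat, tuple(f"{COG_CATEGORIES[cat].split(' ')[0].lower()} protein {j}" for j in (1, 2, 3))
        )
        for j, name in enumerate(names, start=1):
            cid = f"COG{cat}{j:03d}"
            ln = int(rng.integers(150, 260))
            records.append(
                SeqRecord(cid, _random_protein(rng, ln), f"cluster={cid} cat={cat} name={name}")
            )
    return records


@functools.cache
def ssu_reference() -> SeqRecord:
    """Synthetic SSU rRNA reference gene (~1.5 kb)."""
    rng = np.random.default_rng(_REF_SEED + 3)
    return SeqRecord("ssu_ref", _random_dna(rng, 1542), "synthetic 16S rRNA reference")


def parse_tags(description: str) -> dict[str, str]:
    """Parse ``key=value`` tags from a reference record description
    (values may contain spaces until the next ``key=`` token)."""
    tags: dict[str, str] = {}
    key = None
    for tok in description.split():
        if "=" in tok and tok.split("=", 1)[0].isalpha():
            key, val = tok.split("=", 1)
            tags[key] = val
        elif key is not None:
            tags[key] += " " + tok
    return tags


# ---------------------------------------------------------------------------
# back-translation
# ---------------------------------------------------------------------------

_SYNONYMS: dict[str, list[str]] = {}
for _codon, _aa in _CODON_MAP.items():
    if _aa != "*":
        _SYNONYMS.setdefault(_aa, []).append(_codon)
for _aa in _SYNONYMS:
    _SYNONYMS[_aa].sort()
_STOPS = sorted(["TAA", "TAG", "TGA"])


def back_translate(protein: str, rng: np.random.Generator, stop: bool = True) -> str:
    """Back-translate with uniformly random synonymous codons (seeded)."""
    parts = []
    for aa in protein:
        codons = _SYNONYMS[aa]
        parts.append(codons[rng.integers(0, len(codons))])
    if stop:
        parts.append(_STOPS[rng.integers(0, 3)])
    return "".join(parts)


# ---------------------------------------------------------------------------
# community construction
# ---------------------------------------------------------------------------


@dataclass
class Feature:
    """A planted, coordinate-anchored genome feature (0-based half-open)."""

    kind: str
    start: int
    end: int
    strand: str = "+"
    attrs: dict[str, str] = field(default_factory=dict)


@dataclass
class GenomeRecord:
    """A genome/MAG/virus with planted features and truth mechanism."""

    id: str
    seq: str
    role: str  # host | virus
    truth_mechanism: str  # EV_producer | GTA_producer | transducer | none
    features: list[Feature] = field(default_factory=list)
    abundance_cell: float = 0.0
    abundance_pedna: float = 1.0

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)

    def features_of(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]


def _place_elements(
    rng: np.random.Generator,
    genome_len: int,
    elements: list[tuple[str, str, dict[str, str]]],
) -> tuple[str, list[Feature]]:
    """Place sequence elements at uniformly random non-overlapping positions
    (order preserved) in a random-DNA backbone of *genome_len*."""
    total = sum(len(s) for _, s, _ in elements)
    free = genome_len - total
    if free < 0:
        raise ValueError(
            f"planted elements ({total} bp) do not fit in genome of {genome_len} bp"
        )
    cuts = np.sort(rng.integers(0, free + 1, size=len(elements)))
    parts: list[str] = []
    features: list[Feature] = []
    pos = 0
    prev_cut = 0
    for (kind, seq, attrs), cut in zip(elements, cuts):
        gap = int(cut - prev_cut)
        prev_cut = cut
        parts.append(_random_dna(rng, gap))
        pos += gap
        if kind == "__block__":
            # a pre-assembled multi-gene block carrying relative sub-features
            for sf in attrs["subfeatures"]:
                features.append(
                    Feature(sf.kind, pos + sf.start, pos + sf.end, sf.strand, dict(sf.attrs))
                )
        else:
            features.append(Feature(kind, pos, pos + len(seq), "+", dict(attrs)))
        parts.append(seq)
        pos += len(seq)
    parts.append(_random_dna(rng, genome_len - pos))
    return "".join(parts), features


def _build_virus(rng: np.random.Generator, vid: str, length: int) -> GenomeRecord:
    """A virus genome with 2-5 hallmark genes spread along its length,
    the outermost ones near the termini (phage structural modules reach
    the genome ends, which lets homology-based provirus detection recover
    the full integrated boundaries)."""
    hall = hallmark_reference()
    lead = int(rng.integers(200, 2001))
    tail = int(rng.integers(200, 2001))
    # enough genes that consecutive gaps stay within the hallmark linkage
    # distance used for provirus detection (the stand-in's recall relies on
    # the hallmark chain covering the genome)
    n_hall = 4
    while n_hall < min(6, len(hall)):
        approx_inner = length - lead - tail - n_hall * 1250
        if approx_inner / (n_hall - 1) <= 12_000:
            break
        n_hall += 1
    chosen = sorted(int(c) for c in rng.choice(len(hall), size=n_hall, replace=False))
    genes = [(hall[i].id, back_translate(hall[i].seq, rng)) for i in chosen]
    total = sum(len(s) for _, s in genes)
    inner_free = length - total - lead - tail
    if inner_free < 0:
        raise ValueError(f"virus length {length} too short for hallmark genes")
    # near-even gaps with +-10% jitter keep every gap under the linkage cap
    base = inner_free / (n_hall - 1)
    gaps = [int(base * (1.0 + 0.2 * (rng.random() - 0.5))) for _ in range(n_hall - 2)]
    gaps.append(inner_free - sum(gaps))
    parts = [_random_dna(rng, lead)]
    feats: list[Feature] = []
    pos = lead
    for i, (name, seq) in enumerate(genes):
        feats.append(Feature("hallmark_gene", pos, pos + len(seq), "+", {"gene": name}))
        parts.append(seq)
        pos += len(seq)
        gap = int(gaps[i]) if i < len(gaps) else tail
        parts.append(_random_dna(rng, gap))
        pos += gap
    return GenomeRecord(vid, "".join(parts), "virus", "none", feats)


def _gta_elements(rng: np.random.Generator, cluster_id: str):
    """Per-gene (kind, dna, attrs) tuples for the full RcGTA-like set."""
    out = []
    for ref in gta_reference():
        tags = parse_tags(ref.description)
        out.append(
            (
                "gta_gene",
                back_translate(ref.seq, rng),
                {
                    "gta_gene_name": tags["gene"],
                    "core": tags["core"],
                    "cluster_id": cluster_id,
                },
            )
        )
    return out


def _assemble_block(
    rng: np.random.Generator, genes: list[tuple[str, str, dict[str, str]]]
) -> tuple[str, str, dict]:
    """Concatenate genes with 20-60 bp spacers into one placeable block."""
    parts: list[str] = []
    subfeatures: list[Feature] = []
    pos = 0
    for kind, seq, attrs in genes:
        gap = int(rng.integers(20, 61))
        parts.append(_random_dna(rng, gap))
        pos += gap
        subfeatures.append(Feature(kind, pos, pos + len(seq), "+", dict(attrs)))
        parts.append(seq)
        pos += len(seq)
    return "__block__", "".join(parts), {"subfeatures": subfeatures}


def _host_elements(
    rng: np.random.Generator,
    cog_genes: int,
    transposases: int,
) -> list[tuple[str, str, dict[str, str]]]:
    elements: list[tuple[str, str, dict[str, str]]] = []
    # one SSU rRNA gene, lightly diverged from the reference
    ssu = list(ssu_reference().seq)
    nmut = int(rng.binomial(len(ssu), 0.02))
    for p in rng.choice(len(ssu), size=nmut, replace=False):
        cur = ssu[p]
        alt = "ACGT".replace(cur, "")
        ssu[p] = alt[rng.integers(0, 3)]
    elements.append(("ssu_rrna", "".join(ssu), {}))
    # COG genes covering all configured categories
    cogs = cog_reference()
    by_cat: dict[str, list[SeqRecord]] = {}
    for rec in cogs:
        by_cat.setdefault(parse_tags(rec.description)["cat"], []).append(rec)
    cats = sorted(by_cat)
    for j in range(cog_genes):
        cat = cats[j % len(cats)] if j < len(cats) else cats[rng.integers(0, len(cats))]
        pool = by_cat[cat]
        ref = pool[rng.integers(0, len(pool))]
        tags = parse_tags(ref.description)
        elements.append(
            (
                "cog_gene",
                back_translate(ref.seq, rng),
                {"cog_category": cat, "cluster": ref.id, "name": tags["name"]},
            )
        )
    # transposase genes (Mobilome clusters whose name contains "transposase")
    tn_refs = [
        r
        for r in cogs
        if "transposase" in parse_tags(r.description)["name"].lower()
    ]
    for j in range(transposases):
        ref = tn_refs[rng.integers(0, len(tn_refs))]
        tags = parse_tags(ref.description)
        elements.append(
            (
                "transposase",
                back_translate(ref.seq, rng),
                {"cog_category": "X", "cluster": ref.id, "name": tags["name"]},
            )
        )
    rng.shuffle(elements)
    return elements


def _integrate_provirus(
    rng: np.random.Generator, host: GenomeRecord, virus: GenomeRecord
) -> None:
    """Insert *virus* into *host* at a uniformly random point outside any
    planted feature; coordinates of downstream features shift."""
    blocked = sorted((f.start, f.end) for f in host.features)
    gaps = []
    prev = 0
    for a, b in blocked:
        if a > prev:
            gaps.append((prev, a))
        prev = max(prev, b)
    if prev < len(host.seq):
        gaps.append((prev, len(host.seq)))
    lens = np.array([b - a for a, b in gaps], dtype=float)
    gi = int(rng.choice(len(gaps), p=lens / lens.sum()))
    p = int(rng.integers(gaps[gi][0], gaps[gi][1] + 1))
    vlen = len(virus.seq)
    host.seq = host.seq[:p] + virus.seq + host.seq[p:]
    for f in host.features:
        if f.start >= p:
            f.start += vlen
            f.end += vlen
    host.features.append(
        Feature("provirus", p, p + vlen, "+", {"virus_id": virus.id})
    )
    for vf in virus.features:
        host.features.append(
            Feature(
                vf.kind,
                vf.start + p,
                vf.end + p,
                vf.strand,
                {**vf.attrs, "provirus": virus.id},
            )
        )
    host.features.sort(key=lambda f: (f.start, f.end, f.kind))


def build_community(
    n_hosts: int,
    n_viruses: int,
    genome_len_range: tuple[int, int] = (120_000, 180_000),
    mechanism_counts: dict[str, int] | None = None,
    seed: int = 0,
    virus_len_range: tuple[int, int] = (35_000, 45_000),
    cog_genes_per_host: int = 12,
    transposases_per_host: int = 2,
    dispersed_gta_hosts: frozenset[int] | set[int] = frozenset(),
    abundance_sigma: float = 0.5,
) -> list[GenomeRecord]:
    """Build a synthetic community of *n_hosts* host genomes and
    *n_viruses* free virus genomes.

    ``mechanism_counts`` maps truth mechanisms (EV_producer, GTA_producer,
    transducer, none) to host counts and must sum to *n_hosts*.  GTA hosts
    receive the full RcGTA-like cluster (14 genes, all core genes);
    transducer hosts get one dedicated virus integrated as a provirus.
    Cell and peDNA abundances are drawn independently (log-normal,
    sigma=*abundance_sigma*).  Fully deterministic under *seed*.
    """
    counts = dict(mechanism_counts) if mechanism_counts else {"none": n_hosts}
    unknown = set(counts) - set(MECHANISMS)
    if unknown:
        raise ValueError(f"unknown mechanisms in mechanism_counts: {sorted(unknown)}")
    if sum(counts.values()) != n_hosts or any(v < 0 for v in counts.values()):
        raise ValueError("mechanism_counts must be non-negative and sum to n_hosts")
    rng = np.random.default_rng(seed)
    mechanisms: list[str] = []
    for mech in MECHANISMS:
        mechanisms.extend([mech] * counts.get(mech, 0))
    genomes: list[GenomeRecord] = []
    n_gta_so_far = 0
    for h in range(n_hosts):
        mech = mechanisms[h]
        length = int(rng.integers(genome_len_range[0], genome_len_range[1] + 1))
        elements = _host_elements(rng, cog_genes_per_host, transposases_per_host)
        if mech == "GTA_producer":
            gta = _gta_elements(rng, cluster_id=f"gta_host_{h:03d}")
            if n_gta_so_far in dispersed_gta_hosts:
                # Tateyamaria-style: three widely separated subclusters
                k1, k2 = len(gta) // 3, 2 * len(gta) // 3
                sub = [gta[:k1], gta[k1:k2], gta[k2:]]
                host_seq, feats = _place_elements(rng, length, elements)
                host = GenomeRecord(f"host_{h:03d}", host_seq, "host", mech, feats)
                _plant_blocks_apart(rng, host, sub, min_gap=25_000)
                n_gta_so_far += 1
                genomes.append(host)
                continue
            insert_at = int(rng.integers(0, len(elements) + 1))
            elements = (
                elements[:insert_at]
                + [_assemble_block(rng, gta)]
                + elements[insert_at:]
            )
            n_gta_so_far += 1
        seq, feats = _place_elements(rng, length, elements)
        host = GenomeRecord(f"host_{h:03d}", seq, "host", mech, feats)
        if mech == "transducer":
            vlen = int(rng.integers(virus_len_range[0], virus_len_range[1] + 1))
            provirus = _build_virus(rng, f"provirus_of_host_{h:03d}", vlen)
            _integrate_provirus(rng, host, provirus)
        genomes.append(host)
    for v in range(n_viruses):
        vlen = int(rng.integers(virus_len_range[0], virus_len_range[1] + 1))
        genomes.append(_build_virus(rng, f"virus_{v:03d}", vlen))
    # independent cell/peDNA abundances
    for g in genomes:
        a_cell = float(rng.lognormal(0.0, abundance_sigma))
        a_pedna = float(rng.lognormal(0.0, abundance_sigma))
        g.abundance_cell = a_cell if g.role == "host" else 0.0
        g.abundance_pedna = a_pedna
    return genomes


def _plant_blocks_apart(
    rng: np.random.Generator,
    host: GenomeRecord,
    blocks: list[list[tuple[str, str, dict[str, str]]]],
    min_gap: int,
) -> None:
    """Overwrite *host* DNA with gene blocks at positions >= min_gap apart
    (used for dispersed GTA subclusters); skips planted features."""
    L = len(host.seq)
    n = len(blocks)
    seq = list(host.seq)
    occupied = [(f.start, f.end) for f in host.features]
    span = L // n
    for bi, block in enumerate(blocks):
        blen = sum(len(s) for _, s, _ in block) + 60 * len(block)
        lo = bi * span + min_gap // 2
        hi = (bi + 1) * span - blen - min_gap // 2
        for _attempt in range(200):
            p = int(rng.integers(lo, max(lo + 1, hi)))
            if all(e <= p or s >= p + blen for s, e in occupied):
                break
        else:  # pragma: no cover - pathological
            raise ValueError("could not place dispersed GTA subcluster")
        pos = p
        for kind, s, attrs in block:
            gap = int(rng.integers(20, 61))
            pos += gap
            seq[pos : pos + len(s)] = s
            host.features.append(Feature(kind, pos, pos + len(s), "+", dict(attrs)))
            pos += len(s)
        occupied.append((p, pos))
    host.seq = "".join(seq)
    host.features.sort(key=lambda f: (f.start, f.end, f.kind))


# ---------------------------------------------------------------------------
# carrier model and read sampling
# ---------------------------------------------------------------------------


@dataclass
class CarrierMix:
    """Carrier weights plus per-carrier fragment-length parameters.

    Weights must be non-negative and sum to 1; ``free_dna`` and ``cell``
    stay at 0 unless contamination is explicitly requested (the in-silico
    analogue of DNase treatment plus 0.22 um filtration).
    """

    weights: dict[str, float]
    td_fragment_bp: int = 40_000  # generalized transduction: ~viral genome
    sp_fragment_bp: int = 10_000  # specialized transduction: provirus-adjacent
    gta_fragment: tuple[float, float] = (4500.0, 1000.0)  # normal(mean, sd)
    ev_fragment: tuple[float, float] = (math.log(2000.0), 0.6)  # lognormal
    insert: tuple[float, float] = (400.0, 80.0)  # sequencing insert

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(CARRIERS)
        if unknown:
            raise ValueError(f"unknown carriers: {sorted(unknown)}")
        vals = [self.weights.get(c, 0.0) for c in CARRIERS]
        if any(v < 0 for v in vals):
            raise ValueError("carrier weights must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError("carrier weights must sum to 1")

    def weight(self, carrier: str) -> float:
        return self.weights.get(carrier, 0.0)


def default_pedna_mix(
    community: list[GenomeRecord],
    induction: float = 10.0,
    ev: float = 0.40,
    gta: float = 0.25,
    transduction: float = 0.10,
) -> CarrierMix:
    """A carrier mix in which each transducer's provirus shows a peDNA
    depth ratio of *induction* over its flanking host DNA (virion weight
    derived from the transduction weight and the provirus pool)."""
    z_v = 0.0
    z_t = 0.0
    for g in community:
        if g.role == "host" and g.truth_mechanism == "transducer":
            prov = g.features_of("provirus")
            plen = sum(f.end - f.start for f in prov)
            z_v += g.abundance_pedna * induction * plen / len(g.seq)
            z_t += g.abundance_pedna
        elif g.role == "virus":
            z_v += g.abundance_pedna
    if z_t == 0:
        raise ValueError("default_pedna_mix requires at least one transducer")
    virion = transduction * z_v / z_t
    # drop carriers with no eligible producer
    mechs = {g.truth_mechanism for g in community if g.role == "host"}
    ev = ev if "EV_producer" in mechs else 0.0
    gta = gta if "GTA_producer" in mechs else 0.0
    total = ev + gta + transduction + virion
    weights = {
        "transduction_general": transduction / total,
        "virion": virion / total,
    }
    if ev:
        weights["ev"] = ev / total
    if gta:
        weights["gta_particle"] = gta / total
    return CarrierMix(weights=weights)


def _virion_pool(
    community: list[GenomeRecord], induction: float
) -> tuple[list[tuple[GenomeRecord, int, int]], np.ndarray]:
    """Virion sources: free virus genomes plus transducer proviruses at
    copy number elevated by the induction factor."""
    entries: list[tuple[GenomeRecord, int, int]] = []
    weights: list[float] = []
    for g in community:
        if g.role == "virus":
            entries.append((g, 0, len(g.seq)))
            weights.append(g.abundance_pedna)
        elif g.truth_mechanism == "transducer":
            for f in g.features_of("provirus"):
                entries.append((g, f.start, f.end))
                weights.append(
                    g.abundance_pedna * induction * (f.end - f.start) / len(g.seq)
                )
    return entries, np.asarray(weights, dtype=float)


def _host_pool(community, mechanism):
    entries = [
        (g, 0, len(g.seq))
        for g in community
        if g.role == "host" and g.truth_mechanism == mechanism
    ]
    w = np.array([g.abundance_pedna for g, _, _ in entries], dtype=float)
    return entries, w


def _apply_errors(
    codes: np.ndarray, rng: np.random.Generator, err_rate: float
) -> np.ndarray:
    if err_rate <= 0:
        return codes
    mask = rng.random(len(codes)) < err_rate
    n = int(mask.sum())
    if n:
        shift = rng.integers(1, 4, size=n).astype(np.uint8)
        codes = codes.copy()
        codes[mask] = (codes[mask] + shift) % 4
    return codes


_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def sample_pedna_reads(
    community: list[GenomeRecord],
    mix: CarrierMix,
    n_pairs: int,
    read_len: int = 150,
    err_rate: float = 0.005,
    seed: int = 0,
    induction: float = 10.0,
    read_prefix: str = "pedna",
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Draw *n_pairs* peDNA read pairs under the carrier mix.

    Per pair a carrier is drawn from the mix weights, a source genome from
    the carrier-eligible pool (peDNA abundances), a carrier fragment by the
    carrier's length rule, and a sequencing insert uniformly within the
    fragment; mates are the 2x*read_len* ends of the insert with
    independent substitution errors.  Returns the reads and a per-pair
    truth table (read_id, carrier, source_genome, insert interval).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if not 0.0 <= err_rate <= 0.05:
        raise ValueError("err_rate must lie in [0, 0.05]")
    rng = np.random.default_rng(seed)
    pools: dict[str, tuple[list, np.ndarray]] = {}
    for carrier in CARRIERS:
        if mix.weight(carrier) <= 0:
            continue
        if carrier == "virion":
            pools[carrier] = _virion_pool(community, induction)
        elif carrier == "transduction_general":
            pools[carrier] = _host_pool(community, "transducer")
        elif carrier == "transduction_specialized":
            entries, w = _host_pool(community, "transducer")
            entries = [e for e in entries if e[0].features_of("provirus")]
            w = np.array([g.abundance_pedna for g, _, _ in entries], dtype=float)
            pools[carrier] = (entries, w)
        elif carrier == "gta_particle":
            pools[carrier] = _host_pool(community, "GTA_producer")
        elif carrier == "ev":
            pools[carrier] = _host_pool(community, "EV_producer")
        else:  # free_dna, cell: contamination from any cellular genome
            entries = [(g, 0, len(g.seq)) for g in community if g.role == "host"]
            w = np.array([g.abundance_cell for g, _, _ in entries], dtype=float)
            pools[carrier] = (entries, w)
        entries, w = pools[carrier]
        if not entries or w.sum() <= 0:
            raise ValueError(f"carrier {carrier!r} has weight > 0 but no eligible genome")
    active = [c for c in CARRIERS if mix.weight(c) > 0]
    p = np.array([mix.weight(c) for c in active])
    carrier_draw = rng.choice(len(active), size=n_pairs, p=p / p.sum())
    reads: list[ReadPair] = []
    truth_rows = []
    genome_codes: dict[str, np.ndarray] = {}
    for i in range(n_pairs):
        carrier = active[int(carrier_draw[i])]
        entries, w = pools[carrier]
        si = int(rng.choice(len(entries), p=w / w.sum())) if len(entries) > 1 else 0
        g, lo, hi = entries[si]
        L = len(g.seq)
        # carrier fragment
        if carrier == "virion":
            fs, fe = lo, hi
        elif carrier == "transduction_general":
            flen = min(mix.td_fragment_bp, L)
            fs = int(rng.integers(0, L - flen + 1))
            fe = fs + flen
        elif carrier == "transduction_specialized":
            prov = g.features_of("provirus")
            f = prov[int(rng.integers(0, len(prov)))]
            if rng.random() < 0.5 and f.start > read_len:
                fs, fe = max(0, f.start - mix.sp_fragment_bp), f.start
            else:
                fs, fe = f.end, min(L, f.end + mix.sp_fragment_bp)
        elif carrier == "gta_particle":
            flen = int(np.clip(rng.normal(*mix.gta_fragment), read_len, L))
            fs = int(rng.integers(0, L - flen + 1))
            fe = fs + flen
        elif carrier == "ev":
            flen = int(np.clip(rng.lognormal(*mix.ev_fragment), read_len, L))
            fs = int(rng.integers(0, L - flen + 1))
            fe = fs + flen
        else:  # free_dna / cell
            fs, fe = 0, L
        # sequencing insert within the fragment
        flen = fe - fs
        ilen = int(np.clip(rng.normal(*mix.insert), read_len, flen))
        istart = fs + int(rng.integers(0, flen - ilen + 1))
        iend = istart + ilen
        codes = genome_codes.get(g.id)
        if codes is None:
            codes = encode_dna(g.seq)
            genome_codes[g.id] = codes
        m1 = _apply_errors(codes[istart : istart + read_len], rng, err_rate)
        m2raw = codes[iend - read_len : iend][::-1]
        m2 = _apply_errors((3 - m2raw) % 4, rng, err_rate)  # reverse complement
        rid = f"{read_prefix}_{i:07d}"
        reads.append(ReadPair(rid, _decode(m1), _decode(m2)))
        truth_rows.append((rid, carrier, g.id, istart, iend))
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "carrier", "source_genome", "insert_start", "insert_end"],
    )
    return reads, truth


def sample_metagenome_reads(
    community: list[GenomeRecord],
    n_pairs: int,
    read_len: int = 150,
    err_rate: float = 0.005,
    seed: int = 0,
    insert: tuple[float, float] = (400.0, 80.0),
    read_prefix: str = "meta",
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Draw metagenome (cellular) read pairs: uniform inserts from host
    genomes weighted by cell abundance, independent of peDNA output."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if not 0.0 <= err_rate <= 0.05:
        raise ValueError("err_rate must lie in [0, 0.05]")
    hosts = [g for g in community if g.role == "host"]
    if not hosts:
        raise ValueError("metagenome sampling requires at least one host genome")
    w = np.array([g.abundance_cell for g in hosts], dtype=float)
    if w.sum() <= 0:
        raise ValueError("all host cell abundances are zero")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(hosts), size=n_pairs, p=w / w.sum())
    codes_cache = {g.id: encode_dna(g.seq) for g in hosts}
    reads: list[ReadPair] = []
    rows = []
    for i in range(n_pairs):
        g = hosts[int(picks[i])]
        L = len(g.seq)
        ilen = int(np.clip(rng.normal(*insert), read_len, L))
        istart = int(rng.integers(0, L - ilen + 1))
        iend = istart + ilen
        codes = codes_cache[g.id]
        m1 = _apply_errors(codes[istart : istart + read_len], rng, err_rate)
        m2 = _apply_errors((3 - codes[iend - read_len : iend][::-1]) % 4, rng, err_rate)
        rid = f"{read_prefix}_{i:07d}"
        reads.append(ReadPair(rid, _decode(m1), _decode(m2)))
        rows.append((rid, "cell", g.id, istart, iend))
    truth = pd.DataFrame(
        rows, columns=["read_id", "carrier", "source_genome", "insert_start", "insert_end"]
    )
    return reads, truth


# ---------------------------------------------------------------------------
# contigs, truth tables, file output
# ---------------------------------------------------------------------------


def as_contigs(
    community: list[GenomeRecord], chunk_len: int | None = None
) -> list[SeqRecord]:
    """Emit genomes as contigs (``<genome>|c<j>``); when *chunk_len* is
    given genomes are split into consecutive chunks (assembly stand-in)."""
    contigs = []
    for g in community:
        if chunk_len is None:
            contigs.append(SeqRecord(f"{g.id}|c0", g.seq, g.id))
        else:
            for j, a in enumerate(range(0, len(g.seq), chunk_len)):
                contigs.append(SeqRecord(f"{g.id}|c{j}", g.seq[a : a + chunk_len], g.id))
    return contigs


def contig_source(contig_id: str) -> str:
    """Genome id a simulator contig derives from."""
    return contig_id.rsplit("|", 1)[0]


def community_truth(community: list[GenomeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (g.id, g.role, g.truth_mechanism, len(g.seq), g.abundance_cell, g.abundance_pedna)
            for g in community
        ],
        columns=["genome_id", "role", "truth_mechanism", "length", "abundance_cell", "abundance_pedna"],
    )


def features_table(community: list[GenomeRecord]) -> pd.DataFrame:
    rows = []
    for g in community:
        for f in g.features:
            attrs = ";".join(f"{k}={v}" for k, v in sorted(f.attrs.items()))
            rows.append((g.id, f.start, f.end, f.strand, f.kind, attrs))
    return pd.DataFrame(
        rows, columns=["genome", "start", "end", "strand", "kind", "attrs"]
    )


def write_read_pairs(prefix: str | os.PathLike, reads: list[ReadPair]) -> None:
    """Write a read set as ``<prefix>_R1.fastq`` / ``<prefix>_R2.fastq``."""
    write_fastq(f"{prefix}_R1.fastq", [SeqRecord(r.id, r.seq1) for r in reads])
    write_fastq(f"{prefix}_R2.fastq", [SeqRecord(r.id, r.seq2) for r in reads])


def read_read_pairs(prefix: str | os.PathLike) -> list[ReadPair]:
    r1 = read_fastq(f"{prefix}_R1.fastq")
    r2 = read_fastq(f"{prefix}_R2.fastq")
    if len(r1) != len(r2) or any(a.id != b.id for a, b in zip(r1, r2)):
        raise ValueError(f"{prefix}: mate files disagree on read ids")
    return [ReadPair(a.id, a.seq, b.seq) for a, b in zip(r1, r2)]


def write_run_config(path: str | os.PathLike, params: dict) -> None:
    """Plain key-value run-configuration capture."""
    with open(path, "w") as fh:
        for k in sorted(params):
            fh.write(f"{k}\t{params[k]}\n")


def write_community(outdir: str | os.PathLike, community: list[GenomeRecord]) -> None:
    """Write genomes FASTA, features TSV and genome truth TSV."""
    os.makedirs(outdir, exist_ok=True)
    write_fasta(
        os.path.join(outdir, "genomes.fasta"),
        [SeqRecord(g.id, g.seq, f"role={g.role} mechanism={g.truth_mechanism}") for g in community],
    )
    features_table(community).to_csv(
        os.path.join(outdir, "features.tsv"), sep="\t", index=False
    )
    community_truth(community).to_csv(
        os.path.join(outdir, "genome_truth.tsv"), sep="\t", index=False
    )
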