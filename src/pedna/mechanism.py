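"""Attribution of nvpeDNA to source MAGs and their transport mechanism.

peDNA read pairs are recruited to length-filtered MAGs; for each
top-recruiting MAG the pipeline builds a windowed coverage profile,
detects candidate provirus regions (hallmark-homology clusters, a
VirSorter2 stand-in), scores provirus activity from the region/background
depth ratio, searches for an RcGTA-like gene cluster, and combines the
evidence into a mechanism label: EV_producer, GTA_producer, transducer or
unclear.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    Alignment,
    Orf,
    SeqRecord,
    count_pairs_per_target,
    find_orfs,
    kmer_map_reads,
    search_hits,
)
from .simulate import GTA_CORE_GENES, GenomeRecord, parse_tags

PROVIRUS_STATUSES = ("active", "inactive", "absent", "none_found")
MECHANISM_LABELS = ("EV_producer", "GTA_producer", "transducer", "unclear")


@dataclass
class CoverageProfile:
    """Windowed mean depth over a MAG plus a background estimate
    (10%-trimmed mean over windows outside candidate proviral regions)."""

    mag_id: str
    window_bp: int
    depth: np.ndarray
    background: float
    base_depth: np.ndarray = field(repr=False, default=None)


@dataclass
class ProvirusCall:
    mag_id: str
    region: tuple[int, int] | None
    status: str  # active | inactive | absent | none_found
    depth_ratio: float | None = None
    flag: str = ""


@dataclass
class GtaCall:
    mag_id: str
    hits: list = field(default_factory=list)
    n_gta_genes: int = 0
    core_present: frozenset = frozenset()
    functional: bool = False
    dispersed: bool = False


@dataclass
class MechanismCall:
    mag_id: str
    label: str
    provirus: ProvirusCall
    gta: GtaCall
    recruitment_pairs: int = 0


def filter_mags(
    mags: Sequence, min_len: int = 100_000
) -> list:
    """Keep MAGs of length >= *min_len* bp (inclusive), order preserved."""
    return [m for m in mags if len(m.seq) >= min_len]


def recruit_and_rank(
    pedna_reads: Sequence,
    mags: Sequence[SeqRecord],
    k: int = 20,
    alignments: Sequence[Alignment] | None = None,
    kmer: int = 21,
    min_identity: float = 0.9,
) -> list[tuple[str, int]]:
    """Top-*k* MAGs by recruited read-pair count (ties broken toward the
    lexicographically smaller id); MAGs recruiting zero pairs rank last."""
    if not mags:
        raise ValueError("recruit_and_rank requires a non-empty MAG set")
    if alignments is None:
        alignments = kmer_map_reads(pedna_reads, mags, k=kmer, min_identity=min_identity)
    counts = count_pairs_per_target(alignments)
    ranked = sorted(
        ((m.id, counts.get(m.id, 0)) for m in mags), key=lambda t: (-t[1], t[0])
    )
    return ranked[:k]


def coverage_profile(
    mag,
    alignments: Sequence[Alignment],
    window_bp: int = 1000,
    candidate_regions: Sequence[tuple[int, int]] = (),
) -> CoverageProfile:
    """Per-window mean depth from mate alignment intervals; the background
    is the 10%-trimmed mean over windows not overlapping any candidate
    region."""
    if window_bp < 100:
        raise ValueError("window_bp must be >= 100")
    L = len(mag.seq)
    diff = np.zeros(L + 1, dtype=np.int64)
    for a in alignments:
        if a.target_id != mag.id:
            continue
        s = max(0, a.target_pos)
        e = min(L, a.target_pos + a.length)
        if e > s:
            diff[s] += 1
            diff[e] -= 1
    base = np.cumsum(diff[:-1]).astype(float)
    n_win = max(1, -(-L // window_bp))
    depth = np.empty(n_win)
    for w in range(n_win):
        depth[w] = base[w * window_bp : (w + 1) * window_bp].mean()
    is_candidate = np.zeros(n_win, dtype=bool)
    for s, e in candidate_regions:
        is_candidate[s // window_bp : -(-e // window_bp)] = True
    bg_windows = depth[~is_candidate]
    if len(bg_windows) == 0:
        background = 0.0
    else:
        background = float(stats.trim_mean(bg_windows, 0.1))
    return CoverageProfile(mag.id, window_bp, depth, background, base)


def detect_provirus(
    mag,
    hallmark_db: Sequence[SeqRecord],
    orfs: Sequence[Orf] | None = None,
    link_bp: int = 15_000,
    pad_bp: int = 5_000,
    min_hits: int = 2,
    evalue_max: float = 1e-5,
    pident_min: float = 50.0,
) -> list[tuple[int, int]]:
    """Candidate integrated-provirus regions: maximal intervals where
    >= *min_hits* hallmark ORF hits fall within *link_bp* of each other,
    padded by *pad_bp* per side and clipped to the MAG."""
    if not hallmark_db:
        raise ValueError("hallmark_db must be non-empty")
    if orfs is None:
        orfs = find_orfs(SeqRecord(mag.id, mag.seq), min_codons=50)
    queries = [(str(i), o.protein) for i, o in enumerate(orfs)]
    hits = search_hits(queries, hallmark_db, evalue_max=evalue_max, pident_min=pident_min)
    hit_orfs = sorted({int(h.query_id) for h in hits})
    loci = sorted((orfs[i].start, orfs[i].end) for i in hit_orfs)
    regions: list[tuple[int, int]] = []
    cluster: list[tuple[int, int]] = []
    for ivl in loci:
        if cluster and ivl[0] - cluster[-1][1] > link_bp:
            if len(cluster) >= min_hits:
                regions.append((cluster[0][0], cluster[-1][1]))
            cluster = []
        cluster.append(ivl)
    if len(cluster) >= min_hits:
        regions.append((cluster[0][0], cluster[-1][1]))
    L = len(mag.seq)
    return [(max(0, s - pad_bp), min(L, e + pad_bp)) for s, e in regions]


def provirus_status(
    profile: CoverageProfile,
    region: tuple[int, int] | None,
    alpha: float = 3.0,
    epsilon: float = 0.05,
    min_bg: float = 1.0,
) -> ProvirusCall:
    """Score one candidate region from full-resolution depth.

    active: region mean depth / background >= *alpha* (and depth > 0);
    absent: region mean depth <= *epsilon* x background with background
    >= *min_bg*; inactive otherwise.  With neither signal in region nor
    background the call is inactive with flag ``no_signal``.
    """
    if region is None:
        return ProvirusCall(profile.mag_id, None, "none_found")
    s, e = region
    if not (0 <= s < e <= len(profile.base_depth)):
        raise ValueError(f"region {region} outside profile extent")
    depth = float(profile.base_depth[s:e].mean())
    bg = profile.background
    if depth == 0.0 and bg == 0.0:
        return ProvirusCall(profile.mag_id, region, "inactive", None, "no_signal")
    ratio = depth / bg if bg > 0 else float("inf")
    if depth > 0 and ratio >= alpha:
        return ProvirusCall(profile.mag_id, region, "active", ratio)
    if depth <= epsilon * bg and bg >= min_bg:
        return ProvirusCall(profile.mag_id, region, "absent", ratio)
    return ProvirusCall(profile.mag_id, region, "inactive", ratio)


def detect_gta(
    mag,
    gta_db: Sequence[SeqRecord],
    evalue_max: float = 1e-5,
    pident_min: float = 50.0,
    n_min: int = 11,
    orfs: Sequence[Orf] | None = None,
    locus_gap_bp: int = 20_000,
) -> GtaCall:
    """Search the MAG's ORFs for RcGTA-like homologs.

    The cluster is called functional when more than *n_min* - 1 distinct
    reference genes are hit (> 10 by default) and every core gene is
    present; it is flagged dispersed when the hit genes span more than two
    loci separated by >= *locus_gap_bp*.
    """
    gene_of = {}
    core_of = {}
    for rec in gta_db:
        tags = parse_tags(rec.description)
        gene_of[rec.id] = tags.get("gene", rec.id)
        core_of[rec.id] = tags.get("core", "0") == "1"
    core_genes = {gene_of[r] for r in gene_of if core_of[r]}
    if orfs is None:
        orfs = find_orfs(SeqRecord(mag.id, mag.seq), min_codons=50)
    queries = [(str(i), o.protein) for i, o in enumerate(orfs)]
    hits = search_hits(queries, gta_db, evalue_max=evalue_max, pident_min=pident_min)
    # best hit per reference gene (by score)
    best: dict[str, tuple[float, int]] = {}
    for h in hits:
        gene = gene_of[h.subject_id]
        prev = best.get(gene)
        if prev is None or h.score > prev[0]:
            best[gene] = (h.score, int(h.query_id))
    n_genes = len(best)
    core_present = frozenset(g for g in best if g in core_genes)
    functional = n_genes >= n_min and core_present == frozenset(core_genes)
    positions = sorted(orfs[i].start for _, i in best.values())
    n_loci = 0
    prev_pos = None
    for p in positions:
        if prev_pos is None or p - prev_pos >= locus_gap_bp:
            n_loci += 1
        prev_pos = p
    dispersed = n_loci > 2
    return GtaCall(mag.id, hits, n_genes, core_present, functional, dispersed)


def decide_mechanism(
    provirus: ProvirusCall,
    gta: GtaCall,
    recruitment_pairs: int = 0,
    no_signal_recruitment_threshold: int = 0,
) -> MechanismCall:
    """Deterministic decision rule combining the provirus and GTA calls.

    active provirus and no functional GTA -> transducer; functional GTA
    without an active provirus -> GTA_producer; both -> unclear; a
    no-signal coverage flag on a MAG that nonetheless recruits ->
    unclear; otherwise -> EV_producer.
    """
    if provirus.mag_id != gta.mag_id:
        raise ValueError("provirus and GTA calls refer to different MAGs")
    active = provirus.status == "active"
    if active and gta.functional:
        label = "unclear"
    elif active:
        label = "transducer"
    elif gta.functional:
        label = "GTA_producer"
    elif (
        provirus.flag == "no_signal"
        and recruitment_pairs > no_signal_recruitment_threshold
    ):
        label = "unclear"
    else:
        label = "EV_producer"
    return MechanismCall(provirus.mag_id, label, provirus, gta, recruitment_pairs)


_STATUS_RANK = {"active": 0, "absent": 1, "inactive": 2}


def best_provirus_call(
    profile: CoverageProfile,
    regions: Sequence[tuple[int, int]],
    alpha: float = 3.0,
    epsilon: float = 0.05,
    min_bg: float = 1.0,
) -> ProvirusCall:
    """MAG-level provirus call over all candidate regions: an active region
    dominates, then an absent one, then inactive."""
    if not regions:
        return ProvirusCall(profile.mag_id, None, "none_found")
    calls = [provirus_status(profile, r, alpha, epsilon, min_bg) for r in regions]
    calls.sort(
        key=lambda c: (_STATUS_RANK[c.status], -(c.depth_ratio or 0.0))
    )
    return calls[0]


def call_mechanisms(
    mags: Sequence,
    pedna_reads: Sequence,
    hallmark_db: Sequence[SeqRecord],
    gta_db: Sequence[SeqRecord],
    top_k: int = 20,
    min_mag_len: int = 100_000,
    window_bp: int = 1000,
    alpha: float = 3.0,
    epsilon: float = 0.05,
    min_bg: float = 1.0,
    kmer: int = 21,
    min_identity: float = 0.9,
) -> tuple[list[MechanismCall], list[Alignment]]:
    """Full mechanism stage over the top-*top_k* recruiting MAGs.

    All peDNA pairs (not only the non-viral-classified ones) are mapped to
    the MAGs; returns the per-MAG calls plus the alignments for reuse.
    """
    kept = filter_mags(mags, min_mag_len)
    refs = [SeqRecord(m.id, m.seq) for m in kept]
    alignments = kmer_map_reads(pedna_reads, refs, k=kmer, min_identity=min_identity)
    ranked = recruit_and_rank(pedna_reads, refs, k=top_k, alignments=alignments)
    by_id = {m.id: m for m in kept}
    calls: list[MechanismCall] = []
    for mag_id, n_pairs in ranked:
        mag = by_id[mag_id]
        orfs = find_orfs(SeqRecord(mag.id, mag.seq), min_codons=50)
        regions = detect_provirus(mag, hallmark_db, orfs=orfs)
        profile = coverage_profile(mag, alignments, window_bp, regions)
        prov = best_provirus_call(profile, regions, alpha, epsilon, min_bg)
        gta = detect_gta(mag, gta_db, orfs=orfs)
        calls.append(decide_mechanism(prov, gta, n_pairs))
    return calls, alignments


def abundance_correlation(
    pedna_counts: Mapping[str, float], metagenome_counts: Mapping[str, float]
) -> float | None:
    """Squared Pearson correlation between per-MAG relative abundances in
    the peDNA fraction and the metagenome; None when undefined."""
    keys = sorted(set(pedna_counts) & set(metagenome_counts))
    if len(keys) < 3:
        raise ValueError("abundance_correlation requires >= 3 paired counts")
    x = np.array([pedna_counts[k] for k in keys], dtype=float)
    y = np.array([metagenome_counts[k] for k in keys], dtype=float)
    if x.sum() > 0:
        x = x / x.sum()
    if y.sum() > 0:
        y = y / y.sum()
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def write_mechanism_table(
    path: str | os.PathLike, calls: Sequence[MechanismCall]
) -> None:
    """Machine-readable evidence table (one row per MAG) so the automated
    labels can be audited like the manual curation they replace."""
    rows = []
    for c in calls:
        rows.append(
            (
                c.mag_id,
                c.label,
                c.provirus.status,
                "" if c.provirus.depth_ratio is None else f"{c.provirus.depth_ratio:.3f}",
                c.gta.n_gta_genes,
                ",".join(sorted(c.gta.core_present)),
                int(c.gta.functional),
                int(c.gta.dispersed),
                c.recruitment_pairs,
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "mag_id",
            "label",
            "provirus_status",
            "depth_ratio",
            "n_gta_genes",
            "core_present",
            "gta_functional",
            "gta_dispersed",
            "recruitment_pairs",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_provirus_bed(
    path: str | os.PathLike, regions_by_mag: Mapping[str, Sequence[tuple[int, int]]]
) -> None:
    with open(path, "w") as fh:
        for mag_id in sorted(regions_by_mag):
            for s, e in regions_by_mag[mag_id]:
                fh.write(f"{mag_id}\t{s}\t{e}\tprovirus_candidate\n")


def write_coverage_tsv(
    path: str | os.PathLike, profiles: Sequence[CoverageProfile]
) -> None:
    with open(path, "w") as fh:
        fh.write("mag_id\twindow\tstart\tdepth\n")
        for p in profiles:
            for w, d in enumerate(p.depth):
                fh.write(f"{p.mag_id}\t{w}\t{w * p.window_bp}\t{d:.4f}\n")
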