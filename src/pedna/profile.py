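"""Per-mechanism functional profiling of peDNA reads.

Reads are partitioned by the mechanism label of their best MAG (mapped at
high identity), partial protein fragments are predicted per mate
(FragGeneScan stand-in), fragments are assigned to COG clusters and
categories, genes with unusually high peDNA recruitment are flagged
(mean + 2 SD rule), and per-category frequencies are compared with the
matching microbial metagenome profile as signed fold changes.  The
Mobilome (category X) signal can be decomposed into its transposase
share.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    Alignment,
    SeqRecord,
    kmer_map_reads,
    revcomp,
    search_hits,
    translate,
)
from .simulate import parse_tags

logger = logging.getLogger("pedna")

#: transposable-element annotation regex, applied verbatim
TRANSPOSASE_PATTERN = r"IS\d\+*|Tn\d\+*|attTn\d\+*|transposase|Transposase"
_TRANSPOSASE_RE = re.compile(TRANSPOSASE_PATTERN)


@dataclass
class CogAssignment:
    """A read's best COG hit (at most one per read)."""

    read_id: str
    mechanism_label: str
    cog_cluster_id: str
    cog_category: str
    gene_id: str
    high_coverage: bool = False


# ---------------------------------------------------------------------------
# read partitioning and fragment prediction
# ---------------------------------------------------------------------------


def assign_mechanism_reads(
    pedna_reads: Sequence,
    labeled_mags: Mapping[str, str],
    mags: Sequence[SeqRecord],
    min_identity: float = 0.95,
    k: int = 21,
    alignments: Sequence[Alignment] | None = None,
) -> dict[str, list]:
    """Partition read pairs by the mechanism label of their best MAG.

    Pairs mapping at >= *min_identity* to a labelled MAG inherit its
    label; pairs below the threshold (or on unlabelled MAGs) are dropped.
    Returns label -> read list for the EV/GTA/transducer sets.
    """
    if not labeled_mags:
        raise ValueError("labeled MAG set must be non-empty")
    refs = [m for m in mags if m.id in labeled_mags]
    if alignments is None:
        alignments = kmer_map_reads(pedna_reads, refs, k=k, min_identity=min_identity)
    target_of = {
        a.pair_id: a.target_id for a in alignments if a.mate_consistent
    }
    out: dict[str, list] = {}
    for rp in pedna_reads:
        tid = target_of.get(rp.id)
        if tid is None:
            continue
        out.setdefault(labeled_mags[tid], []).append(rp)
    return out


def read_orf(read_seq: str, min_codons: int = 20) -> str | None:
    """Best stop-free reading-frame peptide of a single mate (both
    strands, >= *min_codons* codons); None when no frame qualifies."""
    if len(read_seq) < 60:
        return None
    best = None
    for s in (read_seq, revcomp(read_seq)):
        for frame in range(3):
            sub = s[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            prot = translate(sub)
            for run in prot.split("*"):
                if len(run) >= min_codons and (best is None or len(run) > len(best)):
                    best = run
    return best


def predict_fragments(reads: Sequence, min_codons: int = 20) -> list[tuple[str, str]]:
    """Partial protein fragments per mate, ids suffixed /1 and /2."""
    frags = []
    for rp in reads:
        for mate, seq in (("1", rp.seq1), ("2", rp.seq2)):
            p = read_orf(seq, min_codons)
            if p is not None:
                frags.append((f"{rp.id}/{mate}", p))
    return frags


# ---------------------------------------------------------------------------
# COG assignment
# ---------------------------------------------------------------------------


def cog_assign(
    fragments: Sequence[tuple[str, str]],
    cog_db: Sequence[SeqRecord],
    evalue_max: float = 1e-5,
    qcov_min: float = 80.0,
    scov_min: float = 10.0,
    mechanism_label: str = "",
) -> list[CogAssignment]:
    """Assign each protein fragment to its best COG cluster (max one hit
    per read; query cover >= *qcov_min*, subject cover >= *scov_min*)."""
    tags_by_id = {rec.id: parse_tags(rec.description) for rec in cog_db}
    hits = search_hits(
        fragments, cog_db, evalue_max=evalue_max, pident_min=0.0
    )
    best: dict[str, tuple[float, str]] = {}
    for h in hits:
        if h.qcov < qcov_min or h.scov < scov_min:
            continue
        prev = best.get(h.query_id)
        if prev is None or h.score > prev[0]:
            best[h.query_id] = (h.score, h.subject_id)
    out = []
    for rid in sorted(best):
        sid = best[rid][1]
        tags = tags_by_id[sid]
        out.append(
            CogAssignment(
                rid,
                mechanism_label,
                tags.get("cluster", sid),
                tags.get("cat", "?"),
                sid,
            )
        )
    return out


# ---------------------------------------------------------------------------
# high-coverage gene flag (mean + 2 SD rule)
# ---------------------------------------------------------------------------


def gene_recruitment(
    genes: Sequence[tuple[str, str, int, int]],
    alignments: Sequence[Alignment],
) -> dict[str, float]:
    """peDNA read pairs per gene per kb from mate alignments.

    *genes* rows are (gene_id, mag_id, start, end); mate alignments count
    1/2 pair each when overlapping the gene interval.
    """
    by_mag: dict[str, list[Alignment]] = {}
    for a in alignments:
        by_mag.setdefault(a.target_id, []).append(a)
    out: dict[str, float] = {}
    for gid, mag_id, s, e in genes:
        n_mates = 0
        for a in by_mag.get(mag_id, ()):
            if a.target_pos < e and a.target_pos + a.length > s:
                n_mates += 1
        out[gid] = (n_mates / 2.0) / ((e - s) / 1000.0)
    return out


def flag_high_coverage(
    assignments: Sequence[CogAssignment],
    per_gene_recruitment: Mapping[str, float],
    read_gene: Mapping[str, str] | None = None,
) -> list[CogAssignment]:
    """Set ``high_coverage`` on reads whose assigned gene recruits above
    mean + 2 SD across all genes of the MAG set.

    With fewer than 3 genes, or zero recruitment variance, nothing is
    flagged.  *read_gene* overrides the gene a read inherits (defaults to
    the assignment's ``gene_id``, i.e. the COG reference hit).
    """
    vals = np.array(list(per_gene_recruitment.values()), dtype=float)
    if len(vals) < 3:
        logger.warning("fewer than 3 genes: no high-coverage flags set")
        high_genes: set[str] = set()
    else:
        sd = float(vals.std())  # population SD
        if sd == 0.0:
            high_genes = set()
        else:
            cutoff = float(vals.mean()) + 2.0 * sd
            # a gene sitting exactly on the cutoff counts as high
            high_genes = {
                g
                for g, v in per_gene_recruitment.items()
                if v >= cutoff or np.isclose(v, cutoff)
            }
    out = []
    for a in assignments:
        gene = read_gene.get(a.read_id, a.gene_id) if read_gene else a.gene_id
        out.append(
            CogAssignment(
                a.read_id,
                a.mechanism_label,
                a.cog_cluster_id,
                a.cog_category,
                a.gene_id,
                gene in high_genes,
            )
        )
    return out


# ---------------------------------------------------------------------------
# category frequencies and fold changes
# ---------------------------------------------------------------------------


def category_frequencies(
    assignments: Sequence[CogAssignment],
) -> pd.DataFrame:
    """Per-category read counts: n_tot, n_hc, freq_hc (= n_hc/n_tot, the
    published definition) and freq_raw (= n_tot/total, plain composition).
    Both are emitted so either reading can be audited."""
    rows: dict[str, list[int]] = {}
    for a in assignments:
        n = rows.setdefault(a.cog_category, [0, 0])
        n[0] += 1
        n[1] += int(a.high_coverage)
    total = sum(v[0] for v in rows.values())
    data = [
        (
            cat,
            n_tot,
            n_hc,
            n_hc / n_tot if n_tot else 0.0,
            n_tot / total if total else 0.0,
        )
        for cat, (n_tot, n_hc) in sorted(rows.items())
    ]
    return pd.DataFrame(data, columns=["category", "n_tot", "n_hc", "freq_hc", "freq_raw"])


def fold_changes(
    freq_label: Mapping[str, float],
    freq_microbial: Mapping[str, float],
) -> dict[str, float]:
    """Signed pairwise fold changes between two frequency profiles.

    fc = f_label/f_microbial when the quotient is >= 1, else the negative
    reciprocal -(f_microbial/f_label), so |fc| >= 1 always and no output
    falls in the open interval (-1, 1).  A zero frequency on one side is
    replaced by half the smallest nonzero frequency of the pair; both zero
    (or a category missing on one side) yields NaN.
    """
    if set(freq_label) != set(freq_microbial):
        raise ValueError("profiles cover different category sets")
    out: dict[str, float] = {}
    for cat in sorted(freq_label):
        fl, fm = float(freq_label[cat]), float(freq_microbial[cat])
        if fl == 0.0 and fm == 0.0:
            out[cat] = float("nan")
            continue
        if fl == 0.0 or fm == 0.0:
            pseudo = 0.5 * min(v for v in (fl, fm) if v > 0)
            fl = fl or pseudo
            fm = fm or pseudo
        out[cat] = fl / fm if fl >= fm else -(fm / fl)
    return out


def cog_profile(
    assignments_by_label: Mapping[str, Sequence[CogAssignment]],
    microbial_assignments: Sequence[CogAssignment],
) -> pd.DataFrame:
    """Fig.-7-style profile table: per (mechanism label, category) counts,
    frequencies under both readings and signed fold changes vs the
    microbial profile."""
    micro = category_frequencies(microbial_assignments).set_index("category")
    rows = []
    for label in sorted(assignments_by_label):
        freq = category_frequencies(assignments_by_label[label]).set_index("category")
        cats = sorted(set(freq.index) | set(micro.index))
        for kind in ("freq_hc", "freq_raw"):
            fl = {c: float(freq[kind].get(c, 0.0)) for c in cats}
            fm = {c: float(micro[kind].get(c, 0.0)) for c in cats}
            fc = fold_changes(fl, fm)
            for c in cats:
                rows.append((label, c, kind, fl[c], fm[c], fc[c]))
    long = pd.DataFrame(
        rows,
        columns=["label", "category", "freq_kind", "freq_label", "freq_microbial", "fold_change"],
    )
    counts = []
    for label in sorted(assignments_by_label):
        t = category_frequencies(assignments_by_label[label])
        t.insert(0, "label", label)
        counts.append(t)
    wide = pd.concat(counts, ignore_index=True) if counts else pd.DataFrame()
    return long.merge(wide, on=["label", "category"], how="left")


# ---------------------------------------------------------------------------
# transposase accounting
# ---------------------------------------------------------------------------


def transposase_scan(annotations: Iterable[str] | Mapping[str, Iterable[str]]):
    """Count annotation strings matching the transposable-element regex.

    With a plain iterable of strings, returns the match count; with a
    mapping (e.g. MAG id -> annotation list), returns per-key counts.
    """
    if isinstance(annotations, Mapping):
        return {k: transposase_scan(v) for k, v in annotations.items()}
    return sum(1 for s in annotations if _TRANSPOSASE_RE.search(s))


def mobilome_transposase_fraction(
    assignments: Sequence[CogAssignment],
    cluster_names: Mapping[str, str],
) -> float | None:
    """Share of Mobilome (category X) reads whose COG cluster name contains
    "transposase" (case-insensitive); None without Mobilome reads."""
    mob = [a for a in assignments if a.cog_category == "X"]
    if not mob:
        logger.warning("no Mobilome-assigned reads: fraction undefined")
        return None
    n_tn = sum(
        1
        for a in mob
        if "transposase" in cluster_names.get(a.cog_cluster_id, "").lower()
    )
    return n_tn / len(mob)


def cluster_names_from_db(cog_db: Sequence[SeqRecord]) -> dict[str, str]:
    """cluster_id -> cluster name from a tagged COG reference."""
    out = {}
    for rec in cog_db:
        tags = parse_tags(rec.description)
        out[tags.get("cluster", rec.id)] = tags.get("name", "")
    return out
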