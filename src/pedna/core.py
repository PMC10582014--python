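"""Sequence and alignment primitives shared by every pipeline stage.

This module provides the desk-scale stand-ins for the external tools the
peDNA pipeline is normally built on: FASTA/FASTQ/TSV I/O, a prodigal-like
ORF finder, translation, a Smith-Waterman protein aligner with
Karlin-Altschul E-values (diamond blastp stand-in) and a k-mer seed-and-vote
read mapper (bbmap stand-in).  All coordinates are 0-based, half-open and
anchored on the forward strand.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("pedna")

# ---------------------------------------------------------------------------
# basic types and constants
# ---------------------------------------------------------------------------

DNA_ALPHABET = set("ACGTN")
START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: gapped BLOSUM62 Karlin-Altschul defaults (diamond/BLAST convention)
LAMBDA_DEFAULT = 0.267
K_DEFAULT = 0.041

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# 2-bit base codes; N (and anything else) -> 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_dna(seq: str) -> np.ndarray:
    """Encode DNA into uint8 codes A=0 C=1 G=2 T=3, N/other=4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class SeqRecord:
    """A named DNA (or protein, for reference sets) sequence."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


@dataclass
class Orf:
    """An open reading frame, forward-strand anchored, stop codon included
    in the interval but not in the protein."""

    parent_id: str
    start: int
    end: int
    strand: str
    protein: str


@dataclass
class ProteinHit:
    """A local protein alignment in diamond-blastp-like terms."""

    query_id: str
    subject_id: str
    score: float
    pident: float
    qcov: float
    scov: float
    evalue: float


@dataclass
class ReadPair:
    """A paired-end read (mate 2 stored as sequenced, i.e. reverse strand)."""

    id: str
    seq1: str
    seq2: str


#: a read set is simply a list of ReadPair
ReadSet = list


@dataclass
class Alignment:
    """A single-mate placement on a target (one primary hit per mate)."""

    read_id: str
    target_id: str
    target_pos: int
    identity: float
    length: int
    strand: str = "+"
    mate_consistent: bool = False

    @property
    def pair_id(self) -> str:
        return self.read_id.rsplit("/", 1)[0]


# ---------------------------------------------------------------------------
# FASTA / FASTQ / TSV I/O
# ---------------------------------------------------------------------------


def _validate_records(records: list[SeqRecord], origin: str, strict: bool) -> None:
    seen: set[str] = set()
    for i, rec in enumerate(records):
        if not rec.id:
            raise ValueError(f"{origin}: record {i + 1} has an empty id")
        if rec.id in seen:
            raise ValueError(f"{origin}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        if not rec.seq:
            raise ValueError(f"{origin}: record {rec.id!r} has an empty sequence")
        if strict:
            bad = set(rec.seq.upper()) - DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"{origin}: record {rec.id!r} contains illegal characters "
                    f"{sorted(bad)}"
                )


def read_fasta(path: str | os.PathLike, strict: bool = True) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords (ids unique, DNA alphabet enforced
    when *strict*)."""
    try:
        records = [
            SeqRecord(r.id, str(r.seq), r.description)
            for r in SeqIO.parse(str(path), "fasta")
        ]
    except ValueError as exc:  # malformed record
        raise ValueError(f"{path}: FASTA parse error: {exc}") from exc
    _validate_records(records, str(path), strict)
    return records


def write_fasta(path: str | os.PathLike, records: Iterable[SeqRecord]) -> None:
    SeqIO.write(
        (_BioSeqRecord(Seq(r.seq), id=r.id, description=r.description) for r in records),
        str(path),
        "fasta",
    )


def read_fastq(path: str | os.PathLike, strict: bool = True) -> list[SeqRecord]:
    """Read a FASTQ file (Sanger +33); qualities are not retained."""
    try:
        records = [
            SeqRecord(r.id, str(r.seq), r.description)
            for r in SeqIO.parse(str(path), "fastq")
        ]
    except ValueError as exc:
        raise ValueError(f"{path}: FASTQ parse error: {exc}") from exc
    _validate_records(records, str(path), strict)
    return records


def write_fastq(
    path: str | os.PathLike, records: Iterable[SeqRecord], quality: int = 40
) -> None:
    """Write records as FASTQ with a constant Sanger quality."""
    with open(path, "w") as fh:
        qchar = chr(quality + 33)
        for r in records:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qchar * len(r.seq)}\n")


def write_alignments_tsv(
    path: str | os.PathLike,
    alignments: Sequence[Alignment],
    all_read_ids: Sequence[str] | None = None,
) -> None:
    """Write a headered, deterministically ordered alignment table.

    When *all_read_ids* is given, reads without an alignment are emitted
    with mapped=0.
    """
    mapped = {a.read_id: a for a in alignments}
    ids = list(all_read_ids) if all_read_ids is not None else [a.read_id for a in alignments]
    with open(path, "w") as fh:
        fh.write("read_id\ttarget_id\tpos\tidentity\tmapped\n")
        for rid in ids:
            a = mapped.get(rid)
            if a is None:
                fh.write(f"{rid}\t.\t-1\t0.0\t0\n")
            else:
                fh.write(f"{rid}\t{a.target_id}\t{a.target_pos}\t{a.identity:.4f}\t1\n")


# ---------------------------------------------------------------------------
# translation and ORF finding
# ---------------------------------------------------------------------------

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_MAP: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _c in _STANDARD_TABLE.stop_codons:
    _CODON_MAP[_c] = "*"


def translate(dna: str) -> str:
    """Translate *dna* under the standard genetic code.

    The length must be a multiple of three; a single trailing stop is
    dropped, internal stops appear as '*', codons containing N as 'X'.
    """
    if len(dna) % 3 != 0:
        raise ValueError(f"sequence length {len(dna)} is not a multiple of 3")
    s = dna.upper()
    prot = "".join(
        _CODON_MAP.get(s[i : i + 3], "X") for i in range(0, len(s), 3)
    )
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


def _codon_values(codons: Iterable[str]) -> np.ndarray:
    return np.array(
        sorted(16 * "ACGT".index(c[0]) + 4 * "ACGT".index(c[1]) + "ACGT".index(c[2]) for c in codons),
        dtype=np.int16,
    )


_STOP_VALS = _codon_values(STOP_CODONS)


def _frame_orf_intervals(
    codes: np.ndarray, min_codons: int, start_vals: np.ndarray
) -> list[tuple[int, int]]:
    """Maximal start->stop intervals on one strand (all 3 frames);
    intervals include the stop codon."""
    n = len(codes)
    if n < 6:
        return []
    v = (
        codes[:-2].astype(np.int16) * 16
        + codes[1:-1].astype(np.int16) * 4
        + codes[2:].astype(np.int16)
    )
    v[(codes[:-2] > 3) | (codes[1:-1] > 3) | (codes[2:] > 3)] = -1
    out: list[tuple[int, int]] = []
    for frame in range(3):
        pos = np.arange(frame, n - 2, 3)
        vals = v[pos]
        starts = pos[np.isin(vals, start_vals)]
        stops = pos[np.isin(vals, _STOP_VALS)]
        if len(stops) == 0 or len(starts) == 0:
            continue
        prev_stop = np.concatenate(([frame - 3], stops[:-1]))
        idx = np.searchsorted(starts, prev_stop + 3)
        ok = idx < len(starts)
        s = starts[idx[ok]]
        e = stops[ok]
        keep = (s < e) & ((e - s) // 3 >= min_codons)
        out.extend((int(a), int(b) + 3) for a, b in zip(s[keep], e[keep]))
    return out


def find_orfs(
    record: SeqRecord,
    min_codons: int = 50,
    starts: Iterable[str] = START_CODONS,
) -> list[Orf]:
    """Find every maximal start->stop ORF of >= *min_codons* codons
    (stop excluded from the count) on both strands.

    Coordinates are forward-strand anchored, half-open, and include the
    stop codon.  Alternative starts (GTG/TTG) translate as M.
    """
    if min_codons < 10:
        raise ValueError("min_codons must be >= 10")
    start_vals = _codon_values(starts)
    seq = record.seq.upper()
    n = len(seq)
    orfs: list[Orf] = []
    fwd_codes = encode_dna(seq)
    rc = revcomp(seq)
    for strand, codes, s in (("+", fwd_codes, seq), ("-", encode_dna(rc), rc)):
        for a, b in _frame_orf_intervals(codes, min_codons, start_vals):
            prot = translate(s[a:b])
            prot = "M" + prot[1:]
            if strand == "+":
                ivl = (a, b)
            else:
                ivl = (n - b, n - a)
            orfs.append(Orf(record.id, ivl[0], ivl[1], strand, prot))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


# ---------------------------------------------------------------------------
# Smith-Waterman protein alignment with Karlin-Altschul E-values
# ---------------------------------------------------------------------------

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AAX = _AA20 + "X"


def _extended_blosum62() -> substitution_matrices.Array:
    """BLOSUM62 over the 20 standard residues, with X as a score-0
    wildcard (overriding BLOSUM62's native X penalties)."""
    b62 = substitution_matrices.load("BLOSUM62")
    m = substitution_matrices.Array(alphabet=_AAX, dims=2)
    for a in _AA20:
        for b in _AA20:
            m[a, b] = b62[a, b]
    # X row/column stays 0.0
    return m


_B62X = _extended_blosum62()
_ALIGNER_CACHE: dict[tuple[float, float], Align.PairwiseAligner] = {}


def _aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    key = (gap_open, gap_extend)
    al = _ALIGNER_CACHE.get(key)
    if al is None:
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.substitution_matrix = _B62X
        # BLAST convention: a gap of length L costs gap_open + L*gap_extend
        al.open_gap_score = -(gap_open + gap_extend)
        al.extend_gap_score = -gap_extend
        _ALIGNER_CACHE[key] = al
    return al


def _sanitize_protein(seq: str) -> str:
    s = seq.upper()
    if all(c in _AAX for c in s):
        return s
    logger.debug("non-standard residues treated as score-0 wildcard X")
    return "".join(c if c in _AAX else "X" for c in s)


def evalue_from_score(
    score: float, m: int, n: int, lam: float = LAMBDA_DEFAULT, k: float = K_DEFAULT
) -> float:
    """Karlin-Altschul expectation E = K*m*n*exp(-lambda*S)."""
    return k * m * n * math.exp(-lam * score)


def sw_align(
    query: str,
    subject: str,
    query_id: str = "query",
    subject_id: str = "subject",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    lam: float = LAMBDA_DEFAULT,
    k: float = K_DEFAULT,
    m: int | None = None,
    n: int | None = None,
) -> ProteinHit:
    """Optimal local (Smith-Waterman) alignment under BLOSUM62 with affine
    gaps; pident/qcov/scov from the optimal traceback, E-value from the
    Karlin-Altschul closed form with search-space sizes *m*, *n*
    (defaulting to the sequence lengths)."""
    if not query or not subject:
        raise ValueError("sw_align requires non-empty sequences")
    q = _sanitize_protein(query)
    s = _sanitize_protein(subject)
    al = _aligner(gap_open, gap_extend)
    score = float(al.score(q, s))
    m = m if m is not None else len(q)
    n = n if n is not None else len(s)
    ev = evalue_from_score(score, m, n, lam, k)
    if score <= 0:
        return ProteinHit(query_id, subject_id, 0.0, 0.0, 0.0, 0.0, ev)
    aln = al.align(q, s)[0]
    tblocks, qblocks = aln.aligned  # target=first arg (q), query=second (s)
    qb = tblocks  # blocks on our query
    sb = qblocks  # blocks on our subject
    matches = 0
    columns = 0
    for (qa, qe), (sa, se) in zip(qb, sb):
        columns += qe - qa
        matches += sum(1 for i in range(qe - qa) if q[qa + i] == s[sa + i])
    for i in range(1, len(qb)):
        columns += (qb[i][0] - qb[i - 1][1]) + (sb[i][0] - sb[i - 1][1])
    qspan = qb[-1][1] - qb[0][0]
    sspan = sb[-1][1] - sb[0][0]
    pident = 100.0 * matches / columns if columns else 0.0
    return ProteinHit(
        query_id,
        subject_id,
        score,
        pident,
        100.0 * qspan / len(q),
        100.0 * sspan / len(s),
        ev,
    )


def _kmer_set(seq: str, k: int = 4) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def search_hits(
    queries: Sequence[tuple[str, str]],
    db: Sequence[SeqRecord],
    evalue_max: float = 1e-5,
    pident_min: float = 50.0,
    prefilter: bool = True,
    **align_kwargs,
) -> list[ProteinHit]:
    """All-vs-all protein search of (id, protein) *queries* against *db*,
    keeping hits with E <= *evalue_max* and pident > *pident_min*.

    A shared-4-mer prefilter skips clearly unrelated pairs; any pair able
    to satisfy the thresholds shares 4-mers, so the filter is lossless at
    these settings.
    """
    lam = align_kwargs.get("lam", LAMBDA_DEFAULT)
    kparam = align_kwargs.get("k", K_DEFAULT)
    al = _aligner(
        align_kwargs.get("gap_open", 11.0), align_kwargs.get("gap_extend", 1.0)
    )
    db_clean = [(rec, _sanitize_protein(rec.seq)) for rec in db]
    db_kmers = [_kmer_set(s) for _, s in db_clean] if prefilter else None
    hits: list[ProteinHit] = []
    for qid, qseq in queries:
        q = _sanitize_protein(qseq)
        qk = _kmer_set(q) if prefilter else None
        for j, (rec, s) in enumerate(db_clean):
            if prefilter and qk is not None and db_kmers is not None and not (qk & db_kmers[j]):
                continue
            score = float(al.score(q, s))
            ev = evalue_from_score(score, len(q), len(s), lam, kparam)
            if ev > evalue_max:
                continue
            hit = sw_align(q, s, qid, rec.id, **align_kwargs)
            if hit.evalue <= evalue_max and hit.pident > pident_min:
                hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# k-mer seed-and-vote read mapper
# ---------------------------------------------------------------------------


class KmerIndex:
    """Sorted-array k-mer index over a target set (k odd, 15..31)."""

    def __init__(self, targets: Sequence[SeqRecord], k: int = 21):
        if not (15 <= k <= 31 and k % 2 == 1):
            raise ValueError("k must be odd and within [15, 31]")
        self.k = k
        self.ids = [t.id for t in targets]
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate target ids in mapper index")
        # rank of each target in lexicographic id order, for tie-breaking
        order = sorted(range(len(self.ids)), key=lambda i: self.ids[i])
        self.id_rank = np.empty(len(self.ids), dtype=np.int64)
        for rank, i in enumerate(order):
            self.id_rank[i] = rank
        codes = [encode_dna(t.seq) for t in targets]
        self.lengths = np.array([len(c) for c in codes], dtype=np.int64)
        self.offsets = np.concatenate(([0], np.cumsum(self.lengths)))
        self.global_codes = (
            np.concatenate(codes) if codes else np.empty(0, dtype=np.uint8)
        )
        kmers_parts, tidx_parts, pos_parts = [], [], []
        for i, c in enumerate(codes):
            if len(c) < k:
                continue
            km, valid = _rolling_kmers(c, k)
            pos = np.nonzero(valid)[0]
            kmers_parts.append(km[pos])
            tidx_parts.append(np.full(len(pos), i, dtype=np.int32))
            pos_parts.append(pos.astype(np.int64))
        if kmers_parts:
            kmers = np.concatenate(kmers_parts)
            tidx = np.concatenate(tidx_parts)
            pos = np.concatenate(pos_parts)
            srt = np.argsort(kmers, kind="stable")
            self.kmers = kmers[srt]
            self.tidx = tidx[srt]
            self.pos = pos[srt]
        else:  # pragma: no cover - degenerate
            self.kmers = np.empty(0, dtype=np.uint64)
            self.tidx = np.empty(0, dtype=np.int32)
            self.pos = np.empty(0, dtype=np.int64)


def _rolling_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """uint64 2-bit k-mer values at every position plus a validity mask
    (windows containing N are invalid)."""
    n = len(codes) - k + 1
    vals = np.zeros(n, dtype=np.uint64)
    invalid = np.zeros(n, dtype=bool)
    c64 = codes.astype(np.uint64)
    bad = codes > 3
    for j in range(k):
        vals = (vals << np.uint64(2)) | (c64[j : j + n] & np.uint64(3))
        invalid |= bad[j : j + n]
    return vals, ~invalid


def _vote_and_place(
    index: KmerIndex,
    h_tidx: np.ndarray,
    h_diag: np.ndarray,
) -> tuple[int, int]:
    """Pick the best target by k-mer vote (tie -> lexicographically smaller
    id), then the placement diagonal by majority (tie -> smaller)."""
    if np.all(h_tidx == h_tidx[0]):
        best = int(h_tidx[0])
        d = h_diag
    else:
        counts = np.bincount(h_tidx, minlength=len(index.ids))
        top = counts.max()
        cand = np.nonzero(counts == top)[0]
        best = int(cand[np.argmin(index.id_rank[cand])])
        d = h_diag[h_tidx == best]
    if len(d) == 1 or np.all(d == d[0]):
        return best, int(d[0])
    dmin = int(d.min())
    c = np.bincount(d - dmin)
    return best, int(np.argmax(c)) + dmin  # argmax returns first (smallest) tie


_KMER_SENTINEL = np.uint64(0xFFFFFFFFFFFFFFFF)


def _batch_kmers(codes: np.ndarray, k: int, offs: np.ndarray) -> np.ndarray:
    """Row-wise 2-bit k-mer values at the seed offsets *offs* for a
    (n_reads, L) code matrix; windows containing N get a sentinel value
    absent from any index."""
    n = codes.shape[0]
    vals = np.zeros((n, len(offs)), dtype=np.uint64)
    invalid = np.zeros((n, len(offs)), dtype=bool)
    c64 = codes.astype(np.uint64)
    bad = codes > 3
    for j in range(k):
        col = offs + j
        vals = (vals << np.uint64(2)) | (c64[:, col] & np.uint64(3))
        invalid |= bad[:, col]
    vals[invalid] = _KMER_SENTINEL
    return vals


def _gather_hits(
    index: KmerIndex, kmers: np.ndarray, offs: np.ndarray, max_hits_per_kmer: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flat (row, tidx, diag) hit arrays, sorted by row, for a
    (n_reads, n_seeds) k-mer matrix whose seeds sit at read offsets
    *offs*."""
    n, w = kmers.shape
    flat = kmers.ravel()
    lo = np.searchsorted(index.kmers, flat, side="left")
    nk = len(index.kmers)
    rows_parts, offs_parts, tidx_parts, pos_parts = [], [], [], []
    cell = np.arange(n * w, dtype=np.int64)
    # multiplicity by equality probes instead of a second searchsorted
    for j in range(max_hits_per_kmer):
        idxs = lo + j
        ok = (idxs < nk) & (index.kmers[np.minimum(idxs, nk - 1)] == flat)
        if not ok.any():
            break
        idxs = idxs[ok]
        cells = cell[ok]
        rows_parts.append(cells // w)
        offs_parts.append(offs[cells % w])
        tidx_parts.append(index.tidx[idxs].astype(np.int64))
        pos_parts.append(index.pos[idxs])
    if not rows_parts:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, empty
    rows = np.concatenate(rows_parts)
    qoff = np.concatenate(offs_parts)
    tidx = np.concatenate(tidx_parts)
    pos = np.concatenate(pos_parts)
    if len(rows_parts) > 1:  # restore row-major order
        order = np.argsort(rows, kind="stable")
        rows, qoff, tidx, pos = rows[order], qoff[order], tidx[order], pos[order]
    return rows, tidx, pos - qoff


def _map_single_seqs(
    seqs: Sequence[str],
    index: KmerIndex,
    max_hits_per_kmer: int = 4,
    seed_stride: int = 4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Map each sequence independently; returns (tidx, pos, identity,
    aligned_len, strand_code) with tidx=-1 for unseeded reads.  Seeds are
    sampled every *seed_stride* positions (plus the last window)."""
    nreads = len(seqs)
    out_t = np.full(nreads, -1, dtype=np.int64)
    out_p = np.zeros(nreads, dtype=np.int64)
    out_id = np.zeros(nreads, dtype=np.float64)
    out_len = np.zeros(nreads, dtype=np.int64)
    out_strand = np.zeros(nreads, dtype=np.int8)  # 0='+', 1='-'
    if len(index.kmers) == 0 or nreads == 0:
        return out_t, out_p, out_id, out_len, out_strand
    k = index.k
    g = index.global_codes
    glen = len(g)
    # group reads of equal length so each group maps as one matrix batch
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        if len(s) >= k:
            by_len.setdefault(len(s), []).append(i)
    for L, idx_list in sorted(by_len.items()):
        ids = np.array(idx_list, dtype=np.int64)
        w = L - k + 1
        offs = np.arange(0, w, seed_stride, dtype=np.int64)
        if offs[-1] != w - 1:
            offs = np.append(offs, w - 1)
        fwd = encode_dna("".join(seqs[i] for i in idx_list)).reshape(len(ids), L)
        rc = fwd[:, ::-1]
        rc = np.where(rc < 4, 3 - rc, rc)
        hits = {
            0: _gather_hits(index, _batch_kmers(fwd, k, offs), offs, max_hits_per_kmer),
            1: _gather_hits(index, _batch_kmers(rc, k, offs), offs, max_hits_per_kmer),
        }
        counts = {
            s: np.bincount(hits[s][0], minlength=len(ids)) for s in (0, 1)
        }
        use_rc = counts[1] > counts[0]
        ptr = {
            s: np.searchsorted(hits[s][0], np.arange(len(ids) + 1))
            for s in (0, 1)
        }
        chosen_rows = []
        for r in range(len(ids)):
            strand = 1 if use_rc[r] else 0
            rows, tidx, diag = hits[strand]
            a, b = ptr[strand][r], ptr[strand][r + 1]
            if a == b:
                continue
            t, d = _vote_and_place(index, tidx[a:b], diag[a:b])
            chosen_rows.append((r, strand, t, d))
        if not chosen_rows:
            continue
        rsel = np.array([c[0] for c in chosen_rows], dtype=np.int64)
        ssel = np.array([c[1] for c in chosen_rows], dtype=np.int8)
        tsel = np.array([c[2] for c in chosen_rows], dtype=np.int64)
        dsel = np.array([c[3] for c in chosen_rows], dtype=np.int64)
        codes = np.where(ssel[:, None] == 0, fwd[rsel], rc[rsel])
        toff = index.offsets[tsel]
        tend = toff + index.lengths[tsel]
        col = (toff + dsel)[:, None] + np.arange(L)
        inside = (col >= toff[:, None]) & (col < tend[:, None])
        tvals = g[np.clip(col, 0, glen - 1)]
        aligned = inside.sum(axis=1)
        matches = (inside & (tvals == codes) & (codes < 4)).sum(axis=1)
        ok = aligned > 0
        gi = ids[rsel[ok]]
        out_t[gi] = tsel[ok]
        out_p[gi] = np.maximum(dsel[ok], 0)
        out_id[gi] = matches[ok] / aligned[ok]
        out_len[gi] = aligned[ok]
        out_strand[gi] = ssel[ok]
    return out_t, out_p, out_id, out_len, out_strand


def kmer_map_single(
    reads: Sequence[SeqRecord],
    targets: Sequence[SeqRecord],
    k: int = 21,
    min_identity: float = 0.9,
    min_len: int | None = None,
    index: KmerIndex | None = None,
) -> list[Alignment]:
    """Map single sequences to their best target (seed-and-vote, ungapped
    extension); reads below *min_identity* over >= *min_len* aligned bases
    are unmapped."""
    idx = index if index is not None else KmerIndex(targets, k)
    if not idx.ids:
        logger.warning("empty target set: all reads unmapped")
        return []
    tarr, parr, iarr, larr, sarr = _map_single_seqs([r.seq for r in reads], idx)
    need = min_len if min_len is not None else idx.k
    out = []
    for i, r in enumerate(reads):
        if tarr[i] < 0 or iarr[i] < min_identity or larr[i] < need:
            continue
        out.append(
            Alignment(
                r.id,
                idx.ids[tarr[i]],
                int(parr[i]),
                float(iarr[i]),
                int(larr[i]),
                "+" if sarr[i] == 0 else "-",
                False,
            )
        )
    return out


def kmer_map_reads(
    reads: Sequence,
    targets: Sequence[SeqRecord],
    k: int = 21,
    min_identity: float = 0.9,
    min_len: int | None = None,
    index: KmerIndex | None = None,
) -> list[Alignment]:
    """Map read pairs to the single best target.

    Each mate is placed by shared-k-mer vote then verified by ungapped
    extension identity; a pair counts only when both mates place on the
    same target at >= *min_identity* (tie between targets broken toward the
    lexicographically smaller id).  Two alignments (mate /1 and /2) are
    emitted per mapped pair; unmapped pairs are omitted.
    """
    idx = index if index is not None else KmerIndex(targets, k)
    if not idx.ids:
        logger.warning("empty target set: all read pairs unmapped")
        return []
    seqs: list[str] = []
    for rp in reads:
        seqs.append(rp.seq1)
        seqs.append(rp.seq2)
    tarr, parr, iarr, larr, sarr = _map_single_seqs(seqs, idx)
    need = min_len if min_len is not None else idx.k
    out: list[Alignment] = []
    for j, rp in enumerate(reads):
        a, b = 2 * j, 2 * j + 1
        if tarr[a] < 0 or tarr[b] < 0 or tarr[a] != tarr[b]:
            continue
        if iarr[a] < min_identity or iarr[b] < min_identity:
            continue
        if larr[a] < need or larr[b] < need:
            continue
        tid = idx.ids[tarr[a]]
        for mate, i in (("1", a), ("2", b)):
            out.append(
                Alignment(
                    f"{rp.id}/{mate}",
                    tid,
                    int(parr[i]),
                    float(iarr[i]),
                    int(larr[i]),
                    "+" if sarr[i] == 0 else "-",
                    True,
                )
            )
    return out


def pair_targets(alignments: Sequence[Alignment]) -> dict[str, str]:
    """Pair id -> target id for pair-consistent alignments."""
    return {a.pair_id: a.target_id for a in alignments if a.mate_consistent}


def count_pairs_per_target(alignments: Sequence[Alignment]) -> dict[str, int]:
    """Read-pair recruitment counts per target."""
    counts: dict[str, int] = {}
    for pid, tid in pair_targets(alignments).items():
        counts[tid] = counts.get(tid, 0) + 1
    return counts
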