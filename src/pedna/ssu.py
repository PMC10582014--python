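"""SSU rRNA contamination screen (ViromeQC-style stand-in).

Reports the percentage of read pairs with at least one mate aligning to a
16S/18S rRNA reference.  The screen is descriptive only: because EVs and
GTAs package host DNA (including rRNA genes), an elevated SSU rate neither
proves nor disproves cellular contamination of a peDNA sample, so no
pass/fail verdict is issued.  The published average SSU alignment rate of
microbial metagenomes (0.078%) is attached to the report as comparator
metadata.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

from .core import KmerIndex, SeqRecord, kmer_map_single

#: average SSU alignment rate of public microbial metagenomes (%),
#: reported as context only — never as a contamination verdict
METAGENOME_MEAN_SSU_PERCENT = 0.078


@dataclass
class SsuReport:
    """SSU alignment summary for one read set."""

    sample_id: str
    n_pairs_total: int
    n_pairs_ssu: int
    reference_metagenome_mean_percent: float = METAGENOME_MEAN_SSU_PERCENT

    @property
    def rate_percent(self) -> float:
        return 100.0 * self.n_pairs_ssu / self.n_pairs_total


def ssu_rate(
    reads: Sequence,
    ssu_refs: Sequence[SeqRecord],
    min_identity: float = 0.8,
    min_len: int = 50,
    sample_id: str = "sample",
    k: int = 21,
) -> SsuReport:
    """Percentage of read pairs aligning to any SSU rRNA reference.

    A pair counts as SSU when either mate maps to any reference at
    >= *min_identity* over >= *min_len* aligned bases.  Duplicate
    reference entries and read order do not affect the rate.
    """
    if not ssu_refs:
        raise ValueError("ssu_refs must be non-empty")
    if not reads:
        raise ValueError("ssu_rate requires a non-empty read set")
    # drop duplicate reference sequences so multi-copy references do not
    # fragment the k-mer vote
    seen: set[str] = set()
    refs = []
    for r in ssu_refs:
        if r.seq not in seen:
            seen.add(r.seq)
            refs.append(r)
    index = KmerIndex(refs, k)
    mates = []
    for rp in reads:
        mates.append(SeqRecord(f"{rp.id}/1", rp.seq1))
        mates.append(SeqRecord(f"{rp.id}/2", rp.seq2))
    hits = kmer_map_single(
        mates, refs, k=k, min_identity=min_identity, min_len=min_len, index=index
    )
    pairs = {a.read_id.rsplit("/", 1)[0] for a in hits}
    return SsuReport(sample_id, len(reads), len(pairs))


def write_ssu_report(path: str | os.PathLike, report: SsuReport) -> None:
    """One-row TSV with the SSU rate and the metagenome comparator line."""
    with open(path, "w") as fh:
        fh.write(
            "sample_id\tn_pairs_total\tn_pairs_ssu\trate_percent\t"
            "reference_metagenome_mean_percent\n"
        )
        fh.write(
            f"{report.sample_id}\t{report.n_pairs_total}\t{report.n_pairs_ssu}\t"
            f"{report.rate_percent:.6f}\t{report.reference_metagenome_mean_percent}\n"
        )
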