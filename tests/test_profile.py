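"""Tests for per-mechanism COG profiling, fold changes and transposase
accounting."""

import math

import numpy as np
import pytest

from pedna import core, profile, simulate
from pedna.profile import CogAssignment
from pedna.simulate import CarrierMix
from tests.conftest import random_dna


def read_orf_oracle(seq: str, min_codons: int = 20):
    """Exhaustive 6-frame stop-free-run scan (independent oracle)."""
    runs = []
    if len(seq) < 60:
        return runs
    for s in (seq, core.revcomp(seq)):
        for frame in range(3):
            sub = s[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            prot = ""
            for i in range(0, len(sub), 3):
                codon = sub[i : i + 3]
                prot += "*" if codon in core.STOP_CODONS else core._CODON_MAP.get(codon, "X")
            runs.extend(r for r in prot.split("*") if len(r) >= min_codons)
    return runs


def transposase_oracle(s: str) -> bool:
    """Independent matcher for the transposable-element pattern."""
    if "transposase" in s or "Transposase" in s:
        return True
    for i in range(len(s) - 2):
        if s[i : i + 2] in ("IS", "Tn") and s[i + 2].isdigit():
            return True
    return False


class TestAssignMechanismReads:
    def test_reads_inherit_mag_label(self, small_mech_community, small_mech_reads):
        reads, truth = small_mech_reads
        labeled = {g.id: g.truth_mechanism for g in small_mech_community}
        mags = [core.SeqRecord(g.id, g.seq) for g in small_mech_community]
        by_label = profile.assign_mechanism_reads(reads[:2000], labeled, mags)
        assert set(by_label) == {"EV_producer", "GTA_producer", "transducer"}
        truth_src = dict(zip(truth.read_id, truth.source_genome))
        for label, rs in by_label.items():
            for rp in rs:
                assert labeled[truth_src[rp.id]] == label

    def test_low_identity_read_excluded(self, rng):
        mag = core.SeqRecord("m", random_dna(rng, 8000))
        read = list(mag.seq[1000:1150])
        for p in range(0, 150, 10):  # 10% substitutions
            read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
        pairs = [core.ReadPair("p0", "".join(read), core.revcomp(mag.seq[1400:1550]))]
        out = profile.assign_mechanism_reads(pairs, {"m": "EV_producer"}, [mag])
        assert out == {}

    def test_partition_sizes_match_truth_cross_tab(
        self, small_mech_community, small_mech_reads
    ):
        reads, truth = small_mech_reads
        labeled = {g.id: g.truth_mechanism for g in small_mech_community}
        mags = [core.SeqRecord(g.id, g.seq) for g in small_mech_community]
        by_label = profile.assign_mechanism_reads(reads, labeled, mags)
        truth_counts = truth.source_genome.map(labeled).value_counts()
        for label, rs in by_label.items():
            # mapping losses at minid 95 with 0.5% errors stay below 2%
            assert len(rs) >= 0.98 * truth_counts[label]
            assert len(rs) <= truth_counts[label]


class TestReadOrf:
    def test_in_frame_read_yields_gene_subpeptide(self, rng):
        prot = "M" + "".join(rng.choice(list(core._AA20), 59))
        dna = simulate.back_translate(prot, rng, stop=False)
        frag = profile.read_orf(dna[:90])
        assert frag == prot[:30]

    def test_stop_dense_read_skipped(self):
        assert profile.read_orf("TTAA" * 15) is None

    def test_short_read_skipped(self):
        assert profile.read_orf("ATG" * 19) is None

    def test_matches_six_frame_oracle_on_random_reads(self, rng):
        for _ in range(200):
            seq = random_dna(rng, 100)
            got = profile.read_orf(seq)
            runs = read_orf_oracle(seq)
            if not runs:
                assert got is None
            else:
                assert got in runs and len(got) == max(len(r) for r in runs)


class TestCogAssign:
    def test_identical_fragment_assigned_to_its_cluster(self):
        db = simulate.cog_reference()
        rec = db[0]
        frags = [("r1/1", rec.seq[10:60])]
        out = profile.cog_assign(frags, db)
        assert len(out) == 1
        a = out[0]
        assert a.gene_id == rec.id
        assert a.cog_cluster_id == simulate.parse_tags(rec.description)["cluster"]
        assert a.cog_category == simulate.parse_tags(rec.description)["cat"]

    def test_subject_cover_threshold_rejects(self):
        db = simulate.cog_reference()
        rec = db[0]
        frags = [("r1/1", rec.seq[10:60])]  # ~25% of the subject
        assert profile.cog_assign(frags, db, scov_min=50.0) == []
        assert len(profile.cog_assign(frags, db, scov_min=10.0)) == 1

    def test_assignments_match_planted_gene_truth(self):
        """Each assigned read must physically overlap a planted gene of the
        assigned cluster (truth-table oracle)."""
        com = simulate.build_community(2, 0, mechanism_counts={"EV_producer": 2}, seed=81)
        reads, truth = simulate.sample_pedna_reads(
            com, CarrierMix(weights={"ev": 1.0}), 1500, seed=82
        )
        frags = profile.predict_fragments(reads)
        out = profile.cog_assign(frags, simulate.cog_reference())
        assert len(out) > 10
        truth_by_id = truth.set_index("read_id")
        genomes = {g.id: g for g in com}
        consistent = 0
        for a in out:
            pid, mate = a.read_id.rsplit("/", 1)
            row = truth_by_id.loc[pid]
            g = genomes[row.source_genome]
            if mate == "1":
                ms, me = row.insert_start, row.insert_start + 150
            else:
                ms, me = row.insert_end - 150, row.insert_end
            overlapping = {
                f.attrs.get("cluster")
                for f in g.features
                if f.kind in ("cog_gene", "transposase") and f.start < me and f.end > ms
            }
            consistent += a.cog_cluster_id in overlapping
        # the E-value threshold admits ~K*m*n*E chance hits over ~10^5
        # fragment x reference comparisons; demand near-perfect agreement
        assert consistent / len(out) >= 0.95

    def test_at_most_one_assignment_per_read(self):
        db = simulate.cog_reference()
        frags = [("r1/1", db[0].seq[5:80]), ("r1/1", db[0].seq[5:80])]
        out = profile.cog_assign(frags, db)
        assert len(out) == 1


class TestFlagHighCoverage:
    @staticmethod
    def _assign(gene):
        return CogAssignment("r/1", "EV_producer", "COGX001", "X", gene)

    def test_single_outlier_gene_flagged(self):
        rec = {"g1": 1.0, "g2": 1.0, "g3": 1.0, "g4": 1.0, "g5": 10.0}
        # direct computation: mean 2.8, population SD 3.6, cutoff 10.0
        assert np.mean(list(rec.values())) == pytest.approx(2.8)
        assert np.std(list(rec.values())) == pytest.approx(3.6)
        out = profile.flag_high_coverage(
            [self._assign(g) for g in rec], rec
        )
        assert [a.high_coverage for a in out] == [False, False, False, False, True]

    def test_equal_recruitment_flags_nothing(self):
        rec = {f"g{i}": 2.0 for i in range(5)}
        out = profile.flag_high_coverage([self._assign("g0")], rec)
        assert not out[0].high_coverage

    def test_fewer_than_three_genes_warns_and_flags_nothing(self, caplog):
        with caplog.at_level("WARNING", logger="pedna"):
            out = profile.flag_high_coverage([self._assign("g0")], {"g0": 5.0})
        assert not out[0].high_coverage and "fewer than 3" in caplog.text

    def test_gene_recruitment_pairs_per_kb(self):
        genes = [("g1", "m", 0, 2000), ("g2", "m", 5000, 6000)]
        al = [
            core.Alignment("p0/1", "m", 100, 1.0, 150, "+", True),
            core.Alignment("p0/2", "m", 600, 1.0, 150, "-", True),
            core.Alignment("p1/1", "m", 5100, 1.0, 150, "+", True),
            core.Alignment("p1/2", "m", 9000, 1.0, 150, "-", True),
        ]
        rec = profile.gene_recruitment(genes, al)
        assert rec["g1"] == pytest.approx(0.5)  # 2 mates = 1 pair over 2 kb
        assert rec["g2"] == pytest.approx(0.5)  # 1 mate = 0.5 pair over 1 kb


class TestFoldChanges:
    def test_arithmetic_cases(self):
        fc = profile.fold_changes(
            {"A": 0.2, "B": 0.1, "C": 0.1}, {"A": 0.1, "B": 0.2, "C": 0.1}
        )
        assert fc["A"] == pytest.approx(2.0)
        assert fc["B"] == pytest.approx(-2.0)
        assert fc["C"] == pytest.approx(1.0)

    def test_zero_frequency_uses_half_min_pseudocount(self):
        fc = profile.fold_changes({"A": 0.2, "B": 0.0}, {"A": 0.1, "B": 0.1})
        # pseudocount 0.05 -> -(0.1/0.05) = -2
        assert fc["B"] == pytest.approx(-2.0)

    def test_both_zero_is_missing(self):
        fc = profile.fold_changes({"A": 0.0}, {"A": 0.0})
        assert math.isnan(fc["A"])

    def test_self_comparison_is_plus_one(self):
        p = {"A": 0.3, "B": 0.1, "C": 0.6}
        assert all(v == pytest.approx(1.0) for v in profile.fold_changes(p, p).values())

    def test_excluded_zone_and_antisymmetry(self, rng):
        for _ in range(50):
            a = {c: float(v) for c, v in zip("ABCDE", rng.random(5) + 1e-3)}
            b = {c: float(v) for c, v in zip("ABCDE", rng.random(5) + 1e-3)}
            fab = profile.fold_changes(a, b)
            fba = profile.fold_changes(b, a)
            for c in "ABCDE":
                assert abs(fab[c]) >= 1.0  # nothing in (-1, 1)
                if abs(fab[c]) != 1.0:
                    assert fab[c] == pytest.approx(-fba[c])

    def test_mismatched_categories_rejected(self):
        with pytest.raises(ValueError):
            profile.fold_changes({"A": 0.1}, {"B": 0.1})


class TestTransposaseScan:
    def test_examples(self):
        assert profile.transposase_scan(["IS5 family element", "hypothetical"]) == 1
        assert profile.transposase_scan(["Transposase", "transposase"]) == 2
        assert profile.transposase_scan({"m1": ["IS5"], "m2": ["kinase"]}) == {
            "m1": 1, "m2": 0,
        }

    def test_matches_independent_matcher_on_random_annotations(self, rng):
        vocab = [
            "IS5 family element", "ISx domain", "Tn3 resolvase", "attTn7 site",
            "transposase", "Transposase fragment", "integrase", "DNA polymerase",
            "hypothetical protein", "TnpA", "IS felis", "Tn-like",
        ]
        for _ in range(50):
            ann = [vocab[i] for i in rng.integers(0, len(vocab), size=6)]
            assert profile.transposase_scan(ann) == sum(
                transposase_oracle(s) for s in ann
            )


class TestMobilomeFraction:
    @staticmethod
    def _a(cluster, cat="X"):
        return CogAssignment("r/1", "EV_producer", cluster, cat, cluster)

    NAMES = {"tn1": "IS5 family transposase", "other": "prophage integrase"}

    def test_three_of_four(self):
        assigns = [self._a("tn1")] * 3 + [self._a("other")]
        assert profile.mobilome_transposase_fraction(assigns, self.NAMES) == 0.75

    def test_none_on_transposase_clusters(self):
        assigns = [self._a("other")] * 4
        assert profile.mobilome_transposase_fraction(assigns, self.NAMES) == 0.0

    def test_no_mobilome_reads_is_missing(self):
        assigns = [self._a("c", cat="K")]
        assert profile.mobilome_transposase_fraction(assigns, self.NAMES) is None


class TestEnrichmentRecovery:
    def test_mobilome_fold_change_dominates_for_ev_label(self):
        """EV producers planted with ~3x the community-average Mobilome
        gene density must show the largest positive Mobilome fold change
        (raw-composition reading, fixed seeds)."""
        ev_hosts = simulate.build_community(
            2, 0, mechanism_counts={"EV_producer": 2}, seed=91,
            transposases_per_host=9,
        )
        plain = simulate.build_community(
            4, 0, mechanism_counts={"none": 4}, seed=92, transposases_per_host=1,
        )
        for g in plain:
            g.id = "plain_" + g.id
        com = ev_hosts + plain
        pedna, _ = simulate.sample_pedna_reads(
            com, CarrierMix(weights={"ev": 1.0}), 2500, seed=93
        )
        meta, _ = simulate.sample_metagenome_reads(com, 2500, seed=94)
        db = simulate.cog_reference()
        ev_assign = profile.cog_assign(
            profile.predict_fragments(pedna), db, mechanism_label="EV_producer"
        )
        micro = profile.cog_assign(
            profile.predict_fragments(meta), db, mechanism_label="microbial"
        )
        ev_freq = profile.category_frequencies(ev_assign).set_index("category")
        mi_freq = profile.category_frequencies(micro).set_index("category")
        cats = sorted(set(ev_freq.index) & set(mi_freq.index))
        fc = profile.fold_changes(
            {c: ev_freq.freq_raw[c] for c in cats},
            {c: mi_freq.freq_raw[c] for c in cats},
        )
        assert fc["X"] > 1.0
        assert fc["X"] == max(fc.values())

    def test_per_label_totals_conserved(self):
        a = [CogAssignment(f"r{i}/1", "EV_producer", "c", cat, "g")
             for i, cat in enumerate("XXKKL")]
        t = profile.category_frequencies(a)
        assert t.n_tot.sum() == 5
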