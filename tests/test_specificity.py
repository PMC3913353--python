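"""Cross-hybridization screening: similarity, seed-and-extend, probe reports."""

import random

import pytest

from probegrid.consensus_design import DegenerateProbe
from probegrid.seq_core import (
    DesignParameters,
    SequenceRecord,
    TaxonGroup,
    degeneracy_of,
    reverse_complement,
)
from probegrid.specificity import (
    DatabaseIndex,
    allowed_mismatches,
    evaluate_probe,
    find_cross_hybridizations,
    seed_length,
    similarity,
)


def brute_force_hits(expansion, database, target_taxon, threshold):
    """Oracle: every-window Hamming scan of both strands."""
    l = len(expansion)
    hits = set()
    for grp in database:
        if target_taxon is not None and grp.taxon == target_taxon:
            continue
        for m in grp.members:
            for strand, q in (
                ("+", expansion),
                ("-", reverse_complement(expansion)),
            ):
                for p in range(len(m.sequence) - l + 1):
                    window = m.sequence[p : p + l]
                    matches = sum(a == b for a, b in zip(q, window))
                    if matches / l >= threshold - 1e-12:
                        hits.add((m.id, strand, p + 1))
    return hits


def random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def group_of(seqs, taxon):
    return TaxonGroup(taxon, [
        SequenceRecord(id=f"{taxon}_{i}", sequence=s, taxon=taxon)
        for i, s in enumerate(seqs)
    ])


def probe_for(seq, taxon="target"):
    return DegenerateProbe(taxon=taxon, start=1, length=len(seq),
                           sequence=seq, degeneracy=degeneracy_of(seq),
                           weight=float(degeneracy_of(seq)))


class TestSimilarity:
    def test_examples(self):
        a = "ACGTACGTACGTACGTACGTACGTA"
        assert similarity(a, a) == 1.0
        three = "TCGTACGTACGTACGTACGTACCTC"  # 3 mismatches
        assert similarity(a, three) == pytest.approx(22 / 25)
        four = "TCGTACGTACGTACGAACGTACCTC"
        assert similarity(a, four) == pytest.approx(21 / 25)
        with pytest.raises(ValueError):
            similarity("ACG", "AC")

    def test_threshold_is_inclusive_at_88_percent(self):
        # 22/25 = 0.88 must count as a cross-hybridization
        assert allowed_mismatches(25, 0.88) == 3

    def test_seed_length_keeps_pigeonhole_guarantee(self):
        for l in range(10, 60):
            for s in (0.80, 0.88, 0.92, 1.0):
                k = allowed_mismatches(l, s)
                w = seed_length(l, s)
                assert l // w >= k + 1  # enough disjoint seeds to tile


class TestFindCrossHybridizations:
    def setup_method(self):
        self.params = DesignParameters()
        self.rng = random.Random(21)

    def test_verbatim_plant_is_found_with_similarity_one(self):
        exp = random_seq(self.rng, 25)
        carrier = random_seq(self.rng, 100) + exp + random_seq(self.rng, 100)
        db = [group_of([carrier], "other"), group_of([exp * 2], "target")]
        hits = find_cross_hybridizations(exp, db, "target", self.params)
        assert any(h.similarity == 1.0 and h.strand == "+" for h in hits)
        assert all(h.subject_taxon != "target" for h in hits)

    def test_reverse_complement_plant_gives_minus_strand_hit(self):
        exp = random_seq(self.rng, 25)
        carrier = (random_seq(self.rng, 80) + reverse_complement(exp)
                   + random_seq(self.rng, 80))
        db = [group_of([carrier], "other")]
        hits = find_cross_hybridizations(exp, db, "target", self.params)
        assert [h.strand for h in hits] == ["-"]
        assert hits[0].similarity == 1.0 and hits[0].subject_start == 81

    def test_target_only_database_yields_nothing(self):
        exp = random_seq(self.rng, 25)
        db = [group_of([exp + random_seq(self.rng, 50)], "target")]
        assert find_cross_hybridizations(exp, db, "target", self.params) == []

    def test_mismatch_positions_reported_one_based(self):
        exp = random_seq(self.rng, 25)
        mutated = list(exp)
        mutated[4] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[4]]
        carrier = random_seq(self.rng, 30) + "".join(mutated) \
            + random_seq(self.rng, 30)
        db = [group_of([carrier], "other")]
        hits = find_cross_hybridizations(exp, db, "target", self.params)
        plus = [h for h in hits if h.strand == "+"]
        assert plus and plus[0].mismatch_positions == (5,)
        assert plus[0].similarity == pytest.approx(24 / 25)

    def test_matches_bruteforce_on_random_databases(self):
        params = self.params
        for trial in range(25):
            db = []
            for g in range(2):
                seqs = [random_seq(self.rng, self.rng.randint(60, 300))
                        for _ in range(2)]
                db.append(group_of(seqs, f"g{g}"))
            exp = random_seq(self.rng, 25)
            # plant near-matches with 0-5 mismatches to exercise the boundary
            host = db[0].members[0]
            planted = list(exp)
            for pos in self.rng.sample(range(25), self.rng.randint(0, 5)):
                planted[pos] = self.rng.choice("ACGT")
            host.sequence = host.sequence[:20] + "".join(planted) \
                + host.sequence[45:]
            got = {
                (h.subject_id, h.strand, h.subject_start)
                for h in find_cross_hybridizations(exp, db, None, params)
            }
            want = brute_force_hits(exp, db, None, params.specificity_threshold)
            assert got == want


class TestEvaluateProbe:
    def test_specific_probe_accepted_with_zero_hits(self):
        rng = random.Random(22)
        member = random_seq(rng, 120)
        target = group_of([member], "target")
        other = group_of([random_seq(rng, 120)], "other")
        p = probe_for(member[10:35])
        report = evaluate_probe(p, target, [target, other],
                                DesignParameters())
        assert report.status == "accepted"
        assert report.cross_hyb_count == 0
        assert report.known == {member[10:35]}

    def test_rejected_when_hits_exceed_maximum(self):
        rng = random.Random(23)
        exp = random_seq(rng, 25)
        # plant the expansion in 3 non-target sequences -> 3 hits > MaxXH=2
        carriers = [
            random_seq(rng, 20) + exp + random_seq(rng, 20) for _ in range(3)
        ]
        target = group_of([exp + random_seq(rng, 40)], "target")
        db = [target, group_of(carriers, "other")]
        params = DesignParameters(max_cross_hyb=2)
        report = evaluate_probe(probe_for(exp), target, db, params)
        assert report.cross_hyb_count >= 3
        assert report.status == "rejected_cross_hyb"
        params_ok = DesignParameters(max_cross_hyb=100)
        report2 = evaluate_probe(probe_for(exp), target, db, params_ok)
        assert report2.status == "accepted"

    def test_counts_summed_over_expansions(self):
        rng = random.Random(24)
        a = random_seq(rng, 24)
        pa, pg = "A" + a, "G" + a
        target = group_of([pa + random_seq(rng, 30)], "target")
        other = group_of(
            [random_seq(rng, 15) + pg + random_seq(rng, 15)], "other"
        )
        p = probe_for("R" + a)
        report = evaluate_probe(p, target, [target, other], DesignParameters())
        assert report.known == {pa}
        assert report.explorative == {pg}
        # the explorative expansion's non-target hit is recorded
        assert any(
            h.probe_expansion == pg for hs in report.hits.values() for h in hs
        )
        assert report.cross_hyb_count == len(
            [h for hs in report.hits.values() for h in hs]
        )

    def test_prebuilt_index_equivalent_to_group_list(self):
        rng = random.Random(25)
        db = [group_of([random_seq(rng, 150)], f"g{i}") for i in range(3)]
        exp = random_seq(rng, 25)
        params = DesignParameters()
        idx = DatabaseIndex(db, seed_length(25, params.specificity_threshold))
        direct = find_cross_hybridizations(exp, db, None, params)
        via_index = find_cross_hybridizations(exp, idx, None, params)
        assert direct == via_index
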