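"""Quality filtering, orientation, dereplication, and homogeneity screening."""

import random

import pytest

from probegrid.curation import (
    CurationCriteria,
    Disposition,
    build_database,
    dereplicate_group,
    filter_sequence,
    homogeneity_filter,
    orient_sequence,
)
from probegrid.seq_core import (
    Kingdom,
    SequenceRecord,
    TaxonGroup,
    reverse_complement,
)


def rec(seq, rid="r", taxon="Bacillus", kingdom=Kingdom.PROKARYOTE):
    return SequenceRecord(id=rid, sequence=seq, taxon=taxon, kingdom=kingdom)


def random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def mutate(rng, seq, rate):
    return "".join(
        rng.choice([b for b in "ACGT" if b != c]) if rng.random() < rate else c
        for c in seq
    )


CRIT = CurationCriteria()


class TestFilter:
    def test_length_bounds_are_strict(self):
        rng = random.Random(0)
        assert filter_sequence(rec(random_seq(rng, 1150)), CRIT) \
            == Disposition.REJECTED_LENGTH
        assert filter_sequence(rec(random_seq(rng, 1200)), CRIT) \
            == Disposition.REJECTED_LENGTH  # "greater than" is strict
        assert filter_sequence(rec(random_seq(rng, 1600)), CRIT) \
            == Disposition.REJECTED_LENGTH
        assert filter_sequence(rec(random_seq(rng, 1300)), CRIT) \
            == Disposition.KEPT
        # fungal bound is wider
        assert filter_sequence(
            rec(random_seq(rng, 1700), kingdom=Kingdom.FUNGI), CRIT
        ) == Disposition.KEPT

    def test_unknown_fraction_threshold(self):
        rng = random.Random(1)
        base = random_seq(rng, 1300)
        # 14 scattered N's: 14/1300 ~ 1.08% >= 1%
        seq = list(base)
        for i in range(0, 28, 2):
            seq[i * 40] = "N"
        assert filter_sequence(rec("".join(seq[:1300])), CRIT) \
            == Disposition.REJECTED_UNKNOWN_FRACTION
        # 12 N's: 0.92% < 1% -> kept
        seq = list(base)
        for i in range(12):
            seq[i * 100] = "N"
        assert filter_sequence(rec("".join(seq)), CRIT) == Disposition.KEPT

    def test_unknown_run_boundary(self):
        rng = random.Random(2)
        base = random_seq(rng, 1300)
        five = base[:600] + "N" * 5 + base[605:]
        six = base[:600] + "N" * 6 + base[606:]
        assert filter_sequence(rec(five), CRIT) == Disposition.KEPT
        assert filter_sequence(rec(six), CRIT) == Disposition.REJECTED_UNKNOWN_RUN

    def test_missing_taxon_and_rule_order(self):
        rng = random.Random(3)
        assert filter_sequence(rec(random_seq(rng, 1300), taxon=""), CRIT) \
            == Disposition.REJECTED_TAXON
        # length failure reported before taxon failure
        assert filter_sequence(rec(random_seq(rng, 100), taxon=""), CRIT) \
            == Disposition.REJECTED_LENGTH


class TestOrientation:
    def test_reference_itself_unchanged(self):
        ref = rec("ACGTACGTGGATTACCA" * 10, rid="ref")
        out = orient_sequence(ref, ref)
        assert out.sequence == ref.sequence and not out.reoriented

    def test_reverse_complement_is_flipped(self):
        ref = rec("ACGTACGTGGATTACCA" * 10, rid="ref")
        flipped = rec(reverse_complement(ref.sequence), rid="q")
        out = orient_sequence(flipped, ref)
        assert out.sequence == ref.sequence and out.reoriented

    def test_mutated_then_flipped_sequence_detected(self):
        rng = random.Random(4)
        ref = rec(random_seq(rng, 400), rid="ref")
        q = mutate(rng, ref.sequence, 0.05)
        out = orient_sequence(rec(reverse_complement(q), rid="q"), ref)
        assert out.reoriented and out.sequence == q

    def test_idempotent(self):
        rng = random.Random(5)
        ref = rec(random_seq(rng, 300), rid="ref")
        q = rec(reverse_complement(mutate(rng, ref.sequence, 0.03)), rid="q")
        once = orient_sequence(q, ref)
        twice = orient_sequence(once, ref)
        assert twice.sequence == once.sequence


class TestDereplication:
    def test_examples(self):
        g = TaxonGroup("t", [rec("ACGTACGT", "a"), rec("ACGTACGT", "b")])
        out, removed = dereplicate_group(g)
        assert [m.id for m in out.members] == ["a"] and removed == ["b"]
        g = TaxonGroup("t", [rec("ACGTACGT", "a"), rec("GTAC", "b")])
        out, removed = dereplicate_group(g)
        assert [m.id for m in out.members] == ["a"] and removed == ["b"]
        g = TaxonGroup("t", [rec("ACGT", "a"), rec("ACGA", "b")])
        out, removed = dereplicate_group(g)
        assert len(out.members) == 2 and not removed

    def test_longer_survives_even_when_later(self):
        g = TaxonGroup("t", [rec("GTAC", "frag"), rec("ACGTACGT", "full")])
        out, removed = dereplicate_group(g)
        assert [m.id for m in out.members] == ["full"] and removed == ["frag"]

    def test_idempotent_and_no_substring_pairs(self):
        rng = random.Random(6)
        for _ in range(30):
            seqs = [random_seq(rng, rng.randint(3, 8)) for _ in range(6)]
            # plant containment
            seqs.append(seqs[0][1:])
            g = TaxonGroup("t", [rec(s, f"s{i}") for i, s in enumerate(seqs)])
            out, _ = dereplicate_group(g)
            again, removed2 = dereplicate_group(out)
            assert removed2 == []
            members = [m.sequence for m in out.members]
            for i, a in enumerate(members):
                for j, b in enumerate(members):
                    assert i == j or a not in b


class TestHomogeneity:
    def test_identical_sequences_all_retained(self):
        g = TaxonGroup("t", [rec("ACGTACGTAC", f"s{i}") for i in range(10)])
        out, removed = homogeneity_filter(g)
        assert len(out.members) == 10 and not removed

    def test_outlier_removed(self):
        rng = random.Random(7)
        template = random_seq(rng, 300)
        seqs = [mutate(rng, template, 0.01) for _ in range(9)]
        seqs.append(mutate(rng, template, 0.35))
        g = TaxonGroup("t", [rec(s, f"s{i}") for i, s in enumerate(seqs)])
        out, removed = homogeneity_filter(g)
        assert removed == ["s9"]
        assert len(out.members) == 9

    def test_pair_below_margin_kept_above_margin_tie_keeps_first(self):
        rng = random.Random(8)
        a = random_seq(rng, 200)
        close = mutate(rng, a, 0.02)
        g = TaxonGroup("t", [rec(a, "a"), rec(close, "b")])
        out, removed = homogeneity_filter(g)
        assert not removed
        far = mutate(rng, a, 0.5)
        g = TaxonGroup("t", [rec(a, "a"), rec(far, "b")])
        out, removed = homogeneity_filter(g)
        assert [m.id for m in out.members] == ["a"] and removed == ["b"]

    def test_never_removes_more_than_half(self):
        rng = random.Random(9)
        for trial in range(5):
            t1, t2 = random_seq(rng, 150), random_seq(rng, 150)
            n1 = rng.randint(2, 5)
            n2 = rng.randint(2, 5)
            seqs = [mutate(rng, t1, 0.02) for _ in range(n1)]
            seqs += [mutate(rng, t2, 0.02) for _ in range(n2)]
            g = TaxonGroup("t", [rec(s, f"s{i}") for i, s in enumerate(seqs)])
            out, removed = homogeneity_filter(g)
            assert len(removed) <= len(seqs) / 2


class TestBuildDatabase:
    def test_counts_conserved_on_fixture(self, small_fixture, small_criteria):
        groups, report = build_database(
            small_fixture.records, small_criteria, small_fixture.reference
        )
        assert sum(report.totals().values()) == len(small_fixture.records)
        for taxon, counts in report.group_counts.items():
            n_input = sum(
                1 for r in small_fixture.records if r.taxon == taxon
            )
            assert sum(counts.values()) == n_input

    def test_empty_input_rejected(self, small_criteria):
        with pytest.raises(ValueError):
            build_database([], small_criteria, rec("ACGT" * 100, "ref"))

    def test_all_filtered_yields_no_groups(self, small_criteria):
        rng = random.Random(10)
        records = [
            rec(random_seq(rng, 50), f"short{i}") for i in range(4)
        ]
        groups, report = build_database(
            records, small_criteria, rec(random_seq(rng, 500), "ref")
        )
        assert groups == []
        assert report.totals()["rejected_length"] == 4
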