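"""Retention rules, length filter, greedy clustering, host selection."""

import random

import pytest

from virome_triage.curation import (
    HitList,
    classify_candidate,
    curate,
    first_viral_rank,
    greedy_cluster,
    length_filter,
    pairwise_identity,
    select_candidate_hosts,
)
from virome_triage.io_formats import (
    DomainAnnotation,
    NucleotideSequence,
    TabularHit,
    ViralSubjectSet,
)


def make_hit(sseqid, bitscore=100.0, evalue=1e-10, qseqid="q1", pident=80.0):
    return TabularHit(
        qseqid=qseqid,
        sseqid=sseqid,
        pident=pident,
        aln_length=100,
        mismatch=5,
        gapopen=0,
        qstart=1,
        qend=100,
        sstart=1,
        send=100,
        evalue=evalue,
        bitscore=bitscore,
    )


VIRAL = ViralSubjectSet(members=frozenset({"virus_a", "virus_b"}))


class TestFirstViralRank:
    def test_rank_of_first_viral_hit(self):
        hits = [make_hit("x", 300), make_hit("virus_a", 200), make_hit("y", 100)]
        hl = HitList(qseqid="q1", hits=hits)
        assert first_viral_rank(hl, VIRAL, depth=30) == 2

    def test_viral_hit_beyond_depth_is_absent(self):
        hits = [make_hit(f"s{i}", 300 - i) for i in range(30)]
        hits.append(make_hit("virus_a", 1.0))  # rank 31
        hl = HitList(qseqid="q1", hits=hits + [make_hit(f"t{i}", 0.5) for i in range(4)])
        assert first_viral_rank(hl, VIRAL, depth=30) is None

    def test_viral_hit_exactly_at_depth_boundary(self):
        hits = [make_hit(f"s{i}", 300 - i) for i in range(9)]
        hits.append(make_hit("virus_a", 1.0))
        hl = HitList(qseqid="q1", hits=hits)
        assert first_viral_rank(hl, VIRAL, depth=10) == 10

    def test_empty_hit_list_is_absent(self):
        assert first_viral_rank(HitList(qseqid="q", hits=[]), VIRAL) is None

    def test_bitscore_ordering_overrides_file_order(self):
        hits = [make_hit("x", 50), make_hit("virus_a", 200)]
        assert first_viral_rank(HitList(qseqid="q", hits=hits), VIRAL) == 1
        assert (
            first_viral_rank(
                HitList(qseqid="q", hits=hits, order_policy="file_order"), VIRAL
            )
            == 2
        )

    def test_bitscore_ties_broken_by_evalue_then_input_order(self):
        hits = [
            make_hit("x", 100, evalue=1e-5),
            make_hit("virus_a", 100, evalue=1e-9),
        ]
        assert first_viral_rank(HitList(qseqid="q", hits=hits), VIRAL) == 1


class TestClassifyCandidate:
    @pytest.mark.parametrize(
        "rank,domain,expected",
        [
            (25, True, "retained_domain_rule"),
            (25, False, "excluded"),
            (8, False, "retained_top10_rule"),
            (None, True, "excluded"),
            (None, False, "excluded"),
            (10, False, "retained_top10_rule"),
            (11, False, "excluded"),
            (1, True, "retained_domain_rule"),
        ],
    )
    def test_worked_examples(self, rank, domain, expected):
        assert classify_candidate(rank, domain) == expected

    def test_exhaustive_truth_table(self):
        """Retained iff (rank present AND domain) OR (rank <= 10 AND no domain)."""
        for rank in [None, *range(1, 31)]:
            for domain in (True, False):
                verdict = classify_candidate(rank, domain)
                if rank is not None and domain:
                    assert verdict == "retained_domain_rule"
                elif rank is not None and rank <= 10 and not domain:
                    assert verdict == "retained_top10_rule"
                else:
                    assert verdict == "excluded"

    def test_rank_outside_window_is_argument_error(self):
        with pytest.raises(ValueError):
            classify_candidate(31, True)
        with pytest.raises(ValueError):
            classify_candidate(0, False)

    def test_curate_joins_hits_and_domains(self):
        hits = {
            "q1": [make_hit("virus_a", 200, qseqid="q1"), make_hit("x", 100, qseqid="q1")],
            "q2": [make_hit("y", 200, qseqid="q2")],
        }
        domains = [DomainAnnotation("q1", "cl40470", True)]
        decisions = {d.qseqid: d for d in curate(hits, VIRAL, domains)}
        assert decisions["q1"].verdict == "retained_domain_rule"
        assert decisions["q1"].first_viral_rank == 1
        assert decisions["q2"].verdict == "excluded"


class TestLengthFilter:
    def test_longer_than_500_is_strict(self):
        seqs = [
            NucleotideSequence(id=f"s{n}", residues="A" * n) for n in (400, 500, 501)
        ]
        assert [s.id for s in length_filter(seqs)] == ["s501"]

    def test_empty_input(self):
        assert length_filter([]) == []

    def test_zero_threshold_is_identity(self):
        seqs = [NucleotideSequence(id="a", residues="A")]
        assert length_filter(seqs, min_exclusive=0) == seqs


def mutate(template, rate, rng):
    bases = "ACGT"
    return "".join(
        rng.choice([b for b in bases if b != ch]) if rng.random() < rate else ch
        for ch in template
    )


class TestGreedyCluster:
    def test_identical_sequences_form_one_cluster(self):
        seqs = [
            NucleotideSequence(id="b", residues="ACGT" * 30),
            NucleotideSequence(id="a", residues="ACGT" * 30),
        ]
        (cluster,) = greedy_cluster(seqs)
        assert cluster.representative_id == "a"  # tie broken by id
        assert sorted(cluster.member_ids) == ["a", "b"]

    def test_unrelated_sequences_stay_apart(self):
        rng = random.Random(3)
        seqs = [
            NucleotideSequence(
                id=f"s{i}", residues="".join(rng.choice("ACGT") for _ in range(200))
            )
            for i in range(2)
        ]
        assert len(greedy_cluster(seqs)) == 2

    def test_empty_input(self):
        assert greedy_cluster([]) == []

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            greedy_cluster([], identity_threshold=0.0)

    def test_template_recovery_matches_all_pairs_identity_oracle(self):
        """4 templates x 5 mutated copies at 3% substitutions recover 4 clusters."""
        rng = random.Random(90210)
        templates = [
            "".join(rng.choice("ACGT") for _ in range(300)) for _ in range(4)
        ]
        seqs, labels = [], {}
        for t, template in enumerate(templates):
            for c in range(5):
                sid = f"t{t}c{c}"
                seqs.append(
                    NucleotideSequence(id=sid, residues=mutate(template, 0.03, rng))
                )
                labels[sid] = t
        # oracle: the all-pairs identity structure separates the templates
        for a in seqs:
            for b in seqs:
                if a.id >= b.id:
                    continue
                ident = pairwise_identity(a.residues, b.residues)
                if labels[a.id] == labels[b.id]:
                    assert ident >= 0.90
                else:
                    assert ident < 0.90
        clusters = greedy_cluster(seqs, identity_threshold=0.90)
        assert len(clusters) == 4
        partition = {frozenset(c.member_ids) for c in clusters}
        expected = {
            frozenset(s.id for s in seqs if labels[s.id] == t) for t in range(4)
        }
        assert partition == expected

    def test_output_partitions_input(self, random_sequences):
        seqs = random_sequences(12, 100, 400)
        clusters = greedy_cluster(seqs)
        members = [m for c in clusters for m in c.member_ids]
        assert sorted(members) == sorted(s.id for s in seqs)

    def test_representative_is_longest_member(self):
        long = NucleotideSequence(id="long", residues="ACGTACGT" * 30)
        short = NucleotideSequence(id="short", residues="ACGTACGT" * 28)
        (cluster,) = greedy_cluster([short, long])
        assert cluster.representative_id == "long"

    def test_deterministic_given_sort_order(self, random_sequences):
        seqs = random_sequences(10, 100, 300)
        a = greedy_cluster(seqs)
        b = greedy_cluster(list(reversed(seqs)))
        assert [c.member_ids for c in a] == [c.member_ids for c in b]


class TestSelectCandidateHosts:
    def test_over_90_percent_is_strict(self):
        hits = {
            "q1": [
                make_hit("fungus_a", pident=89.9),
                make_hit("fungus_b", pident=90.0),
                make_hit("fungus_c", pident=90.1),
            ]
        }
        assert select_candidate_hosts(hits) == {"fungus_c"}

    def test_empty_mapping(self):
        assert select_candidate_hosts({}) == set()

    def test_subject_appears_once_despite_multiple_queries(self):
        hits = {
            "q1": [make_hit("fungus_a", pident=95.0, qseqid="q1")],
            "q2": [make_hit("fungus_a", pident=96.0, qseqid="q2")],
        }
        assert select_candidate_hosts(hits) == {"fungus_a"}

    def test_intersection_with_mitochondrial_availability(self):
        hits = {
            "q1": [
                make_hit("with_mito", pident=95.0),
                make_hit("no_mito", pident=95.0),
            ]
        }
        assert select_candidate_hosts(hits, allowed_subjects={"with_mito"}) == {
            "with_mito"
        }
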