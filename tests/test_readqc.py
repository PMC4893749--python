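"""Read QC rules: truncation, EE, merging, dereplication, clustering."""

import numpy as np
import pytest

from cagflow import readqc, simulate
from cagflow.readqc import (
    FastqRead,
    UniqueSeq,
    cluster_otus,
    dereplicate,
    expected_error,
    global_identity,
    map_reads,
    merge_pair,
    qc_filter_reads,
    truncate_at_quality,
)


def read(bases, quals, rid="r"):
    return FastqRead(id=rid, bases=bases, quals=np.asarray(quals))


def mutate(seq: str, positions, rng=None) -> str:
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestTruncation:
    @pytest.mark.parametrize(
        "quals, expected_len",
        [([30, 30, 2, 30], 2), ([40, 40, 40], 3), ([2, 30, 30], 0)],
    )
    def test_truncates_before_first_low_q_base(self, quals, expected_len):
        r = read("ACGT"[: len(quals)], quals)
        assert len(truncate_at_quality(r)) == expected_len

    def test_qmax_is_inclusive(self):
        r = read("ACG", [3, 3, 3])
        assert len(truncate_at_quality(r, qmax=3)) == 0


class TestExpectedError:
    @pytest.mark.parametrize(
        "quals, ee",
        [([20] * 400, 4.0), ([30] * 50, 0.05), ([], 0.0)],
    )
    def test_phred_sum(self, quals, ee):
        assert expected_error(quals) == pytest.approx(ee)

    def test_negative_q_rejected(self):
        with pytest.raises(ValueError):
            expected_error([-1, 30])


class TestMergePair:
    @pytest.fixture()
    def template(self):
        return simulate.make_otu_sequences(1, 500, seed=9)["OTU001"]

    def make_pair(self, template, read_len, q=35):
        fwd = read(template[:read_len], [q] * read_len, "p")
        rev_frag = readqc.reverse_complement(template[-read_len:])
        rev = read(rev_frag, [q] * read_len, "p")
        return fwd, rev

    def test_exact_overlap_merges_to_template(self, template):
        fwd, rev = self.make_pair(template, 300)  # true overlap 100
        merged = merge_pair(fwd, rev)
        assert merged is not None
        assert merged.bases == template
        assert merged.overlap_len == 100

    def test_overlap_of_49_fails(self, template):
        # reads of length (500+49)//... choose len so 2L-500 = 49
        fwd, rev = self.make_pair(template[:499], 274)  # 2*274-499=49
        assert merge_pair(fwd, rev) is None

    def test_high_mismatch_overlap_fails(self, template):
        fwd, rev = self.make_pair(template, 300)
        # corrupt 20 of the 100 overlap positions on the forward read
        bad = mutate(fwd.bases, range(200, 220))
        fwd_bad = read(bad, fwd.quals, "p")
        assert merge_pair(fwd_bad, rev) is None

    def test_higher_quality_base_wins_in_overlap(self, template):
        fwd, rev = self.make_pair(template, 300)
        # plant one error in the forward overlap with low Q: rev must win
        bad = mutate(fwd.bases, [250])
        quals = np.full(300, 35)
        quals[250] = 10
        merged = merge_pair(read(bad, quals, "p"), rev)
        assert merged.bases == template
        assert merged.quals[250] == 35

    def test_tie_keeps_forward_base(self, template):
        fwd, rev = self.make_pair(template, 300)
        bad = mutate(fwd.bases, [250])
        merged = merge_pair(read(bad, fwd.quals, "p"), rev)
        assert merged.bases[250] == bad[250]

    def test_empty_read_returns_none(self, template):
        fwd, rev = self.make_pair(template, 300)
        empty = read("", [])
        assert merge_pair(empty, rev) is None


class TestFilter:
    @pytest.mark.parametrize(
        "length, kept",
        [(399, False), (400, True), (450, True)],  # "longer than 399 bp"
    )
    def test_length_rule(self, length, kept):
        r = readqc.MergedRead("m", "A" * length, np.full(length, 40), 60)
        assert bool(qc_filter_reads([r])) is kept

    def test_ee_boundary_inclusive(self):
        # "no more than 0.5" keeps a read whose EE equals the cutoff and
        # drops one epsilon above it
        quals = np.r_[np.full(50, 20), np.full(350, 90)]
        ee = expected_error(quals)  # ~0.5 + 350 * 1e-9
        r = readqc.MergedRead("m", "A" * 400, quals, 60)
        assert qc_filter_reads([r], max_ee=ee) == [r]
        assert qc_filter_reads([r], max_ee=ee - 1e-9) == []

    def test_filter_is_order_stable_and_idempotent(self):
        rng = np.random.default_rng(0)
        reads = [
            readqc.MergedRead(
                f"m{i}",
                "A" * 420,
                rng.integers(15, 41, size=420),
                60,
            )
            for i in range(30)
        ]
        once = qc_filter_reads(reads)
        twice = qc_filter_reads(once)
        assert [r.id for r in once] == [r.id for r in twice]


class TestDereplicate:
    def test_singletons_discarded(self):
        out = dereplicate(["AAA", "AAA", "CCC"])
        assert [(u.sequence, u.size) for u in out] == [("AAA", 2)]

    def test_empty_input(self):
        assert dereplicate([]) == []

    def test_sorted_by_size_then_sequence(self):
        reads = ["TTT"] * 3 + ["AAA"] * 3 + ["GGG"] * 2
        out = dereplicate(reads)
        assert [(u.sequence, u.size) for u in out] == [
            ("AAA", 3),
            ("TTT", 3),
            ("GGG", 2),
        ]


class TestClusterAndMap:
    @pytest.fixture()
    def base_seq(self):
        return simulate.make_otu_sequences(1, 100, seed=5)["OTU001"]

    def test_two_mismatches_join_one_centroid(self, base_seq):
        # identity 98/100 >= 0.97
        variant = mutate(base_seq, [10, 50])
        assert global_identity(base_seq, variant) == pytest.approx(0.98)
        out = cluster_otus(
            [UniqueSeq(base_seq, 10), UniqueSeq(variant, 5)]
        )
        assert len(out) == 1 and out[0].size == 15

    def test_five_mismatches_make_two_centroids(self, base_seq):
        variant = mutate(base_seq, [10, 30, 50, 70, 90])
        assert global_identity(base_seq, variant) == pytest.approx(0.95)
        out = cluster_otus(
            [UniqueSeq(base_seq, 10), UniqueSeq(variant, 5)]
        )
        assert len(out) == 2

    def test_single_input_is_its_own_centroid(self, base_seq):
        out = cluster_otus([UniqueSeq(base_seq, 4)])
        assert out[0].sequence == base_seq

    def test_identity_one_keeps_every_unique(self):
        seqs = simulate.make_otu_sequences(6, 100, seed=2)
        uniques = [UniqueSeq(s, 2) for s in seqs.values()]
        assert len(cluster_otus(uniques, identity=1.0)) == 6

    def test_exact_read_counted_at_its_centroid(self, base_seq):
        table = map_reads([base_seq], [UniqueSeq(base_seq, 10)], sample_id="s")
        assert int(table.counts.iloc[0, 0]) == 1

    def test_distant_read_dropped(self, base_seq):
        far = mutate(base_seq, range(0, 10))  # 90% identity
        table = map_reads([far], [UniqueSeq(base_seq, 10)], sample_id="s")
        assert int(table.counts.sum().sum()) == 0

    def test_identity_tie_goes_to_more_abundant_centroid(self, base_seq):
        # two centroids each 2 mismatches from the read, sizes 3 vs 9
        c1 = mutate(base_seq, [10, 20])
        c2 = mutate(base_seq, [60, 70])
        table = map_reads(
            [base_seq],
            [UniqueSeq(c1, 3), UniqueSeq(c2, 9)],
            sample_id="s",
        )
        assert table.counts.iloc[0].tolist() == [0, 1]

    def test_mapping_never_exceeds_input_reads(self, base_seq):
        rng = np.random.default_rng(3)
        reads = [
            mutate(base_seq, rng.choice(100, size=rng.integers(0, 8), replace=False))
            for _ in range(40)
        ]
        table = map_reads(reads, [UniqueSeq(base_seq, 10)], sample_id="s")
        assert int(table.counts.sum().sum()) <= 40


class TestPipelineConcordance:
    def test_decisions_match_generator_expectations(self):
        templates = simulate.make_otu_sequences(3, 440, seed=3)
        qf = np.r_[np.full(220, 35), np.full(30, 20)]
        qr = np.r_[np.full(210, 33), np.full(40, 18)]
        qm = simulate.QualityModel(fwd=qf, rev=qr)
        fwd, rev, expected = simulate.simulate_paired_reads(
            templates, {k: 60 for k in templates}, qm, seed=11
        )
        _, decisions = readqc.process_pairs(fwd, rev)
        assert all(decisions[k] == expected[k] for k in expected)
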