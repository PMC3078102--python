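import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relhom.datasets import (
    FastaParseError,
    HomologyDataset,
    ProteinSequence,
    compute_T,
    filter_by_identity,
    make_family_split,
    pairwise_identity,
    read_fasta,
    read_manifest,
    sample_negatives,
)


@pytest.fixture
def dataset(toy_sequences):
    return HomologyDataset(toy_sequences)


class TestReadFasta:
    def test_two_records(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nVCK\n>s2\nACD\n")
        seqs = read_fasta(p)
        assert len(seqs) == 2
        assert seqs[0].id == "s1" and seqs[0].residues == "VCK"

    def test_lowercase_canonicalized(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nvck\n")
        assert read_fasta(p)[0].residues == "VCK"

    def test_nonstandard_residue_kept_in_length(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nAXC\n")
        assert len(read_fasta(p)[0]) == 3

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(FastaParseError):
            read_fasta(p)

    def test_bad_letters_name_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">good\nACD\n>bad\nAC1\n")
        with pytest.raises(FastaParseError, match="bad"):
            read_fasta(p)

    def test_order_preserved(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">z\nAA\n>a\nCC\n")
        assert [s.id for s in read_fasta(p)] == ["z", "a"]


class TestManifest:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("s1\tfamA\tsfX\ns2\tfamB\tsfX\n")
        m = read_manifest(p)
        assert m == {"s1": ("famA", "sfX"), "s2": ("famB", "sfX")}

    def test_bad_field_count(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("s1\tfamA\n")
        with pytest.raises(ValueError, match="3 tab-separated"):
            read_manifest(p)


class TestComputeT:
    def test_spec_example(self):
        assert compute_T(100, 10, 10) == 4

    def test_small_remainder(self):
        assert compute_T(21, 10, 10) == 1

    def test_exactly_one_draw(self):
        assert compute_T(40, 10, 10) == 1

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError):
            compute_T(20, 10, 10)

    @given(
        D=st.integers(30, 500),
        tr=st.integers(1, 10),
        te=st.integers(1, 10),
        delta=st.integers(1, 5),
    )
    def test_monotone_in_positive_size(self, D, tr, te, delta):
        if D <= tr + te + delta:
            return
        assert compute_T(D, tr + delta, te) <= compute_T(D, tr, te)


class TestFamilySplit:
    def test_partition(self, dataset):
        split = make_family_split(dataset, "famA")
        assert set(split.positive_test) == {"s1", "s2"}
        assert set(split.positive_train) == {"s3"}
        assert set(split.remaining_pool) == {"s4", "s5"}
        total = len(split.positive_test) + len(split.positive_train) + len(split.remaining_pool)
        assert total == len(dataset)

    def test_unknown_family(self, dataset):
        with pytest.raises(KeyError):
            make_family_split(dataset, "nope")

    def test_degenerate_family(self, toy_sequences):
        solo = HomologyDataset(
            toy_sequences[:3]
            + [ProteinSequence("s6", "KKKKK", family="famD", superfamily="sfZ")]
            + toy_sequences[3:]
        )
        with pytest.raises(ValueError, match="degenerate"):
            make_family_split(solo, "famD")


class TestSampleNegatives:
    @pytest.fixture
    def big_split(self):
        from relhom.datasets import FamilySplit

        pool = tuple(f"n{i}" for i in range(100))
        return FamilySplit(
            target_family="f",
            positive_test=("p1", "p2", "p3"),
            positive_train=("q1", "q2"),
            remaining_pool=pool,
            T=4,
        )

    def test_deterministic(self, big_split):
        a = sample_negatives(big_split, 1, seed=42)
        b = sample_negatives(big_split, 1, seed=42)
        assert a == b

    def test_runs_differ(self, big_split):
        a = sample_negatives(big_split, 1, seed=42)
        b = sample_negatives(big_split, 2, seed=42)
        assert a.negative_train != b.negative_train or a.negative_test != b.negative_test

    def test_balanced_and_disjoint(self, big_split):
        r = sample_negatives(big_split, 1, seed=0)
        assert len(r.negative_train) == 2
        assert len(r.negative_test) == 3
        assert not set(r.negative_train) & set(r.negative_test)
        assert set(r.negative_train) <= set(big_split.remaining_pool)

    def test_pool_too_small(self):
        from relhom.datasets import FamilySplit

        split = FamilySplit(
            target_family="f",
            positive_test=("p1", "p2"),
            positive_train=("q1", "q2"),
            remaining_pool=("n1", "n2", "n3"),
            T=1,
        )
        with pytest.raises(ValueError):
            sample_negatives(split, 1, seed=0)

    def test_expected_pool_coverage(self, big_split):
        # T ≈ pool/draw draws should cover ≥ 1 - 1/e of the pool.
        draw = len(big_split.positive_train) + len(big_split.positive_test)
        T = math.ceil(len(big_split.remaining_pool) / draw)
        seen = set()
        for t in range(1, T + 1):
            r = sample_negatives(big_split, t, seed=7)
            seen |= set(r.negative_train) | set(r.negative_test)
        assert len(seen) >= (1 - 1 / math.e) * len(big_split.remaining_pool)


class TestPairwiseIdentity:
    def test_identical(self):
        a = ProteinSequence("a", "ACDEFGHIKL")
        b = ProteinSequence("b", "ACDEFGHIKL")
        assert pairwise_identity(a, b) == pytest.approx(100.0)

    def test_disjoint(self):
        a = ProteinSequence("a", "AAAA")
        b = ProteinSequence("b", "CCCC")
        assert pairwise_identity(a, b) == pytest.approx(0.0)

    def test_symmetric(self):
        a = ProteinSequence("a", "ACDEWKL")
        b = ProteinSequence("b", "ACDKKLW")
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_in_range(self):
        rng = np.random.default_rng(0)
        letters = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(5):
            a = ProteinSequence("a", "".join(rng.choice(list(letters), 30)))
            b = ProteinSequence("b", "".join(rng.choice(list(letters), 25)))
            assert 0 <= pairwise_identity(a, b) <= 100


class TestFilterByIdentity:
    def test_identical_collapse(self):
        seqs = [
            ProteinSequence(f"s{i}", "ACDEFGHIKL", family="f", superfamily="sf")
            for i in range(3)
        ]
        ds = HomologyDataset(seqs)
        out = filter_by_identity(ds, 30)
        # one survivor, then dropped because its family has < 2 members
        assert len(out) == 0

    def test_all_below_threshold_unchanged(self):
        seqs = [
            ProteinSequence("a", "AAAAAAAAAA", family="f", superfamily="sf"),
            ProteinSequence("b", "CCCCCCCCCC", family="f", superfamily="sf"),
        ]
        ds = HomologyDataset(seqs)
        out = filter_by_identity(ds, 30)
        assert {s.id for s in out} == {"a", "b"}

    def test_output_pairs_below_threshold(self):
        rng = np.random.default_rng(5)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        base = "".join(rng.choice(letters, 20))
        seqs = []
        for i in range(8):
            s = list(base)
            for j in range(20):
                if rng.random() < 0.4:
                    s[j] = letters[rng.integers(20)]
            seqs.append(ProteinSequence(f"s{i}", "".join(s), family="f", superfamily="sf"))
        out = filter_by_identity(HomologyDataset(seqs), 60)
        kept = list(out)
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                assert pairwise_identity(kept[i], kept[j]) < 60

    def test_bad_threshold(self, toy_sequences):
        with pytest.raises(ValueError):
            filter_by_identity(HomologyDataset(toy_sequences), 0)


class TestProteinSequence:
    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ProteinSequence("x", "")

    def test_duplicate_ids_rejected(self):
        seqs = [
            ProteinSequence("a", "AC", family="f", superfamily="sf"),
            ProteinSequence("a", "CD", family="f", superfamily="sf"),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            HomologyDataset(seqs)
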