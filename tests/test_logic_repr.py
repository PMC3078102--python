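import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from relhom.datasets import ProteinSequence
from relhom.logic_repr import (
    ALN_CONS,
    ALN_PC,
    PROPERTY_GROUPS,
    SEQ,
    GroundAtom,
    KnowledgeBase,
    alignment_atoms_query,
    alignment_atoms_train,
    bin_percentage,
    build_kb,
    parse_atom,
    physchem_column_atoms,
    sequential_atoms,
)
from relhom.profile_hmm import Alignment, build_phmm


class TestPropertyGroups:
    def test_sixteen_groups(self):
        assert len(PROPERTY_GROUPS) == 16

    def test_exact_memberships(self):
        assert PROPERTY_GROUPS["small"] == set("AGST")
        assert PROPERTY_GROUPS["tiny"] == set("AG")
        assert PROPERTY_GROUPS["hydrophobic"] == set("ILMV")
        # unusual but verbatim membership
        assert PROPERTY_GROUPS["charged"] == set("DEHIKLRV")
        assert PROPERTY_GROUPS["polar"] == set("DEHKNQRSTWY")
        assert PROPERTY_GROUPS["bulky"] == set("FHRWY")

    def test_tiny_subset_of_small(self):
        assert PROPERTY_GROUPS["tiny"] <= PROPERTY_GROUPS["small"]


class TestBinPercentage:
    def test_boundaries(self):
        assert bin_percentage(0) == 1
        assert bin_percentage(100) == 11

    def test_between_10_and_20(self):
        # bin 2 means "between 10 and 20%"
        assert bin_percentage(15) == 2

    def test_formula_all_integers(self):
        for y in range(101):
            assert bin_percentage(y) == y // 10 + 1

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            bin_percentage(-1)
        with pytest.raises(ValueError):
            bin_percentage(100.5)

    @given(st.floats(min_value=0, max_value=100, allow_nan=False))
    def test_range(self, y):
        assert 1 <= bin_percentage(y) <= 11


class TestSequentialAtoms:
    def test_all_hydrophobic(self):
        atoms = sequential_atoms(ProteinSequence("s", "IIII"))
        assert GroundAtom("hydrophobic", ("s", 11)) in atoms
        assert GroundAtom("aminoacidRatio", ("s", "i", 11)) in atoms

    def test_tiny_and_small_both_full(self):
        atoms = sequential_atoms(ProteinSequence("s", "AG"))
        assert GroundAtom("tiny", ("s", 11)) in atoms
        assert GroundAtom("small", ("s", 11)) in atoms

    def test_pair_ratio_constant_lowercase(self):
        atoms = sequential_atoms(ProteinSequence("s", "ACGCG"))
        pairs = {a for a in atoms if a.predicate == "aminoacidPairRatio"}
        assert any(a.args[1] == "cg" for a in pairs)

    def test_one_atom_per_group(self):
        atoms = sequential_atoms(ProteinSequence("s", "ACDEFGHIKLMNPQRSTVWY"))
        for group in PROPERTY_GROUPS:
            assert sum(1 for a in atoms if a.predicate == group) == 1

    def test_nonstandard_excluded_from_counts(self):
        # X counts toward length but not toward any group numerator.
        with_x = sequential_atoms(ProteinSequence("s", "AAXX"))
        tiny = next(a for a in with_x if a.predicate == "tiny")
        assert tiny.args[1] == bin_percentage(50.0)
        ratios = {a.args[1] for a in with_x if a.predicate == "aminoacidRatio"}
        assert ratios == {"a"}

    def test_shuffle_invariance(self):
        rng = np.random.default_rng(0)
        residues = "ACDEFGHIKLMNPQRSTVWYAAC"
        shuffled = "".join(rng.permutation(list(residues)))
        a1 = {
            (a.predicate, a.args[1:])
            for a in sequential_atoms(ProteinSequence("s", residues))
            if a.predicate in PROPERTY_GROUPS or a.predicate == "aminoacidRatio"
        }
        a2 = {
            (a.predicate, a.args[1:])
            for a in sequential_atoms(ProteinSequence("s", shuffled))
            if a.predicate in PROPERTY_GROUPS or a.predicate == "aminoacidRatio"
        }
        assert a1 == a2

    def test_counts_recompute_exactly(self):
        seq = ProteinSequence("s", "ACDEFAAGG")
        atoms = sequential_atoms(seq)
        n = len(seq.residues)
        for group, members in PROPERTY_GROUPS.items():
            count = sum(1 for r in seq.residues if r in members)
            expected = bin_percentage(100.0 * count / n)
            atom = next(a for a in atoms if a.predicate == group)
            assert atom.args[1] == expected


class TestAlignmentAtoms:
    def test_train_atoms(self):
        aln = Alignment({"s1": "VC", "s2": "-C"})
        atoms = alignment_atoms_train(aln)
        assert GroundAtom("col", ("s1", "v", 1)) in atoms
        assert GroundAtom("col", ("s1", "c", 2)) in atoms
        assert GroundAtom("col", ("s2", "c", 2)) in atoms
        assert len(atoms) == 3  # one per non-gap cell

    def test_query_projection_conserved(self):
        rows = {f"s{i}": "ACDEFGHIKL" for i in range(5)}
        phmm = build_phmm(Alignment(rows))
        query = ProteinSequence("q", "ACDEFGHIKL")
        atoms = alignment_atoms_query(phmm, query)
        assert atoms == {
            GroundAtom("col", ("q", ch.lower(), i + 1))
            for i, ch in enumerate("ACDEFGHIKL")
        }

    def test_query_atoms_bounded_by_nodes(self):
        rows = {f"s{i}": "ACDEF" for i in range(3)}
        phmm = build_phmm(Alignment(rows))
        query = ProteinSequence("q", "ACDEFWWWWWW")
        atoms = alignment_atoms_query(phmm, query)
        assert len(atoms) <= phmm.n_nodes


class TestPhyschemColumnAtoms:
    def test_a_in_small_and_tiny(self):
        derived = physchem_column_atoms({GroundAtom("col", ("s1", "a", 34))})
        assert GroundAtom("colProp", ("s1", "small", 34)) in derived
        assert GroundAtom("colProp", ("s1", "tiny", 34)) in derived

    def test_i_hydrophobic_not_small(self):
        derived = physchem_column_atoms({GroundAtom("col", ("s1", "i", 7))})
        assert GroundAtom("colProp", ("s1", "hydrophobic", 7)) in derived
        assert GroundAtom("colProp", ("s1", "small", 7)) not in derived

    def test_output_size_is_membership_sum(self):
        atoms = {
            GroundAtom("col", ("s1", "a", 1)),
            GroundAtom("col", ("s1", "w", 2)),
        }
        derived = physchem_column_atoms(atoms)
        expected = sum(
            1
            for a in atoms
            for members in PROPERTY_GROUPS.values()
            if str(a.args[1]).upper() in members
        )
        assert len(derived) == expected

    def test_non_col_rejected(self):
        with pytest.raises(ValueError):
            physchem_column_atoms({GroundAtom("tiny", ("s1", 3))})

    def test_image_matches_independent_recomputation(self):
        rng = np.random.default_rng(4)
        letters = "ACDEFGHIKLMNPQRSTVWY"
        atoms = {
            GroundAtom("col", (f"s{rng.integers(3)}", letters[rng.integers(20)].lower(), int(rng.integers(1, 20))))
            for _ in range(30)
        }
        derived = physchem_column_atoms(atoms)
        recomputed = set()
        for a in atoms:
            for g, members in PROPERTY_GROUPS.items():
                if str(a.args[1]).upper() in members:
                    recomputed.add(GroundAtom("colProp", (a.args[0], g, a.args[2])))
        assert derived == recomputed


class TestBuildKb:
    @pytest.fixture
    def setup(self):
        rows = {f"s{i}": "ACDEFGHIKL" for i in range(3)}
        aln = Alignment(rows)
        phmm = build_phmm(aln)
        train = [
            ProteinSequence(f"s{i}", "ACDEFGHIKL", family="f", superfamily="sf")
            for i in range(3)
        ]
        query = [ProteinSequence("q", "ACDEFGHIKL", family="g", superfamily="sg")]
        return aln, phmm, train, query

    def test_seq_only_has_no_col(self, setup):
        _, _, train, _ = setup
        kb = build_kb(train, {SEQ})
        assert not any(a.predicate in ("col", "colProp") for a in kb.atoms)

    def test_union_of_representations(self, setup):
        aln, phmm, train, _ = setup
        kb_all = build_kb(train, {SEQ, ALN_CONS, ALN_PC}, phmm=phmm, alignment=aln)
        expected = set()
        for s in train:
            expected |= sequential_atoms(s)
        col = alignment_atoms_train(aln)
        expected |= col | physchem_column_atoms(col)
        assert kb_all.atoms == expected

    def test_missing_alignment_errors(self, setup):
        _, _, train, _ = setup
        with pytest.raises(ValueError):
            build_kb(train, {ALN_CONS})

    def test_query_goes_through_phmm(self, setup):
        aln, phmm, _, query = setup
        kb = build_kb(query, {ALN_CONS}, phmm=phmm, alignment=aln)
        assert any(a.predicate == "col" and a.seq_id == "q" for a in kb.atoms)

    def test_deterministic(self, setup):
        aln, phmm, train, query = setup
        kb1 = build_kb(train + query, {SEQ, ALN_CONS, ALN_PC}, phmm=phmm, alignment=aln)
        kb2 = build_kb(train + query, {SEQ, ALN_CONS, ALN_PC}, phmm=phmm, alignment=aln)
        assert kb1.atoms == kb2.atoms

    def test_unknown_representation(self, setup):
        _, _, train, _ = setup
        with pytest.raises(ValueError, match="unknown"):
            build_kb(train, {"Nope"})


class TestKbSerialization:
    def test_atom_text_round_trip(self):
        atom = GroundAtom("col", ("s1", "v", 1))
        assert str(atom) == "col(s1,v,1)."
        assert parse_atom(str(atom)) == atom

    def test_kb_round_trip(self, toy_kb):
        text = toy_kb.to_text()
        back = KnowledgeBase.from_text(text)
        assert back.atoms == toy_kb.atoms
        assert back.examples == toy_kb.examples
        assert back.labels == toy_kb.labels

    def test_orphan_atoms_rejected(self):
        with pytest.raises(ValueError, match="unknown examples"):
            KnowledgeBase(
                atoms={GroundAtom("col", ("ghost", "v", 1))}, examples={"e1"}
            )
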