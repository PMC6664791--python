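import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irescan.errors import DegenerateInputError, EngineError
from irescan.kmer import BASES
from irescan.sequence_io import RnaSequence
from irescan.structure import (
    MIN_HAIRPIN_LOOP,
    BaselineEngine,
    FoldResult,
    QmfeResult,
    StubEngine,
    dinucleotide_shuffle,
    fold,
    get_engine,
    pair_score,
    qmfe,
    structural_feature_vector,
    triplet_features,
    triplet_names,
)

from conftest import random_rna

rna_text = st.text(alphabet="ACGU", min_size=1, max_size=40)


class ScriptedEngine:
    """Returns pmfe values from a list, in call order (test-only)."""

    name = "scripted"

    def __init__(self, pmfes):
        self._pmfes = list(pmfes)
        self._i = 0

    def fold(self, seq):
        pmfe = self._pmfes[self._i]
        self._i += 1
        return FoldResult("." * seq.length, pmfe, engine=self.name)


# --- independent oracle: enumerate every nested structure -----------------


def all_pairings(lo, hi):
    """All pseudoknot-free pair sets on [lo, hi] with min hairpin loop."""
    if lo >= hi:
        yield frozenset()
        return
    # position lo unpaired
    for rest in all_pairings(lo + 1, hi):
        yield rest
    # lo paired with j
    for j in range(lo + MIN_HAIRPIN_LOOP + 1, hi + 1):
        for inner in all_pairings(lo + 1, j - 1):
            for outer in all_pairings(j + 1, hi):
                yield inner | outer | {(lo, j)}


def brute_force_best(seq: str) -> float:
    best = 0.0
    for pairing in all_pairings(0, len(seq) - 1):
        score = sum(pair_score(seq[i], seq[j]) for i, j in pairing)
        if any(pair_score(seq[i], seq[j]) == 0 for i, j in pairing):
            continue
        best = max(best, score)
    return best


class TestFoldResult:
    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError):
            FoldResult("(((..", -1.0)
        with pytest.raises(ValueError):
            FoldResult("..)..(", -1.0)

    def test_invalid_char_rejected(self):
        with pytest.raises(ValueError):
            FoldResult("..x..", -1.0)


class TestBaselineEngine:
    def test_unpairable_homopolymer(self):
        r = BaselineEngine().fold(RnaSequence("x", "AAAA"))
        assert r.structure == "...."
        assert r.pmfe == 0.0

    def test_stub_contract(self):
        stub = StubEngine({"GGGAAACCC": ("(((...)))", -1.0)})
        r = stub.fold(RnaSequence("x", "GGGAAACCC"))
        assert (r.structure, r.pmfe) == ("(((...)))", -1.0)

    def test_stub_unknown_sequence_errors(self):
        with pytest.raises(EngineError):
            StubEngine({}).fold(RnaSequence("x", "ACGU"))

    def test_gggaaaccc_matches_brute_force(self):
        seq = "GGGAAACCC"
        r = BaselineEngine().fold(RnaSequence("x", seq))
        assert r.n_pairs >= 3
        assert -r.pmfe == brute_force_best(seq)

    @pytest.mark.parametrize(
        "seq",
        ["GGGAAACCC", "GCGCAAAGCGC", "AUAUAAAUAU", "ACGUACGUA", "GGUUAACCG"],
    )
    def test_matches_exhaustive_enumeration(self, seq):
        r = BaselineEngine().fold(RnaSequence("x", seq))
        assert -r.pmfe == brute_force_best(seq)

    @given(rna_text)
    @settings(max_examples=40, deadline=None)
    def test_invariants_on_random_input(self, text):
        r = BaselineEngine().fold(RnaSequence("x", text))
        assert len(r.structure) == len(text)
        if r.n_pairs:
            assert r.pmfe < 0
        else:
            assert r.pmfe == 0

    def test_deterministic(self, rng):
        seq = random_rna(rng, 60)
        e = BaselineEngine()
        r1, r2 = e.fold(seq), e.fold(seq)
        assert r1.structure == r2.structure
        assert r1.pmfe == r2.pmfe

    def test_structure_score_consistent_with_pmfe(self, rng):
        # the traceback structure must account for exactly -pmfe
        seq = random_rna(rng, 50)
        r = BaselineEngine().fold(seq)
        stack, total = [], 0.0
        for i, ch in enumerate(r.structure):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                j = stack.pop()
                assert i - j > MIN_HAIRPIN_LOOP
                total += pair_score(seq.residues[j], seq.residues[i])
        assert total == pytest.approx(-r.pmfe)

    def test_fold_wrapper_checks_alignment(self):
        bad = StubEngine({"ACGU": ("..", 0.0)})
        with pytest.raises(EngineError):
            fold(RnaSequence("x", "ACGU"), bad)

    def test_engine_factory(self):
        assert get_engine("baseline").name == "baseline"
        assert get_engine("external:RNAfold").command == "RNAfold"
        with pytest.raises(ValueError):
            get_engine("mystery")


class TestTriplets:
    def test_all_unpaired_acgu(self):
        fv = triplet_features(RnaSequence("x", "ACGU"), FoldResult("....", 0.0))
        d = fv.as_dict()
        assert d["C..."] == 0.5
        assert d["G..."] == 0.5
        assert sum(d.values()) == pytest.approx(1.0)

    def test_gggaaaccc_manual_enumeration(self):
        fv = triplet_features(
            RnaSequence("x", "GGGAAACCC"), FoldResult("(((...)))", -1.0)
        )
        d = fv.as_dict()
        expected = ["G(((", "G((.", "A(..", "A...", "A..(", "C.((", "C((("]
        for name in expected:
            assert d[name] == pytest.approx(1 / 7), name
        assert sum(d.values()) == pytest.approx(1.0)
        assert sum(1 for v in d.values() if v > 0) == 7

    def test_vector_length_32(self, rng):
        seq = random_rna(rng, 30)
        r = BaselineEngine().fold(seq)
        assert len(triplet_features(seq, r)) == 32
        assert len(triplet_names()) == 32

    def test_too_short_rejected(self):
        with pytest.raises(DegenerateInputError):
            triplet_features(RnaSequence("x", "AC"), FoldResult("..", 0.0))

    def test_misaligned_structure_rejected(self):
        with pytest.raises(ValueError):
            triplet_features(RnaSequence("x", "ACGU"), FoldResult("...", 0.0))

    @given(rna_text.filter(lambda t: len(t) >= 3))
    @settings(max_examples=40, deadline=None)
    def test_sums_to_one(self, text):
        seq = RnaSequence("x", text)
        fv = triplet_features(seq, BaselineEngine().fold(seq))
        assert fv.values.min() >= 0
        assert fv.values.sum() == pytest.approx(1.0)


def dinuc_counts(s: str) -> Counter:
    return Counter(zip(s, s[1:]))


class TestShuffle:
    def test_homopolymer_identity(self):
        out = dinucleotide_shuffle(RnaSequence("x", "AAAA"), 0)
        assert out.residues == "AAAA"

    def test_acac_forced_identity(self):
        # brute force: ACAC is the only length-4 sequence with dinucleotide
        # multiset {AC:2, CA:1}
        target = dinuc_counts("ACAC")
        admissible = [
            "".join(t)
            for t in itertools.product(BASES, repeat=4)
            if dinuc_counts("".join(t)) == target
        ]
        assert admissible == ["ACAC"]
        for seed in range(5):
            assert dinucleotide_shuffle(RnaSequence("x", "ACAC"), seed).residues == "ACAC"

    def test_exact_dinucleotide_preservation_200bases(self, rng):
        seq = random_rna(rng, 200)
        for seed in range(10):
            out = dinucleotide_shuffle(seq, seed)
            assert dinuc_counts(out.residues) == dinuc_counts(seq.residues)
            assert out.residues[0] == seq.residues[0]
            assert out.residues[-1] == seq.residues[-1]

    def test_membership_in_admissible_set_all_lengths_up_to_6(self):
        # group every ACGU string by its (first, last, dinuc multiset)
        # signature, then require each shuffle to land in its group
        for L in range(2, 7):
            groups = {}
            for t in itertools.product(BASES, repeat=L):
                s = "".join(t)
                key = (s[0], s[-1], frozenset(dinuc_counts(s).items()))
                groups.setdefault(key, set()).add(s)
            rng = np.random.default_rng(L)
            for t in itertools.islice(itertools.product(BASES, repeat=L), 0, None, 7):
                s = "".join(t)
                key = (s[0], s[-1], frozenset(dinuc_counts(s).items()))
                out = dinucleotide_shuffle(RnaSequence("x", s), rng)
                assert out.residues in groups[key]

    def test_covers_admissible_set(self):
        # every admissible permutation should be reachable across seeds
        s = "ACGUAGCA"
        target = dinuc_counts(s)
        admissible = {
            "".join(t)
            for t in itertools.product(BASES, repeat=len(s))
            if dinuc_counts("".join(t)) == target
            and t[0] == s[0]
            and t[-1] == s[-1]
        }
        seen = {
            dinucleotide_shuffle(RnaSequence("x", s), seed).residues
            for seed in range(300)
        }
        assert seen == admissible

    def test_seeded_reproducibility(self, rng):
        seq = random_rna(rng, 100)
        a = dinucleotide_shuffle(seq, 42).residues
        b = dinucleotide_shuffle(seq, 42).residues
        assert a == b

    def test_too_short_rejected(self):
        with pytest.raises(DegenerateInputError):
            dinucleotide_shuffle(RnaSequence("x", "A"), 0)

    def test_ambiguity_rejected(self):
        with pytest.raises(ValueError):
            dinucleotide_shuffle(RnaSequence("x", "ACGN", has_ambiguity=True), 0)

    def test_1000_random_sequences_preserve_counts(self):
        rng = np.random.default_rng(99)
        for i in range(1000):
            length = int(rng.integers(2, 80))
            seq = random_rna(rng, length, f"s{i}")
            out = dinucleotide_shuffle(seq, rng)
            assert dinuc_counts(out.residues) == dinuc_counts(seq.residues)


class TestQmfe:
    def test_formula_n0(self):
        assert QmfeResult(-50.0, 10, 0).qmfe == 0.0

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            QmfeResult(-1.0, 5, 6)

    def test_homopolymer_all_ties(self):
        r = qmfe(RnaSequence("x", "A" * 50), 10, BaselineEngine(), 0)
        assert r.n == 10
        assert r.qmfe == pytest.approx(10 / 11)

    def test_scripted_worked_example(self):
        # original -10; exactly 3 of 9 shuffles at -11 (more stable)
        engine = ScriptedEngine([-10, -11, -9, -11, -9, -9, -11, -9, -9, -9])
        seq = RnaSequence("x", "ACGUACGUACGUACGUGCA")
        r = qmfe(seq, 9, engine, 0)
        assert r.n == 3
        assert r.qmfe == pytest.approx(3 / 10)

    def test_ties_count_toward_n(self):
        engine = ScriptedEngine([-10, -10, -10, -5])
        r = qmfe(RnaSequence("x", "ACGUACGU"), 3, engine, 0)
        assert r.n == 2

    def test_monotonicity_in_original_pmfe(self):
        null = [-8.0, -6.0, -4.0, -2.0]
        values = []
        for original in (-9.0, -5.0, -1.0):
            engine = ScriptedEngine([original] + null)
            values.append(qmfe(RnaSequence("x", "ACGUACGU"), 4, engine, 0).qmfe)
        assert values == sorted(values)  # deeper pmfe -> lower qmfe

    def test_n1_gives_zero_or_half(self):
        rng = np.random.default_rng(3)
        for i in range(5):
            seq = random_rna(rng, 30, f"s{i}")
            r = qmfe(seq, 1, BaselineEngine(), i)
            assert r.qmfe in (0.0, 0.5)

    def test_bounds(self, rng):
        seq = random_rna(rng, 40)
        r = qmfe(seq, 7, BaselineEngine(), 5)
        assert 0 <= r.qmfe <= 7 / 8

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError):
            qmfe(RnaSequence("x", "ACGU"), 0, BaselineEngine(), 0)


class TestStructuralVector:
    def test_length_33(self, rng):
        seq = random_rna(rng, 40)
        fv = structural_feature_vector(seq, BaselineEngine(), N=5, rng_seed=0)
        assert len(fv) == 33
        assert fv.names[-1] == "QMFE"

    def test_matches_components(self, rng):
        seq = random_rna(rng, 40)
        engine = BaselineEngine()
        fv = structural_feature_vector(seq, engine, N=5, rng_seed=7)
        trip = triplet_features(seq, engine.fold(seq))
        q = qmfe(seq, 5, engine, 7)
        assert fv.values[:32] == pytest.approx(trip.values)
        assert fv.values[32] == pytest.approx(q.qmfe)

    def test_all_unpaired_case(self):
        seq = RnaSequence("x", "A" * 30)
        fv = structural_feature_vector(seq, BaselineEngine(), N=4, rng_seed=0)
        d = fv.as_dict()
        assert d["A..."] == pytest.approx(1.0)
        assert d["QMFE"] == pytest.approx(4 / 5)
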