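import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bamir.io_formats import SequenceRecord
from bamir.novel_mirna_filter import (
    AlignedRead,
    FilterCriteria,
    HairpinCandidate,
    StructureError,
    arm_support,
    assign_reads_to_arms,
    count_hairpin_loops,
    evaluate_candidate,
    five_prime_homogeneity,
    mfe_per_nucleotide,
    seed_family_match,
    three_prime_overhang,
)
from bamir.synthetic_data import HairpinSimSpec, simulate_hairpin_candidate

from conftest import oracle_hairpin_loops, random_dot_bracket


def make_candidate(dot_bracket, mature=(0, 22), star=None, mfe=-20.0):
    n = len(dot_bracket)
    star = star or (n - 22, n)
    seq = ("AC" * n)[:n]
    return HairpinCandidate("c", seq, dot_bracket, mfe, mature, star)


class TestHairpinLoops:
    @pytest.mark.parametrize(
        "structure,expected",
        [
            ("((((....))))", 1),
            ("..((..))..((..))..", 2),
            ("(((..((...))..((...))..)))", 2),
            ("()", 1),
            ("....", 0),
        ],
    )
    def test_examples(self, structure, expected):
        assert count_hairpin_loops(structure) == expected

    def test_unbalanced_rejected(self):
        with pytest.raises(StructureError):
            count_hairpin_loops("((..)")

    def test_matches_pair_enclosure_oracle_on_random_structures(self):
        rng = random.Random(42)
        for _ in range(1000):
            db = random_dot_bracket(rng)
            assert count_hairpin_loops(db) == oracle_hairpin_loops(db), db


class TestArmAssignment:
    candidate = HairpinCandidate(
        "h", "ACGU" * 15, "(" * 25 + "." * 10 + ")" * 25, -20.0, (0, 25), (35, 60)
    )

    @pytest.mark.parametrize(
        "start,expected_arm",
        [(0, "mature"), (3, "mature"), (4, "unassigned"), (35, "star"), (33, "star")],
    )
    def test_window_rule(self, start, expected_arm):
        read = AlignedRead(start, start + 20, 0, 1)
        mature, star, unassigned = assign_reads_to_arms([read], self.candidate)
        got = "mature" if mature else "star" if star else "unassigned"
        assert got == expected_arm

    def test_read_outside_precursor_rejected(self):
        with pytest.raises(ValueError):
            assign_reads_to_arms([AlignedRead(50, 70, 0, 1)], self.candidate)


class TestArmSupport:
    def test_weighted_sum_of_perfect_reads(self):
        reads = [AlignedRead(0, 20, 0, 20), AlignedRead(1, 21, 0, 15), AlignedRead(0, 20, 1, 100)]
        assert arm_support(reads) == 35

    def test_empty_arm(self):
        assert arm_support([]) == 0


class TestHomogeneity:
    def test_single_start(self):
        assert five_prime_homogeneity([AlignedRead(5, 25, 0, 7)]) == 1.0

    def test_weighted_fraction(self):
        reads = [AlignedRead(5, 25, 0, 30), AlignedRead(6, 26, 2, 10)]
        assert five_prime_homogeneity(reads) == pytest.approx(0.75)

    def test_tie_gives_shared_max_fraction(self):
        reads = [AlignedRead(5, 25, 0, 20), AlignedRead(6, 26, 0, 20)]
        assert five_prime_homogeneity(reads) == pytest.approx(0.5)

    @given(
        st.lists(
            st.tuples(st.integers(0, 5), st.integers(0, 2), st.integers(1, 50)),
            min_size=1,
            max_size=10,
        )
    )
    @settings(deadline=None)
    def test_in_unit_interval_when_nonempty(self, raw):
        reads = [AlignedRead(s, s + 20, mm, c) for s, mm, c in raw]
        assert 0 < five_prime_homogeneity(reads) <= 1


class TestOverhang:
    def test_blunt_duplex(self):
        db = "(" * 22 + "." * 6 + ")" * 22
        assert three_prime_overhang(make_candidate(db)) == 0

    def test_two_nt_protrusion(self):
        # 22 paired + loop + 22 paired + 2 dangling 3' nt; last arm spans the tail
        db = "(" * 22 + "." * 6 + ")" * 22 + ".."
        cand = make_candidate(db, star=(30, 52))
        assert three_prime_overhang(cand) == 2

    def test_recessed_end_negative(self):
        db = "." + "(" * 22 + "." * 6 + ")" * 22
        cand = make_candidate(db, mature=(0, 23), star=(29, 51))
        assert three_prime_overhang(cand) == -1

    def test_unpaired_terminus_undefined(self):
        db = "." * 5 + "(" * 20 + "." * 6 + ")" * 20 + "." * 5
        cand = make_candidate(db, mature=(0, 25), star=(31, 56))
        assert three_prime_overhang(cand) is None


class TestMfePerNt:
    @pytest.mark.parametrize(
        "mfe,length,expected", [(-30, 60, -0.5), (-10, 100, -0.1), (-12, 60, -0.2)]
    )
    def test_values(self, mfe, length, expected):
        assert mfe_per_nucleotide(mfe, length) == pytest.approx(expected)

    def test_boundary_passes(self):
        # -0.2 kcal/mol/nt sits exactly on the inclusive threshold
        assert mfe_per_nucleotide(-12, 60) <= FilterCriteria().mfe_per_nt_max


class TestEvaluateCandidate:
    def test_all_pass_fixture(self):
        cand, reads, truth = simulate_hairpin_candidate(HairpinSimSpec(rng_seed=7))
        report = evaluate_candidate(cand, reads)
        assert report.overall_pass
        assert truth["overall_pass"]

    def test_star_nine_fails_only_star(self):
        cand, reads, _ = simulate_hairpin_candidate(HairpinSimSpec(star_reads_0mm=9, rng_seed=7))
        report = evaluate_candidate(cand, reads)
        failed = [k for k, v in report.criteria.items() if not v.passed]
        assert failed == ["star_support"]
        assert not report.overall_pass

    def test_overall_pass_is_conjunction(self):
        cand, reads, _ = simulate_hairpin_candidate(HairpinSimSpec(rng_seed=1))
        report = evaluate_candidate(cand, reads)
        assert report.overall_pass == all(r.passed for r in report.criteria.values())

    def test_decisions_match_generator_truth(self):
        rng = random.Random(11)
        for _ in range(100):
            spec = HairpinSimSpec(
                mature_reads_0mm=rng.choice([0, 5, 29, 30, 31, 50]),
                star_reads_0mm=rng.choice([0, 9, 10, 11, 20]),
                homogeneity_target=rng.choice([0.45, 0.5, 0.55, 0.9, 1.0]),
                overhang_3p=rng.choice([-2, 0, 2, 4, 5, 6]),
                n_subhairpins=rng.choice([1, 1, 2, 3]),
                mfe_per_nt_target=rng.choice([-0.5, -0.25, -0.2, -0.15, -0.1]),
                rng_seed=rng.randrange(2**31),
            )
            cand, reads, truth = simulate_hairpin_candidate(spec)
            report = evaluate_candidate(cand, reads)
            got = {k: v.passed for k, v in report.criteria.items()}
            assert got == truth["criteria"], spec

    def test_assignment_matches_generator_truth(self):
        cand, reads, truth = simulate_hairpin_candidate(
            HairpinSimSpec(homogeneity_target=0.6, rng_seed=13)
        )
        mature, star, unassigned = assign_reads_to_arms(reads, cand)
        labels = ["mature"] * len(mature) + ["star"] * len(star)
        assert not unassigned
        assert labels == truth["read_arms"]

    def test_relaxing_thresholds_is_monotone(self):
        cand, reads, _ = simulate_hairpin_candidate(
            HairpinSimSpec(star_reads_0mm=9, overhang_3p=5, rng_seed=3)
        )
        strict = evaluate_candidate(cand, reads)
        relaxed = evaluate_candidate(
            cand,
            reads,
            FilterCriteria(
                mature_min_reads=1,
                star_min_reads=1,
                homogeneity_min=0.0,
                overhang_range=(-5, 10),
                mfe_per_nt_max=0.0,
                max_hairpin_loops=5,
            ),
        )
        for name, res in strict.criteria.items():
            assert relaxed.criteria[name].passed >= res.passed


class TestSeedFamily:
    def test_shared_seed_matches(self):
        novel = [SequenceRecord("n1", "AGCAUUAACGGUCAAGCUUU")]
        ref = [SequenceRecord("r1", "GGCAUUAACGCCCCCCCCCC")]  # same nt 2-8
        assert seed_family_match(novel, ref) == [("n1", "r1")]

    def test_shifted_seed_no_match(self):
        novel = [SequenceRecord("n1", "AGCAUUAACGGUCAAGCUUU")]
        ref = [SequenceRecord("r1", "GAGCAUUAACGGUCAAGCUU")]  # shifted by 1
        assert seed_family_match(novel, ref) == []

    def test_self_match_reported(self):
        rec = SequenceRecord("n1", "AGCAUUAACGGUCAAGCUUU")
        assert ("n1", "n1") in seed_family_match([rec], [rec])
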