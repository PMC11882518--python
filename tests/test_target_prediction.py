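import random

import numpy as np
import pytest

from bamir._energy_params import STACK_ENERGIES
from bamir.io_formats import GenomicInterval, SequenceRecord, reverse_complement
from bamir.synthetic_data import UTRSimSpec, simulate_utr_with_sites
from bamir.target_prediction import (
    EnergyConfig,
    PredictionConfig,
    Site,
    classify_seed_site,
    duplex_energy,
    extract_longest_3utrs,
    filter_interactions,
    frame_to_sites,
    scan_utr,
)

from conftest import oracle_classify

MIRNA = SequenceRecord("mir-x", "AGCAUUAACGGUCAAGCUUU")


def random_mirna(rng, length=21):
    return SequenceRecord("m", "".join(rng.choice("ACGU") for _ in range(length)))


class TestClassifySeedSite:
    # rc(m2-8) for MIRNA is GUUAAUG + C; target windows read 5'->3'
    @pytest.mark.parametrize(
        "window,expected",
        [
            (reverse_complement(MIRNA.sequence[1:8]) + "A", "8mer"),
            (reverse_complement(MIRNA.sequence[1:8]) + "G", "7mer-m8"),
            ("C" + reverse_complement(MIRNA.sequence[1:7]) + "A", "7mer-A1"),
            ("C" + reverse_complement(MIRNA.sequence[1:7]) + "C", "6mer"),
            (reverse_complement(MIRNA.sequence[2:8]) + "GC", "off-6mer"),
            ("ACGUACGU", None),
        ],
    )
    def test_class_taxonomy(self, window, expected):
        assert classify_seed_site(MIRNA, window) == expected

    def test_window_length_enforced(self):
        with pytest.raises(ValueError):
            classify_seed_site(MIRNA, "ACGUACG")

    def test_agrees_with_string_oracle(self):
        rng = random.Random(7)
        for _ in range(2000):
            m = random_mirna(rng)
            window = "".join(rng.choice("ACGU") for _ in range(8))
            assert classify_seed_site(m, window) == oracle_classify(m, window)

    def test_agrees_with_oracle_on_planted_windows(self):
        # near-match windows are the hard cases; plant then perturb one nt
        rng = random.Random(8)
        for _ in range(500):
            m = random_mirna(rng)
            window = list(reverse_complement(m.sequence[1:8]) + rng.choice("ACGU"))
            i = rng.randrange(8)
            window[i] = rng.choice("ACGU")
            w = "".join(window)
            assert classify_seed_site(m, w) == oracle_classify(m, w)


class TestDuplexEnergy:
    def test_toy_gc_helix_hand_summed(self):
        # three GG/CC stacks (-3.30 each) + initiation 4.09
        assert duplex_energy("GGGG", "CCCC") == pytest.approx(-5.81)

    def test_au_ended_helix_hand_summed(self):
        # AGGA:UCCU = 4.09 + (-2.10 - 3.30 - 2.40) + 2 * 0.45 terminal AU
        assert duplex_energy("AGGA", "UCCU") == pytest.approx(-2.81)

    def test_no_pairing_returns_zero(self):
        assert duplex_energy("AAAA", "AAAA") == 0.0

    def test_never_positive_and_symmetric(self):
        rng = random.Random(3)
        for _ in range(200):
            a = "".join(rng.choice("ACGU") for _ in range(rng.randint(4, 25)))
            b = "".join(rng.choice("ACGU") for _ in range(rng.randint(4, 25)))
            e_ab = duplex_energy(a, b)
            assert e_ab <= 0
            assert e_ab == pytest.approx(duplex_energy(b, a))

    def test_matches_bruteforce_best_helix(self):
        """Exhaustive oracle: enumerate every register and every contiguous
        pair run directly from the stack table."""

        def oracle(a, b, cfg):
            from bamir._energy_params import ALL_PAIRS, TERMINAL_AU_PENALTY

            rb = b[::-1]
            best = 0.0
            for shift in range(-(len(a) - 1), len(rb)):
                idx = [
                    i
                    for i in range(max(0, -shift), min(len(a), len(rb) - shift))
                ]
                for p in idx:
                    for q in idx:
                        if q < p:
                            continue
                        pairs = [(a[i], rb[i + shift]) for i in range(p, q + 1)]
                        if not all(pr in ALL_PAIRS for pr in pairs):
                            continue
                        e = cfg.initiation
                        for i in range(p, q):
                            e += STACK_ENERGIES[(a[i], a[i + 1], rb[i + shift], rb[i + 1 + shift])]
                        for end in (pairs[0], pairs[-1]):
                            if end not in (("C", "G"), ("G", "C")):
                                e += TERMINAL_AU_PENALTY
                        best = min(best, e)
            return best

        rng = random.Random(5)
        cfg = EnergyConfig()
        for _ in range(60):
            a = "".join(rng.choice("ACGU") for _ in range(rng.randint(5, 14)))
            b = "".join(rng.choice("ACGU") for _ in range(rng.randint(5, 14)))
            assert duplex_energy(a, b, cfg) == pytest.approx(oracle(a, b, cfg))

    def test_wobble_disallowed_never_stronger(self):
        rng = random.Random(9)
        for _ in range(50):
            a = "".join(rng.choice("ACGU") for _ in range(12))
            b = "".join(rng.choice("ACGU") for _ in range(12))
            assert duplex_energy(a, b, EnergyConfig(allow_wobble=False)) >= duplex_energy(a, b)


class TestScanUtr:
    def test_recovers_planted_sites_exactly(self, mirna):
        spec = UTRSimSpec(
            utr_length=260,
            planted_sites=(("8mer", 20), ("7mer-m8", 60), ("7mer-A1", 100),
                           ("6mer", 140), ("off-6mer", 180)),
            rng_seed=21,
        )
        utr, truth = simulate_utr_with_sites(mirna, spec)
        found = scan_utr(mirna, utr)
        assert [(s.utr_position, s.site_class) for s in found] == [
            (s.utr_position, s.site_class) for s in truth
        ]

    def test_short_utr_empty(self, mirna):
        assert scan_utr(mirna, SequenceRecord("u", "ACGUACG")) == []

    def test_full_reverse_complement_single_site(self, mirna):
        utr = SequenceRecord("u", reverse_complement(mirna.sequence))
        sites = scan_utr(mirna, utr)
        assert len(sites) == 1
        assert sites[0].site_class in ("8mer", "7mer-m8")


class TestFilterInteractions:
    def site(self, gene, mirna="m1", pos=0, cls="8mer", energy=-10.0):
        return Site(gene, mirna, pos, cls, energy)

    def test_single_site_utr_dropped(self):
        table = filter_interactions([self.site("g1")])
        assert table.empty

    def test_strong_6mer_dropped_regardless_of_energy(self):
        sites = [self.site("g1", cls="6mer", energy=-12.0),
                 self.site("g1", pos=30), self.site("g1", pos=60)]
        table = filter_interactions(sites)
        assert table["n_sites"].tolist() == [2]

    def test_energy_boundary_retained(self):
        sites = [self.site("g1", energy=-7.0), self.site("g1", pos=30, energy=-7.0)]
        table = filter_interactions(sites)
        assert len(table) == 1

    def test_energy_above_cutoff_dropped(self):
        sites = [self.site("g1", energy=-6.9), self.site("g1", pos=30)]
        table = filter_interactions(sites)
        assert table.empty  # one survivor falls below the 2-site minimum

    def test_site_count_spans_mirnas_by_default(self):
        sites = [self.site("g1", mirna="m1"), self.site("g1", mirna="m2", pos=40)]
        table = filter_interactions(sites)
        assert sorted(table["mirna_id"]) == ["m1", "m2"]

    def test_per_pair_variant(self):
        sites = [self.site("g1", mirna="m1"), self.site("g1", mirna="m2", pos=40)]
        table = filter_interactions(sites, PredictionConfig(count_sites_per_pair=True))
        assert table.empty

    def test_idempotent(self):
        rng = random.Random(2)
        sites = [
            self.site(f"g{rng.randrange(5)}", mirna=f"m{rng.randrange(3)}",
                      pos=i * 10, cls=rng.choice(["8mer", "7mer-m8", "6mer"]),
                      energy=-rng.uniform(3, 15))
            for i in range(40)
        ]
        once = filter_interactions(sites)
        again = filter_interactions(frame_to_sites_from_table(once))
        # refiltering the aggregated table's surviving sites changes nothing
        assert once[["mirna_id", "gene_id"]].values.tolist() == \
            again[["mirna_id", "gene_id"]].values.tolist()

    def test_retained_classes_and_energies(self):
        rng = random.Random(4)
        sites = [
            self.site(f"g{rng.randrange(4)}", pos=i * 9,
                      cls=rng.choice(["8mer", "7mer-m8", "7mer-A1", "6mer", "off-6mer"]),
                      energy=-rng.uniform(2, 14))
            for i in range(60)
        ]
        table = filter_interactions(sites)
        assert (table["min_energy"] <= -7).all()
        assert set(table["best_class"]) <= {"8mer", "7mer-m8", "7mer-A1"}


def frame_to_sites_from_table(table):
    """Re-expand an aggregated interaction table into representative sites."""
    sites = []
    for row in table.itertuples():
        for i in range(int(row.n_sites)):
            sites.append(Site(row.gene_id, row.mirna_id, i * 10, row.best_class,
                              float(row.min_energy)))
    return sites


class TestLongest3Utrs:
    GENOME = {"chr1": "ACGTACGTACGTACGTACGTACGTACGTAC"}  # 30 nt toy chromosome

    def feats(self, rows):
        return [
            (g, t, "three_prime_utr", GenomicInterval("chr1", s, e, strand))
            for g, t, s, e, strand in rows
        ]

    def test_longest_transcript_wins(self):
        feats = self.feats([("g1", "t1", 0, 6, "+"), ("g1", "t2", 0, 10, "+")])
        (rec,) = extract_longest_3utrs(feats, self.GENOME)
        assert len(rec.sequence) == 10

    def test_tie_breaks_lexicographically(self):
        feats = self.feats([("g1", "tB", 0, 6, "+"), ("g1", "tA", 10, 16, "+")])
        (rec,) = extract_longest_3utrs(feats, self.GENOME)
        assert rec.sequence == "GUACGU"  # tA's slice, transcribed

    def test_minus_strand_reverse_complemented(self):
        feats = self.feats([("g1", "t1", 0, 8, "-")])
        (rec,) = extract_longest_3utrs(feats, self.GENOME)
        assert rec.sequence == reverse_complement("ACGUACGU")

    def test_spliced_utr_concatenated(self):
        feats = self.feats([("g1", "t1", 0, 4, "+"), ("g1", "t1", 8, 12, "+")])
        (rec,) = extract_longest_3utrs(feats, self.GENOME)
        assert rec.sequence == "ACGU" + "ACGU"
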