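"""Assembly metrics against brute-force oracles, and strain grouping."""

import itertools
import math

import numpy as np
import pytest

from sagcycle.formats import Assembly, Contig, PipelineConfig, revcomp
from sagcycle.metrics import (
    depth_bias_stats,
    duplication_ratio,
    fragment_ani,
    genome_fraction,
    group_strains,
    nxx,
    tnf_correlation,
    tnf_vector,
)
from sagcycle.simulate import simulate_genome

from conftest import random_seq


@pytest.fixture(scope="module")
def truth40k():
    return simulate_genome(40000, 0.45, seed=301, circular=False)


class TestGenomeFraction:
    def test_assembly_equals_truth(self, truth40k):
        asm = Assembly(contigs=[Contig("c", truth40k.seq)])
        assert genome_fraction(asm, truth40k) == pytest.approx(100.0)

    def test_half_assembly(self, truth40k):
        asm = Assembly(contigs=[Contig("c", truth40k.seq[:20000])])
        assert genome_fraction(asm, truth40k) == pytest.approx(50.0, abs=0.5)

    def test_unrelated_contigs_zero(self, truth40k):
        asm = Assembly(
            contigs=[Contig(f"c{i}", random_seq(5000, seed=400 + i))
                     for i in range(3)]
        )
        assert genome_fraction(asm, truth40k) == 0.0

    def test_circular_truth_via_doubling(self):
        g = simulate_genome(30000, 0.5, seed=302, circular=True)
        rotated = g.seq[11000:] + g.seq[:11000]
        asm = Assembly(contigs=[Contig("c", rotated)])
        assert genome_fraction(asm, g) == pytest.approx(100.0, abs=0.2)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            genome_fraction(Assembly(contigs=[]), "")


class TestDuplicationRatio:
    def test_perfect_single_copy(self, truth40k):
        asm = Assembly(contigs=[Contig("c", truth40k.seq)])
        assert duplication_ratio(asm, truth40k) == pytest.approx(1.0,
                                                                 abs=0.01)

    def test_half_duplicated_assembly(self, truth40k):
        asm = Assembly(
            contigs=[Contig("full", truth40k.seq),
                     Contig("extra", truth40k.seq[:20000])]
        )
        assert duplication_ratio(asm, truth40k) == pytest.approx(1.5,
                                                                 abs=0.01)

    def test_two_disjoint_halves(self, truth40k):
        asm = Assembly(
            contigs=[Contig("a", truth40k.seq[:20000]),
                     Contig("b", truth40k.seq[20000:])]
        )
        assert duplication_ratio(asm, truth40k) == pytest.approx(1.0,
                                                                 abs=0.01)


class TestNxx:
    @pytest.mark.parametrize(
        "lengths,x,genome_size,expected",
        [
            ([5, 4, 3, 2], 50, None, 4),    # cumulative 5,9 >= 7
            # NG50 with genome 28: need >= 14; cumulative sums 5,9,12,14
            # first reach 14 at the length-2 contig
            ([5, 4, 3, 2], 50, 28, 2),
            ([42], 50, None, 42),
            ([], 50, None, 0),
        ],
    )
    def test_worked_examples(self, lengths, x, genome_size, expected):
        assert nxx(lengths, x, genome_size) == expected

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(303)
        for _ in range(20):
            lengths = rng.integers(1, 1000, size=rng.integers(1, 30)).tolist()
            total = sum(lengths)
            # exhaustive: largest L in lengths with sum(>=L) >= total/2
            best = 0
            for L in sorted(set(lengths), reverse=True):
                if sum(x for x in lengths if x >= L) >= total / 2:
                    best = max(best, L)
            assert nxx(lengths, 50) == best


class TestDepthStats:
    def test_uniform_depth_zero_gini(self):
        s = depth_bias_stats(np.full(1000, 7))
        assert s["gini"] == pytest.approx(0.0, abs=1e-12)
        assert s["breadth"] == 1.0
        assert s["mean"] == 7.0

    def test_half_coverage_breadth(self):
        d = np.concatenate([np.full(500, 10), np.zeros(500)])
        assert depth_bias_stats(d)["breadth"] == 0.5

    def test_gini_matches_brute_force(self):
        rng = np.random.default_rng(304)
        d = rng.integers(0, 50, size=300).astype(float)
        s = depth_bias_stats(d)
        n = len(d)
        brute = sum(
            abs(a - b) for a, b in itertools.product(d, d)
        ) / (2 * n * n * d.mean())
        assert s["gini"] == pytest.approx(brute, abs=1e-9)


class TestTnf:
    def test_self_correlation_is_one(self):
        s = random_seq(5000, seed=305)
        assert tnf_correlation(s, s) == pytest.approx(1.0)

    def test_reverse_complement_correlation_is_one(self):
        s = random_seq(5000, seed=306)
        assert tnf_correlation(s, revcomp(s)) == pytest.approx(1.0)

    def test_vector_matches_brute_force_counts(self):
        s = random_seq(3000, seed=307)
        v = tnf_vector(s)
        assert len(v) == 136
        # brute force: count canonical 4-mers with a dict
        counts: dict = {}
        for i in range(len(s) - 3):
            kmer = s[i : i + 4]
            canon = min(kmer, revcomp(kmer))
            counts[canon] = counts.get(canon, 0) + 1
        brute = np.zeros(136)
        # rebuild the canonical ordering used by tnf_vector
        order: dict = {}
        for code in range(256):
            kmer = "".join(
                "ACGT"[(code >> (2 * (3 - j))) & 3] for j in range(4)
            )
            canon = min(kmer, revcomp(kmer))
            if canon not in order:
                order[canon] = len(order)
        for kmer, n in counts.items():
            brute[order[kmer]] = n
        brute /= brute.sum()
        assert np.allclose(v, brute)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            tnf_vector("ACGT" * 100)


class TestFragmentAni:
    def test_identical_genomes(self):
        s = random_seq(30000, seed=308)
        r = fragment_ani(s, s)
        assert r.defined
        assert r.ani == pytest.approx(100.0)
        assert r.mapped_fraction == 1.0

    def test_two_percent_divergence(self):
        s = random_seq(30000, seed=309)
        rng = np.random.default_rng(310)
        other = list(s)
        for p in rng.choice(len(s), size=int(0.02 * len(s)), replace=False):
            other[p] = "ACGT"[("ACGT".index(other[p]) + 1) % 4]
        r = fragment_ani(s, "".join(other))
        assert r.defined
        assert r.ani == pytest.approx(98.0, abs=0.3)

    def test_unrelated_genomes_flagged_undefined(self):
        a = random_seq(30000, seed=311)
        b = random_seq(30000, seed=312)
        r = fragment_ani(a, b)
        assert not r.defined
        assert math.isnan(r.ani)


class TestGroupStrains:
    CFG = PipelineConfig()

    def test_passing_pair_grouped(self):
        groups = group_strains(
            {("a", "b"): {"ani": 96, "tnf": 0.95, "marker": 99.5}}, self.CFG
        )
        assert groups == [{"a", "b"}]

    def test_strict_threshold_separates(self):
        groups = group_strains(
            {("a", "b"): {"ani": 94.9, "tnf": 0.95, "marker": 99.5}},
            self.CFG,
        )
        assert groups == [{"a"}, {"b"}]

    def test_boundary_value_is_not_enough(self):
        # thresholds are strictly greater-than
        groups = group_strains(
            {("a", "b"): {"ani": 95.0, "tnf": 0.95}}, self.CFG
        )
        assert groups == [{"a"}, {"b"}]

    def test_single_linkage_transitive_closure(self):
        pairs = {
            ("a", "b"): {"ani": 97, "tnf": 0.95},
            ("b", "c"): {"ani": 97, "tnf": 0.95},
            ("a", "c"): {"ani": 90, "tnf": 0.5},
        }
        assert group_strains(pairs, self.CFG) == [{"a", "b", "c"}]

    def test_marker_skipped_when_absent(self):
        groups = group_strains(
            {("a", "b"): {"ani": 96, "tnf": 0.95}}, self.CFG
        )
        assert groups == [{"a", "b"}]

    def test_asymmetric_table_rejected(self):
        pairs = {
            ("a", "b"): {"ani": 97, "tnf": 0.95},
            ("b", "a"): {"ani": 80, "tnf": 0.95},
        }
        with pytest.raises(ValueError, match="asymmetric"):
            group_strains(pairs, self.CFG)
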