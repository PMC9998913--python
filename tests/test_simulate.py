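"""Simulator contracts: determinism, bias statistics, truth tracking."""

import numpy as np
import pytest

from sagcycle.formats import write_fastq
from sagcycle.simulate import (
    BiasProfile,
    make_bias_profile,
    pooled_sag_long_reads,
    read_truth,
    sample_long_reads,
    sample_short_reads,
    simulate_genome,
    truth_breadth,
    write_truth,
)


class TestSimulateGenome:
    def test_length_and_determinism(self):
        g1 = simulate_genome(50000, 0.5, seed=1)
        g2 = simulate_genome(50000, 0.5, seed=1)
        assert len(g1.seq) == 50000
        assert g1.seq == g2.seq
        assert set(g1.seq) <= set("ACGT")

    def test_gc_content_within_binomial_bound(self):
        # sd = sqrt(p(1-p)/L) ~ 0.00216; 3.3 sd < 0.01
        g = simulate_genome(50000, 0.37, seed=2)
        gc = (g.seq.count("G") + g.seq.count("C")) / len(g.seq)
        assert abs(gc - 0.37) < 0.01

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.7])
    def test_gc_out_of_range(self, bad):
        with pytest.raises(ValueError):
            simulate_genome(5000, bad, seed=1)

    def test_too_short(self):
        with pytest.raises(ValueError):
            simulate_genome(500, 0.5, seed=1)


class TestBiasProfile:
    def test_full_breadth_no_dropout(self, genome20k):
        p = make_bias_profile(genome20k, target_breadth=1.0, seed=4)
        assert not p.dropout_mask.any()
        assert (p.weights > 0).all()

    def test_half_breadth_hits_target(self, genome20k):
        p = make_bias_profile(genome20k, target_breadth=0.5, seed=5)
        assert 0.48 <= p.breadth <= 0.52

    def test_skew_heavy_tail(self, genome50k):
        # many tiles so position-level quantiles approximate the lognormal:
        # p95/median of lognormal(0, 2) is e^(1.645*2) ~ 27 >> 5
        ratios = [
            float(
                np.percentile(
                    make_bias_profile(
                        genome50k, n_amplicons=200, skew=2.0,
                        target_breadth=1.0, seed=s,
                    ).weights,
                    95,
                )
                / np.median(
                    make_bias_profile(
                        genome50k, n_amplicons=200, skew=2.0,
                        target_breadth=1.0, seed=s,
                    ).weights
                )
            )
            for s in range(3)
        ]
        assert all(r > 5 for r in ratios)

    def test_zero_breadth_rejected(self, genome20k):
        with pytest.raises(ValueError):
            make_bias_profile(genome20k, target_breadth=0.0, seed=1)

    def test_dropout_invariant(self, genome20k):
        p = make_bias_profile(genome20k, target_breadth=0.6, seed=6)
        assert (p.weights[p.dropout_mask] == 0).all()
        with pytest.raises(ValueError):
            BiasProfile(
                weights=np.ones(10), dropout_mask=np.ones(10, dtype=bool)
            )


class TestLongReads:
    def test_no_chimeras_when_rate_zero(self, clean_reads20k):
        assert all(not r.truth.junctions for r in clean_reads20k)

    def test_error_free_reads_are_exact_substrings(self, genome20k):
        lin = simulate_genome(20000, 0.5, seed=3, circular=False)
        p = make_bias_profile(lin, target_breadth=1.0, skew=0.0, seed=1)
        reads = sample_long_reads(
            lin, p, mean_depth=5, error_rate=0.0, chimera_rate=0.0, seed=9
        )
        for r in reads:
            (s, e, strand) = r.truth.intervals[0]
            assert strand == "+"
            assert lin.seq[s:e] == r.seq

    def test_realized_depth_near_nominal(self, genome20k, uniform_profile20k):
        reads = sample_long_reads(
            genome20k, uniform_profile20k, mean_depth=30,
            error_rate=0.0, chimera_rate=0.0, seed=11,
        )
        depth = sum(len(r.seq) for r in reads) / len(genome20k)
        assert 27 <= depth <= 33

    def test_breadth_tracks_target(self, genome50k):
        for target in (0.4, 0.6):
            p = make_bias_profile(
                genome50k, target_breadth=target, skew=1.0, seed=13
            )
            reads = sample_long_reads(
                genome50k, p, mean_depth=25, error_rate=0.0,
                chimera_rate=0.0, seed=14,
            )
            realized = truth_breadth(reads, len(genome50k))
            assert abs(realized - target) <= 0.03

    def test_chimera_fraction_within_binomial_bounds(self, genome50k):
        p = make_bias_profile(genome50k, target_breadth=1.0, seed=15)
        reads = sample_long_reads(
            genome50k, p, mean_depth=40, error_rate=0.0,
            chimera_rate=0.05, seed=16,
        )
        frac = sum(bool(r.truth.junctions) for r in reads) / len(reads)
        # 99% binomial band around 0.05 at n=400
        sd = (0.05 * 0.95 / len(reads)) ** 0.5
        assert abs(frac - 0.05) <= 2.6 * sd

    def test_determinism_byte_identical(self, genome20k, uniform_profile20k,
                                        tmp_path):
        a, b = (
            sample_long_reads(
                genome20k, uniform_profile20k, mean_depth=10,
                error_rate=0.01, chimera_rate=0.02, seed=21,
            )
            for _ in range(2)
        )
        fa, fb = tmp_path / "a.fastq", tmp_path / "b.fastq"
        write_fastq(a, fa)
        write_fastq(b, fb)
        assert fa.read_bytes() == fb.read_bytes()

    def test_profile_length_mismatch(self, genome20k):
        bad = BiasProfile(
            weights=np.ones(100), dropout_mask=np.zeros(100, dtype=bool)
        )
        with pytest.raises(ValueError):
            sample_long_reads(genome20k, bad, mean_depth=5)


class TestShortReads:
    def test_zero_depth_empty(self, genome20k):
        assert sample_short_reads(genome20k, depth=0.001, read_len=150) == []

    def test_error_free_exact(self, genome20k):
        from sagcycle.formats import revcomp

        doubled = genome20k.seq * 2
        reads = sample_short_reads(genome20k, depth=2, seed=31)
        for r in reads:
            s, e, strand = r.truth.intervals[0]
            expect = doubled[s:e]
            assert r.seq == (expect if strand == "+" else revcomp(expect))

    def test_read_count_arithmetic(self, genome20k):
        reads = sample_short_reads(genome20k, depth=50, read_len=150)
        assert len(reads) == round(50 * len(genome20k) / 150)


class TestTruthFile:
    def test_round_trip_and_interval_counts(self, genome20k,
                                            uniform_profile20k, tmp_path):
        reads = sample_long_reads(
            genome20k, uniform_profile20k, mean_depth=10,
            error_rate=0.0, chimera_rate=0.3, seed=41,
        )
        p = tmp_path / "truth.tsv"
        write_truth(reads, p)
        back = read_truth(p)
        n_chim = sum(bool(r.truth.junctions) for r in reads)
        n_intervals = sum(len(t.intervals) for t in back.values())
        assert n_intervals == 2 * n_chim + (len(reads) - n_chim)
        for r in reads:
            assert back[r.id].intervals == r.truth.intervals
            assert back[r.id].junctions == r.truth.junctions

    def test_zero_junction_file(self, clean_reads20k, tmp_path):
        p = tmp_path / "truth.tsv"
        write_truth(clean_reads20k, p)
        assert "junction" not in p.read_text()


def test_pooled_sags_cover_genome(genome50k):
    reads, profiles = pooled_sag_long_reads(
        genome50k, n_sags=5, pooled_mean_depth=40,
        min_union_breadth=0.99, min_pooled_cov=3, seed=1,
    )
    assert len(profiles) == 5
    for p in profiles:
        assert 0.37 <= p.breadth <= 0.63
    assert truth_breadth(reads, len(genome50k)) >= 0.99
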