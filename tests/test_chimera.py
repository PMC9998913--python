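"""Chimera detection and read splitting, with simulator truth as oracle."""

import pytest

from sagcycle.align import all_vs_all, build_index, map_read
from sagcycle.chimera import (
    detect_breakpoints,
    detect_breakpoints_from_overlaps,
    split_reads,
    trim_with_overlaps,
)
from sagcycle.formats import Read, ReadTruth, revcomp
from sagcycle.simulate import make_bias_profile, sample_long_reads

from conftest import random_seq


@pytest.fixture(scope="module")
def truth50k():
    return random_seq(50000, seed=23)


@pytest.fixture(scope="module")
def truth_index(truth50k):
    return build_index([("g", truth50k)])


def _breakpoints_vs_reference(read, index):
    return detect_breakpoints(read, map_read(read, index,
                                             refine_identity=False))


class TestReferenceMode:
    def test_clean_read_no_breakpoints(self, truth50k, truth_index,
                                       make_read):
        r = make_read("r", truth50k[10000:16000])
        assert _breakpoints_vs_reference(r, truth_index) == []

    def test_direct_chimera_breakpoint_position(self, truth50k, truth_index,
                                                make_read):
        r = make_read("c", truth50k[1000:6000] + truth50k[30000:35000])
        bps = _breakpoints_vs_reference(r, truth_index)
        assert len(bps) == 1
        assert abs(bps[0] - 5000) <= 50

    def test_inverted_chimera(self, truth50k, truth_index, make_read):
        r = make_read(
            "c", truth50k[1000:6000] + revcomp(truth50k[30000:35000])
        )
        bps = _breakpoints_vs_reference(r, truth_index)
        assert len(bps) == 1
        assert abs(bps[0] - 5000) <= 50

    def test_foldback_chimera(self, truth50k, truth_index, make_read):
        # second segment re-copies template just behind the first
        r = make_read("c", truth50k[5000:9000] + truth50k[8300:9000])
        bps = _breakpoints_vs_reference(r, truth_index)
        assert len(bps) == 1
        assert abs(bps[0] - 4000) <= 50

    def test_fragmented_reference_spanning_is_concordant(self, truth50k,
                                                         make_read):
        # read runs off contig A onto contig B: not a chimera
        idx = build_index(
            [("A", truth50k[:25000]), ("B", truth50k[25000:])]
        )
        r = make_read("r", truth50k[22000:28000])
        alns = map_read(r, idx, refine_identity=False)
        assert len(alns) == 2
        assert detect_breakpoints(r, alns) == []

    def test_circular_origin_wrap_is_concordant(self, truth50k, make_read):
        idx = build_index([("C", truth50k)])
        r = make_read("r", truth50k[-3000:] + truth50k[:3000])
        alns = map_read(r, idx, refine_identity=False)
        assert detect_breakpoints(
            r, alns, circular_targets=frozenset({"C"})
        ) == []
        # without the circular flag the same read is discordant
        assert len(detect_breakpoints(r, alns)) == 1

    def test_wrong_read_alignments_rejected(self, truth50k, truth_index,
                                            make_read):
        r = make_read("x", truth50k[:5000])
        alns = map_read(("y", truth50k[:5000]), truth_index)
        with pytest.raises(ValueError):
            detect_breakpoints(r, alns)


class TestOverlapMode:
    def test_junction_detected_from_support_drop(self, truth50k, make_read):
        # chimeric read joining two loci; honest reads cover each locus
        chim = make_read("chim", truth50k[2000:5000] + truth50k[30000:33000])
        honest = [
            make_read(f"a{i}", truth50k[s : s + 4000])
            for i, s in enumerate((1000, 1500, 2500, 3000))
        ] + [
            make_read(f"b{i}", truth50k[s : s + 4000])
            for i, s in enumerate((29000, 29500, 30500, 31000))
        ]
        overlaps = all_vs_all([chim, *honest])
        by_chim = [
            o if o.aln.query_id == "chim" else o.flip()
            for o in overlaps
            if "chim" in (o.aln.query_id, o.aln.target_id)
        ]
        bps = detect_breakpoints_from_overlaps(chim, by_chim)
        assert len(bps) == 1
        assert abs(bps[0] - 3000) <= 150


class TestSplitReads:
    def test_one_breakpoint_two_fragments(self, make_read):
        r = make_read("r", "A" * 1500 + "C" * 1500)
        out, rep = split_reads([r], {"r": [1500]})
        assert [x.id for x in out] == ["r:0", "r:1"]
        assert out[0].seq == "A" * 1500 and out[1].seq == "C" * 1500
        assert rep.n_fragments_kept == 2

    def test_short_fragment_dropped(self, make_read):
        r = make_read("r", "A" * 3000)
        out, rep = split_reads([r], {"r": [2700]})
        assert len(out) == 1 and len(out[0].seq) == 2700
        assert rep.n_fragments_dropped == 1

    def test_no_breakpoints_identity(self, make_read):
        r = make_read("r", "A" * 3000)
        out, _ = split_reads([r], {})
        assert out == [r]

    def test_total_bases_never_increase(self, make_read):
        reads = [make_read(f"r{i}", "ACGT" * 800) for i in range(5)]
        bps = {"r0": [1200], "r2": [900, 2000]}
        out, _ = split_reads(reads, bps)
        assert sum(len(r.seq) for r in out) <= sum(len(r.seq) for r in reads)

    def test_truth_junctions_propagated(self):
        r = Read(
            id="r", seq="A" * 4000, quals=(30,) * 4000,
            truth=ReadTruth(junctions=(1500, 3200)),
        )
        out, _ = split_reads([r], {"r": [1500]})
        assert out[0].truth.junctions == ()
        assert out[1].truth.junctions == (1700,)


class TestEndToEndRecall:
    def test_simulated_junction_recall_and_precision(self, genome50k):
        """On error-free simulated reads mapped to the truth genome,
        junction recall >= 0.9 within +/-50 bp and zero breakpoints on
        non-chimeric reads."""
        profile = make_bias_profile(
            genome50k, target_breadth=1.0, skew=0.0, seed=51
        )
        chimeric = [
            r
            for r in sample_long_reads(
                genome50k, profile, mean_depth=25, error_rate=0.0,
                chimera_rate=0.999, seed=52,
            )
            if r.truth.junctions
        ][:500]
        clean = sample_long_reads(
            genome50k, profile, mean_depth=25, error_rate=0.0,
            chimera_rate=0.0, seed=53,
        )[:500]
        index = build_index([("g", genome50k.seq)])
        found = 0
        for r in chimeric:
            bps = detect_breakpoints(
                r,
                map_read(r, index, refine_identity=False),
                circular_targets=frozenset({"g"}),
            )
            (j,) = r.truth.junctions
            if any(abs(b - j) <= 50 for b in bps):
                found += 1
        assert found / len(chimeric) >= 0.9
        false_pos = sum(
            bool(
                detect_breakpoints(
                    r,
                    map_read(r, index, refine_identity=False),
                    circular_targets=frozenset({"g"}),
                )
            )
            for r in clean
        )
        assert false_pos == 0

    def test_splitting_idempotent_on_own_output(self, genome50k):
        profile = make_bias_profile(
            genome50k, target_breadth=1.0, skew=0.0, seed=54
        )
        reads = sample_long_reads(
            genome50k, profile, mean_depth=10, error_rate=0.0,
            chimera_rate=0.2, seed=55,
        )
        overlaps = all_vs_all(reads)
        once, _ = trim_with_overlaps(reads, overlaps)
        overlaps2 = all_vs_all(once)
        twice, rep2 = trim_with_overlaps(once, overlaps2)
        assert sum(len(r.seq) for r in twice) <= sum(len(r.seq) for r in once)
        # no new junction-type breakpoints on already-split reads
        assert rep2.n_breakpoints <= rep2.n_reads * 0.05
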