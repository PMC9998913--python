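"""Minimizer mapping and overlap detection, with an external mapper as an
independent oracle on planted instances."""

import subprocess

import pytest

from sagcycle.align import (
    DEFAULT_K,
    all_vs_all,
    build_index,
    map_read,
    primary_alignment,
)
from sagcycle.formats import Read, revcomp, write_fasta, write_fastq

from conftest import random_seq


@pytest.fixture(scope="module")
def target50k():
    return random_seq(50000, seed=17)


@pytest.fixture(scope="module")
def index50k(target50k):
    return build_index([("t", target50k)])


class TestIndex:
    def test_planted_minimizer_positions(self):
        # every sampled minimizer must report its true position
        seq = random_seq(100, seed=1)
        idx = build_index([("t", seq)])
        from sagcycle.align import minimizers

        pos, codes, _ = minimizers(seq)
        for p, c in zip(pos.tolist(), codes.tolist()):
            assert (0, p, True) in idx.lookup(c) or (
                0, p, False
            ) in idx.lookup(c)

    def test_duplicate_targets_two_postings(self):
        seq = random_seq(500, seed=2)
        idx = build_index([("a", seq), ("b", seq)])
        from sagcycle.align import minimizers

        pos, codes, _ = minimizers(seq)
        hits = idx.lookup(int(codes[0]))
        assert len(hits) == 2
        assert {h[0] for h in hits} == {0, 1}

    def test_homopolymer_single_kmer(self):
        idx = build_index([("h", "A" * 1000)])
        assert idx.n_distinct_kmers == 1

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            build_index([("t", "ACGT" * 100)], k=29)


class TestMapRead:
    def test_planted_substring(self, target50k, index50k):
        sub = target50k[5000:7000]
        (a,) = map_read(("q", sub), index50k)
        assert a.strand == "+"
        assert abs(a.tstart - 5000) <= DEFAULT_K
        assert abs(a.tend - 7000) <= DEFAULT_K
        assert a.identity_est == 1.0

    def test_reverse_complement_strand_symmetry(self, target50k, index50k):
        sub = revcomp(target50k[5000:7000])
        (a,) = map_read(("q", sub), index50k)
        assert a.strand == "-"
        assert abs(a.tstart - 5000) <= DEFAULT_K
        assert abs(a.tend - 7000) <= DEFAULT_K

    def test_random_query_no_hit(self, index50k):
        # expected shared 15-mers ~ 2000*50000/4^15 ~ 0.1, far below chain
        assert map_read(("q", random_seq(2000, seed=99)), index50k) == []

    def test_order_invariance(self, target50k):
        reads = [
            ("a", target50k[1000:4000]),
            ("b", target50k[10000:13000]),
        ]
        idx1 = build_index([("t", target50k)])
        alns = {q: map_read((q, s), idx1) for q, s in reads}
        for q, s in reversed(reads):
            assert map_read((q, s), idx1) == alns[q]

    def test_primary_is_longest_chain(self, target50k, index50k):
        chimera = target50k[2000:5000] + target50k[30000:31500]
        alns = map_read(("c", chimera), index50k)
        assert len(alns) == 2
        p = primary_alignment(alns)
        assert p.qstart < 100  # the 3 kb segment wins

    def test_split_alignments_for_chimera(self, target50k, index50k):
        chimera = target50k[2000:4000] + revcomp(target50k[30000:32000])
        alns = map_read(("c", chimera), index50k)
        strands = {a.strand for a in alns}
        assert strands == {"+", "-"}


class TestOverlaps:
    def test_dovetail_suffix_prefix(self, target50k, make_read):
        r1 = make_read("a", target50k[0:3000])
        r2 = make_read("b", target50k[2000:5000])
        (o,) = all_vs_all([r1, r2])
        assert o.kind == "dovetail"
        assert o.aln.query_id == "a" and o.query_suffix
        assert abs(o.aln.qspan - 1000) <= 2 * DEFAULT_K
        f = o.flip()
        assert f.aln.query_id == "b" and not f.query_suffix

    def test_disjoint_reads_no_overlap(self, target50k, make_read):
        r1 = make_read("a", target50k[0:3000])
        r2 = make_read("b", target50k[10000:13000])
        assert all_vs_all([r1, r2]) == []

    def test_containment_flag(self, target50k, make_read):
        big = make_read("big", target50k[2000:5000])
        small = make_read("small", target50k[2700:3700])
        (o,) = all_vs_all([big, small])
        # reported from the smaller id ('big'); 'small' is the contained one
        assert o.kind == "contained_target"
        assert o.flip().kind == "contained_query"

    def test_reverse_dovetail(self, target50k, make_read):
        r1 = make_read("a", target50k[0:3000])
        r2 = make_read("b", revcomp(target50k[2000:5000]))
        (o,) = all_vs_all([r1, r2])
        assert o.kind == "dovetail"
        assert o.aln.strand == "-"


class TestExternalOracle:
    def test_intervals_agree_with_minimap2(self, tmp_path, target50k):
        """Planted reads: our chain intervals must agree with minimap2's
        primary alignments within a chain-end tolerance."""
        ref = tmp_path / "ref.fasta"
        write_fasta([("t", target50k)], ref)
        reads = [
            Read(
                id=f"r{i}",
                seq=target50k[s : s + 3000] if i % 2 == 0
                else revcomp(target50k[s : s + 3000]),
                quals=(30,) * 3000,
            )
            for i, s in enumerate(range(0, 40000, 4000))
        ]
        fq = tmp_path / "reads.fastq"
        write_fastq(reads, fq)
        out = subprocess.run(
            ["minimap2", "-x", "map-ont", str(ref), str(fq)],
            capture_output=True, text=True, check=True,
        )
        mm2 = {}
        for line in out.stdout.splitlines():
            cols = line.split("\t")
            mm2.setdefault(cols[0], []).append(
                (int(cols[7]), int(cols[8]), cols[4])
            )
        idx = build_index([("t", target50k)])
        for r in reads:
            ours = map_read(r, idx)
            assert ours, f"no alignment for {r.id}"
            best = primary_alignment(ours)
            assert r.id in mm2, f"minimap2 missed {r.id}"
            ts, te, strand = mm2[r.id][0]
            assert best.strand == strand
            assert abs(best.tstart - ts) <= 50
            assert abs(best.tend - te) <= 50
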