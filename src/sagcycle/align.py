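"""Minimizer-anchored read mapping and all-vs-all overlap detection.

The mapper indexes (w,k)-minimizers of the canonical strand, chains shared
minimizers per (target, strand) diagonal band, and reports one alignment
per retained chain.  It trades base-accurate CIGARs for speed: downstream
stages need intervals and an identity estimate, which is refined with a
banded edit-distance alignment (edlib) over the chained spans.

All coordinates are 0-based half-open on the forward strand of each
sequence; a '-' strand alignment means the reverse complement of the query
interval matches the forward target interval.  Anchor collection and
chaining are vectorized: an all-vs-all pass over a few megabases of reads
touches tens of millions of anchors, which rules out per-anchor Python.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np

from .formats import Alignment, Read, revcomp

DEFAULT_K = 15
DEFAULT_W = 10
MIN_ANCHOR_BASES = 100
CHAIN_BAND = 500          # max diagonal drift within one chain, bp
OVERHANG_TOL = 150        # dovetail/containment end slack, bp

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

_U64MAX = np.uint64(0xFFFFFFFFFFFFFFFF)


def _hash_codes(codes: np.ndarray) -> np.ndarray:
    """Invertible 64-bit mixing so minimizer choice is not biased toward
    lexicographically small k-mers."""
    h = codes * np.uint64(0x9E3779B97F4A7C15)
    h ^= h >> np.uint64(29)
    h *= np.uint64(0xBF58476D1CE4E5B9)
    h ^= h >> np.uint64(32)
    return h


def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (canonical code, canonical-is-reverse flag, valid flag) for
    every k-mer start position of ``seq``."""
    arr = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        e = np.empty(0, dtype=np.uint64)
        return e, np.empty(0, bool), np.empty(0, bool)
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = (win < 4).all(axis=1)
    codes64 = win.astype(np.uint64)
    pow_f = np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64)
    pow_r = np.uint64(4) ** np.arange(k, dtype=np.uint64)
    fwd = (codes64 * pow_f).sum(axis=1)
    rev = ((np.uint64(3) - codes64) * pow_r).sum(axis=1)
    is_rev = rev < fwd
    canon = np.where(is_rev, rev, fwd)
    return canon, is_rev, valid


def minimizers(
    seq: str, k: int = DEFAULT_K, w: int = DEFAULT_W
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample (position, canonical code, canonical-is-reverse) minimizers:
    the lowest-hash k-mer of every window of w consecutive k-mers, ties to
    the leftmost.  K-mers containing non-ACGT bases are never sampled."""
    canon, is_rev, valid = _kmer_codes(seq, k)
    n = len(canon)
    if n == 0:
        return np.empty(0, np.int64), np.empty(0, np.uint64), np.empty(0, bool)
    h = _hash_codes(canon)
    h = np.where(valid, h, _U64MAX)
    if n <= w:
        pos = np.array([int(h.argmin())])
    else:
        wins = np.lib.stride_tricks.sliding_window_view(h, w)
        pos = np.unique(wins.argmin(axis=1) + np.arange(len(wins)))
    pos = pos[valid[pos]]
    return pos.astype(np.int64), canon[pos], is_rev[pos]


class MinimizerIndex:
    """Minimizer index over a set of target sequences.

    Postings are stored as flat sorted arrays (by code) so that query
    anchor collection is a searchsorted + repeat, with no Python loop over
    individual anchors.
    """

    def __init__(
        self,
        targets: Sequence[tuple[str, str]],
        k: int = DEFAULT_K,
        w: int = DEFAULT_W,
    ):
        if k > 28:
            raise ValueError("k must be <= 28 to fit a 64-bit code")
        if any(not seq for _, seq in targets):
            raise ValueError("target sequences must be non-empty")
        self.k, self.w = k, w
        self.names = [name for name, _ in targets]
        self.seqs = {name: seq for name, seq in targets}
        if len(self.seqs) != len(targets):
            raise ValueError("duplicate target ids")
        self.lengths = {name: len(seq) for name, seq in targets}

        all_codes, all_tid, all_pos, all_rev = [], [], [], []
        for tid, (_, seq) in enumerate(targets):
            pos, codes, is_rev = minimizers(seq, k, w)
            all_codes.append(codes)
            all_tid.append(np.full(len(pos), tid, dtype=np.int32))
            all_pos.append(pos)
            all_rev.append(is_rev)
        codes = np.concatenate(all_codes) if all_codes else np.empty(0, np.uint64)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._tid = np.concatenate(all_tid)[order] if len(codes) else np.empty(0, np.int32)
        self._pos = np.concatenate(all_pos)[order] if len(codes) else np.empty(0, np.int64)
        self._rev = np.concatenate(all_rev)[order] if len(codes) else np.empty(0, bool)

    def lookup(self, code: int) -> list[tuple[int, int, bool]]:
        """Postings (target index, position, canonical-is-reverse) of one
        minimizer code; mainly for tests and diagnostics."""
        lo = np.searchsorted(self._codes, np.uint64(code), side="left")
        hi = np.searchsorted(self._codes, np.uint64(code), side="right")
        return [
            (int(self._tid[i]), int(self._pos[i]), bool(self._rev[i]))
            for i in range(lo, hi)
        ]

    @property
    def n_distinct_kmers(self) -> int:
        return len(np.unique(self._codes))

    def anchors(
        self, q_pos: np.ndarray, q_codes: np.ndarray, q_rev: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """All (query pos, target idx, target pos, strand+) anchor tuples
        shared between the query minimizers and the index, vectorized."""
        lo = np.searchsorted(self._codes, q_codes, side="left")
        hi = np.searchsorted(self._codes, q_codes, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            e = np.empty(0, np.int64)
            return e, e.astype(np.int32), e, np.empty(0, bool)
        rep_q = np.repeat(np.arange(len(q_codes)), counts)
        # flat posting indices: lo[i] + local offset within each slice
        offs = np.arange(total) - np.repeat(
            np.concatenate(([0], np.cumsum(counts)[:-1])), counts
        )
        flat = np.repeat(lo, counts) + offs
        same = q_rev[rep_q] == self._rev[flat]
        return q_pos[rep_q], self._tid[flat], self._pos[flat], same


def build_index(
    targets: Sequence[tuple[str, str]], k: int = DEFAULT_K, w: int = DEFAULT_W
) -> MinimizerIndex:
    return MinimizerIndex(targets, k, w)


def edlib_identity(a: str, b: str, mode: str = "NW") -> float:
    """Base-level identity of a global (NW) or infix (HW) alignment,
    1 - editDistance / max(len)."""
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode=mode, task="distance")
    d = res["editDistance"]
    if d < 0:
        return 0.0
    return max(0.0, 1.0 - d / max(len(a), len(b)))


def _chains_from_anchors(
    qa: np.ndarray,
    ta_tid: np.ndarray,
    ta_pos: np.ndarray,
    plus: np.ndarray,
    k: int,
    band: int = CHAIN_BAND,
):
    """Group anchors into per-(target, strand) diagonal-band chains.

    Returns a list of (tid, strand, qstart, qend, tstart, tend,
    anchor_bases) tuples; fully vectorized except the final per-chain
    summary loop (chains are few).
    """
    if len(qa) == 0:
        return []
    strand_code = (~plus).astype(np.int64)  # 0 = '+', 1 = '-'
    diag = np.where(plus, ta_pos - qa, -(ta_pos + qa))
    order = np.lexsort((qa, diag, strand_code, ta_tid.astype(np.int64)))
    tid_s = ta_tid[order]
    str_s = strand_code[order]
    diag_s = diag[order]
    qa_s = qa[order]
    ta_s = ta_pos[order]
    newgrp = np.empty(len(order), bool)
    newgrp[0] = True
    newgrp[1:] = (
        (np.diff(tid_s.astype(np.int64)) != 0)
        | (np.diff(str_s) != 0)
        | (np.diff(diag_s) > band)
    )
    starts = np.nonzero(newgrp)[0]
    counts = np.diff(np.append(starts, len(newgrp)))
    chains = []
    for s, c in zip(starts.tolist(), counts.tolist()):
        q = qa_s[s : s + c]
        t = ta_s[s : s + c]
        # anchored query bases: union of [q, q+k) intervals
        qs_sorted = np.sort(q)
        ab = int(np.minimum(np.diff(qs_sorted), k).sum()) + k
        chains.append(
            (
                int(tid_s[s]),
                "+" if str_s[s] == 0 else "-",
                int(q.min()), int(q.max()) + k,
                int(t.min()), int(t.max()) + k,
                ab,
            )
        )
    return chains


def map_read(
    read: Read | tuple[str, str],
    index: MinimizerIndex,
    min_anchor_bases: int = MIN_ANCHOR_BASES,
    refine_identity: bool = True,
) -> list[Alignment]:
    """Map one read against the index; one Alignment per retained chain.

    Chains with fewer than ``min_anchor_bases`` anchored query bases are
    discarded.  Output is sorted by (target_id, tstart, strand, qstart) so
    mapping is deterministic and invariant to read-set order.
    """
    if isinstance(read, Read):
        qid, seq = read.id, read.seq
    else:
        qid, seq = read
    qlen = len(seq)
    pos, codes, is_rev = minimizers(seq, index.k, index.w)
    if len(pos) == 0:
        return []
    qa, tid, tpos, plus = index.anchors(pos, codes, is_rev)
    chains = _chains_from_anchors(qa, tid, tpos, plus, index.k)
    chains = [c for c in chains if c[6] >= min_anchor_bases]
    if not chains:
        return []
    best_ab = max(c[6] for c in chains)
    second_ab = max(
        (c[6] for c in chains if c[6] != best_ab), default=0
    ) if len(chains) > 1 else 0
    mapq = min(60, best_ab - second_ab)
    out = []
    for tid_i, strand, qs, qe, ts, te, ab in chains:
        tname = index.names[tid_i]
        ident = min(1.0, ab / max(qe - qs, 1))
        if refine_identity:
            qseq = seq[qs:qe]
            if strand == "-":
                qseq = revcomp(qseq)
            ident = max(edlib_identity(qseq, index.seqs[tname][ts:te]), 1e-9)
        out.append(
            Alignment(
                query_id=qid, target_id=tname, qlen=qlen, qstart=qs,
                qend=qe, strand=strand, tlen=index.lengths[tname],
                tstart=ts, tend=te, n_anchor_bases=ab, identity_est=ident,
                mapq_proxy=mapq if ab == best_ab else 0,
            )
        )
    out.sort(key=lambda a: (a.target_id, a.tstart, a.strand, a.qstart))
    return out


def primary_alignment(alignments: Sequence[Alignment]) -> Alignment | None:
    """The longest chain (most anchor bases; ties by target/position)."""
    if not alignments:
        return None
    return min(
        alignments,
        key=lambda a: (-a.n_anchor_bases, a.target_id, a.tstart, a.strand),
    )


# --------------------------------------------------------------------------- #
# all-vs-all read overlaps
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class Overlap:
    """A read-to-read overlap: an Alignment plus its geometric class.

    kind is one of 'dovetail', 'contained_query' (query inside target),
    'contained_target' (target inside query), or 'internal' (a local match
    reaching neither end properly -- typically a repeat or a chimera
    signature).  For dovetails, ``query_suffix`` is True when the query's
    suffix is the glued end.
    """

    aln: Alignment
    kind: str
    query_suffix: bool = False

    def flip(self) -> "Overlap":
        """The same overlap seen from the target read's perspective."""
        a = self.aln
        flipped = Alignment(
            query_id=a.target_id, target_id=a.query_id, qlen=a.tlen,
            qstart=a.tstart, qend=a.tend, strand=a.strand, tlen=a.qlen,
            tstart=a.qstart, tend=a.qend, n_anchor_bases=a.n_anchor_bases,
            identity_est=a.identity_est, mapq_proxy=a.mapq_proxy,
        )
        kind = {
            "contained_query": "contained_target",
            "contained_target": "contained_query",
        }.get(self.kind, self.kind)
        if self.kind == "dovetail":
            qsuf = (not self.query_suffix) if a.strand == "+" else self.query_suffix
        else:
            qsuf = False
        return Overlap(aln=flipped, kind=kind, query_suffix=qsuf)


def classify_overlap(aln: Alignment, tol: int = OVERHANG_TOL) -> Overlap:
    """Classify an overlap alignment by which sequence ends it reaches."""
    q_head = aln.qstart <= tol
    q_tail = aln.qlen - aln.qend <= tol
    t_head = aln.tstart <= tol
    t_tail = aln.tlen - aln.tend <= tol
    if q_head and q_tail:
        return Overlap(aln, "contained_query")
    if t_head and t_tail:
        return Overlap(aln, "contained_target")
    if aln.strand == "+":
        if q_tail and t_head:
            return Overlap(aln, "dovetail", query_suffix=True)
        if q_head and t_tail:
            return Overlap(aln, "dovetail", query_suffix=False)
    else:
        if q_tail and t_tail:
            return Overlap(aln, "dovetail", query_suffix=True)
        if q_head and t_head:
            return Overlap(aln, "dovetail", query_suffix=False)
    return Overlap(aln, "internal")


def all_vs_all(
    reads: Sequence[Read],
    k: int = DEFAULT_K,
    w: int = DEFAULT_W,
    min_overlap: int = MIN_ANCHOR_BASES,
    refine_identity: bool = False,
) -> list[Overlap]:
    """All-vs-all read overlaps; one record per unordered read pair and
    chain, reported from the lexicographically smaller read id (use
    Overlap.flip() for the mirrored view).  Self-hits are excluded.
    ``min_overlap`` bounds the overlap *span*; the anchor-base floor only
    rejects sparse spurious chains.  Deterministic and invariant to input
    read order."""
    index = build_index([(r.id, r.seq) for r in reads], k, w)
    anchor_floor = max(MIN_ANCHOR_BASES, int(0.4 * min_overlap))
    out: list[Overlap] = []
    for r in sorted(reads, key=lambda r: r.id):
        alns = map_read(
            r, index, min_anchor_bases=anchor_floor,
            refine_identity=refine_identity,
        )
        for a in alns:
            if a.target_id <= a.query_id:  # self or mirrored pair
                continue
            if min(a.qspan, a.tspan) < min_overlap:
                continue
            out.append(classify_overlap(a))
    return out
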