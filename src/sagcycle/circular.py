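"""Circularity detection and canonical form for circular contigs.

A linear contig assembled from a circular genome carries a duplicated
stretch: its start reappears near its end.  ``circularize`` finds that
duplication (prefix searched against the rest of the contig, the implied
tail verified end-to-end), trims one copy, and rotates the result to a
canonical form so that two assemblies of the same circle compare equal as
plain strings.
"""

from __future__ import annotations

import edlib

from .formats import revcomp


def least_rotation(s: str) -> str:
    """Lexicographically smallest rotation (Booth's algorithm, O(n))."""
    if not s:
        return s
    ss = s + s
    n = len(ss)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return ss[k : k + len(s)]


def canonical_rotation(seq: str) -> str:
    """Canonical form of a circular sequence: the smaller of the least
    rotations of the two strands.  Invariant under rotation and strand
    flip, so circular-sequence equality is plain string equality."""
    return min(least_rotation(seq), least_rotation(revcomp(seq)))


def circularize(
    seq: str,
    min_overlap: int = 500,
    min_identity: float = 0.95,
    canonicalize: bool = True,
) -> tuple[str, bool]:
    """Detect an end-to-end self-overlap and close the contig.

    The first ``min_overlap`` bases are searched downstream; a candidate
    cut at position p is accepted when the whole tail seq[p:] aligns to a
    prefix of the contig at >= min_identity (this rejects mid-contig
    repeat hits).  Returns (sequence, circular flag); when circular, the
    duplicate copy is trimmed and the sequence canonically rotated.
    """
    L = len(seq)
    if L < 2 * min_overlap:
        return seq, False
    max_dist = int(min_overlap * (1.0 - min_identity)) + 1
    # fall back to interior prefix windows in case the very first bases
    # are themselves noisy
    for off in (0, min_overlap, 2 * min_overlap):
        if off + 2 * min_overlap >= L // 2:
            break
        pattern = seq[off : off + min_overlap]
        text = seq[off + min_overlap :]
        res = edlib.align(pattern, text, mode="HW", task="locations",
                          k=max_dist)
        if res["editDistance"] < 0:
            continue
        # prefer the rightmost verifying cut (least trimmed sequence);
        # a hit of seq[off:off+mo] at text offset s implies circle period
        # P = mo + s: seq[x] ~ seq[x+P] for x >= off
        starts = sorted({loc[0] for loc in res["locations"]}, reverse=True)
        for s in starts:
            period = min_overlap + s
            dup_len = L - period
            if dup_len < int(0.3 * min_overlap) or dup_len > L // 2 + min_overlap:
                continue
            dup = seq[period + off :]
            if not dup:
                continue
            chk = edlib.align(
                dup, seq[off : off + len(dup) + 50], mode="SHW",
                task="distance",
            )
            if chk["editDistance"] < 0:
                continue
            if 1.0 - chk["editDistance"] / max(len(dup), 1) >= min_identity:
                closed = seq[:period]
                if canonicalize:
                    closed = canonical_rotation(closed)
                return closed, True
    return seq, False
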