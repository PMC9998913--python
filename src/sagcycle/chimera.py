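"""Detection and splitting of chimeric long reads before assembly.

MDA joins non-adjacent (possibly inverted) genomic segments into single
molecules; assembling such reads produces misjoins.  Two detection paths
are provided:

* reference mode (a draft assembly exists): a read's mappings are scanned
  along the query; a breakpoint is called between query-adjacent segments
  that are discordant (different targets, different strands, or a
  target-coordinate jump inconsistent with the query gap), and inside long
  unmapped stretches flanked by solid mappings.

* overlap mode (no reference yet): a breakpoint is called where overlap
  support from other reads drops to zero while both flanks are supported,
  the minimal analogue of support-based trimming.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .align import Overlap
from .formats import Alignment, Read, ReadTruth

MAX_QUERY_GAP = 200       # max query gap between discordant segments, bp
MAX_COORD_JUMP = 1000     # forward target jump vs query gap tolerance, bp
NEG_JUMP_TOL = 100        # backward target jump tolerance (indel slack), bp
MIN_UNCOVERED = 500       # unmapped internal stretch that implies a junction
MIN_FRAGMENT = 1000       # fragments below this are discarded after splitting
SPAN_MARGIN = 100         # overlap mode: a read spans a position by >= this
END_TRIM_MIN = 250        # unsupported read-end runs longer than this are cut
MIN_INTERIOR_RUN = 120    # interior zero-support runs below this are noise


@dataclass
class TrimReport:
    n_reads: int = 0
    n_with_breakpoints: int = 0
    n_breakpoints: int = 0
    n_fragments_kept: int = 0
    n_fragments_dropped: int = 0


BOUNDARY_TOL = 200        # alignments this close to a contig end may simply
                          # run off a fragmented reference


def _exits_target(a: Alignment, tol: int = BOUNDARY_TOL) -> bool:
    """The alignment reaches its target's boundary in the direction the
    read continues (rightward on the query)."""
    if a.strand == "+":
        return a.tlen - a.tend <= tol
    return a.tstart <= tol


def _enters_target(a: Alignment, tol: int = BOUNDARY_TOL) -> bool:
    """The alignment starts at its target's boundary in the direction the
    read arrives from (leftward on the query)."""
    if a.strand == "+":
        return a.tstart <= tol
    return a.tlen - a.tend <= tol


def detect_breakpoints(
    read: Read,
    alignments: Sequence[Alignment],
    min_fragment: int = MIN_FRAGMENT,
    circular_targets: frozenset[str] = frozenset(),
) -> list[int]:
    """Breakpoint offsets on ``read`` from its mappings to a reference.

    A breakpoint is called between query-adjacent segments that are
    discordant, unless the discordance is explained by reference
    fragmentation: a read running off the end of one contig and onto the
    start of another is concordant, as is a wrap across the origin of a
    circular reference contig.  Internal uncovered stretches flanked by
    solid same-target mappings are cut only when the reference *jumps*
    (skips more target than query), never when the read merely carries
    sequence the reference lacks -- those reads are the point of the
    debiasing cycle.
    """
    for a in alignments:
        if a.query_id != read.id:
            raise ValueError(
                f"alignment of {a.query_id} passed for read {read.id}"
            )
    if not alignments:
        return []
    segs = sorted(alignments, key=lambda a: (a.qstart, a.qend))
    L = len(read.seq)
    breakpoints: set[int] = set()

    for a, b in zip(segs, segs[1:]):
        gap = b.qstart - a.qend
        if gap > MAX_QUERY_GAP:
            continue
        if a.target_id != b.target_id or a.strand != b.strand:
            # fragmented-reference spanning is concordant
            if _exits_target(a) and _enters_target(b):
                continue
            discordant = True
        else:
            if a.strand == "+":
                tjump = b.tstart - a.tend
            else:
                tjump = a.tstart - b.tend
            if (
                a.target_id in circular_targets
                and tjump < 0
                and abs(tjump + a.tlen - gap) <= MAX_COORD_JUMP
            ):
                continue  # wrap across the circular origin
            # a backward jump re-copies template already passed: the
            # fold-back chimera signature, discordant at any magnitude
            discordant = (
                tjump - gap > MAX_COORD_JUMP or tjump < -NEG_JUMP_TOL
            )
        if discordant:
            bp = (a.qend + max(b.qstart, a.qend)) // 2
            if 0 < bp < L:
                breakpoints.add(bp)

    # long internal uncovered stretches: chimeric only when the reference
    # coordinates jump forward past more sequence than the query skipped
    by_pos = segs
    for a, b in zip(by_pos, by_pos[1:]):
        gap = b.qstart - a.qend
        if gap <= MIN_UNCOVERED:
            continue
        if (a.qend - a.qstart) < min_fragment or (
            b.qend - b.qstart
        ) < min_fragment:
            continue
        if a.target_id == b.target_id and a.strand == b.strand:
            if a.strand == "+":
                tjump = b.tstart - a.tend
            else:
                tjump = a.tstart - b.tend
            if tjump > gap + MAX_COORD_JUMP:
                bp = (a.qend + b.qstart) // 2
                if 0 < bp < L:
                    breakpoints.add(bp)
    return sorted(breakpoints)


def detect_breakpoints_from_overlaps(
    read: Read,
    overlaps: Sequence[Overlap],
    min_support: int = 2,
    span_margin: int = SPAN_MARGIN,
) -> list[int]:
    """Overlap-mode breakpoints: positions where the number of other reads
    spanning by >= span_margin on both sides drops to zero while both
    flanks reach support >= min_support.  ``overlaps`` are this read's
    overlaps, oriented with the read as query (flip() if needed)."""
    L = len(read.seq)
    support = np.zeros(L + 1, dtype=np.int32)
    for o in overlaps:
        a = o.aln
        if a.query_id != read.id:
            raise ValueError(
                f"overlap of {a.query_id} passed for read {read.id}"
            )
        lo, hi = a.qstart + span_margin, a.qend - span_margin
        if hi > lo:
            support[lo] += 1
            support[hi] -= 1
    support = np.cumsum(support[:-1])
    breakpoints: list[int] = []
    zero = support == 0
    if not zero.any() or zero.all():
        return []
    # runs of zero support strictly inside the read
    edges = np.flatnonzero(np.diff(zero.astype(np.int8)))
    runs = []
    start = 0 if zero[0] else None
    for e in edges.tolist():
        if zero[e + 1]:
            start = e + 1
        else:
            if start is not None:
                runs.append((start, e + 1))
            start = None
    if start is not None:
        runs.append((start, L))
    for s, e in runs:
        left = support[:s]
        right = support[e:]
        if s == 0 or e == L:
            # unsupported read END: junk/chimeric tails get trimmed off
            # (the margin keeps ordinary sampling-edge overhangs intact)
            if e - s <= END_TRIM_MIN:
                continue
            if s == 0 and e < L and right.max(initial=0) >= min_support:
                breakpoints.append(e)
            elif e == L and s > 0 and left.max(initial=0) >= min_support:
                breakpoints.append(s)
            continue
        if e - s < MIN_INTERIOR_RUN:
            # a dip this short is the span-margin shadow of a thin but
            # real bridge (two read groups nearly abutting), not a
            # junction: a true chimeric junction shadows ~2x the margin
            continue
        if left.max(initial=0) >= min_support and right.max(initial=0) >= min_support:
            bp = (s + e) // 2
            if 0 < bp < L:
                breakpoints.append(bp)
    return sorted(breakpoints)


def split_reads(
    reads: Sequence[Read],
    breakpoints: dict[str, list[int]],
    min_fragment: int = MIN_FRAGMENT,
) -> tuple[list[Read], TrimReport]:
    """Cut each read at its breakpoints; fragments shorter than
    ``min_fragment`` are discarded.  Fragment ids get deterministic
    ':<i>' suffixes; reads without breakpoints pass through unchanged.
    Simulation truth intervals are propagated per fragment."""
    report = TrimReport(n_reads=len(reads))
    out: list[Read] = []
    for read in reads:
        bps = sorted(b for b in breakpoints.get(read.id, []) if 0 < b < len(read.seq))
        if not bps:
            out.append(read)
            report.n_fragments_kept += 1
            continue
        report.n_with_breakpoints += 1
        report.n_breakpoints += len(bps)
        cuts = [0, *bps, len(read.seq)]
        for i, (s, e) in enumerate(zip(cuts, cuts[1:])):
            if e - s < min_fragment:
                report.n_fragments_dropped += 1
                continue
            quals = read.quals[s:e] if read.quals is not None else None
            truth = None
            if read.truth is not None:
                juncs = tuple(
                    j - s for j in read.truth.junctions if s < j < e
                )
                truth = ReadTruth(intervals=read.truth.intervals, junctions=juncs)
            out.append(
                Read(
                    id=f"{read.id}:{i}", seq=read.seq[s:e], quals=quals,
                    source_sag=read.source_sag, truth=truth,
                )
            )
            report.n_fragments_kept += 1
    return out, report


def trim_with_reference(
    reads: Sequence[Read],
    alignments_by_read: dict[str, list[Alignment]],
    min_fragment: int = MIN_FRAGMENT,
    circular_targets: frozenset[str] = frozenset(),
) -> tuple[list[Read], TrimReport]:
    bps = {
        r.id: detect_breakpoints(
            r, alignments_by_read.get(r.id, []), min_fragment,
            circular_targets=circular_targets,
        )
        for r in reads
    }
    return split_reads(reads, bps, min_fragment)


def trim_with_overlaps(
    reads: Sequence[Read],
    overlaps: Sequence[Overlap],
    min_fragment: int = MIN_FRAGMENT,
) -> tuple[list[Read], TrimReport]:
    by_read: dict[str, list[Overlap]] = {r.id: [] for r in reads}
    for o in overlaps:
        if o.aln.query_id in by_read:
            by_read[o.aln.query_id].append(o)
        f = o.flip()
        if f.aln.query_id in by_read:
            by_read[f.aln.query_id].append(f)
    bps = {
        r.id: detect_breakpoints_from_overlaps(r, by_read[r.id])
        for r in reads
    }
    return split_reads(reads, bps, min_fragment)
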