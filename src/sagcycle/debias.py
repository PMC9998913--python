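"""Depth computation and depth-capped read subsampling.

MDA amplification concentrates sequencing depth on a few regions; capping
retained depth (default 50x) against the current draft frees the assembler
from the over-amplified regions and lets under-represented ones surface in
the next cycle.

The subsampling rule is a greedy sweep over primary alignments sorted by
(target, start, -aligned length, read id): a read is retained iff at least
one position in its span still has retained depth below the cap.  Two
guarantees follow directly from the rule:

P1  every position's final depth >= min(cap, its unsubsampled depth) --
    the sweep cannot starve a position while any read covering it is
    still rejected, because that read would have seen the position under
    the cap and been retained;
P2  every rejected read's span lies entirely in positions whose final
    depth >= cap (depth at those positions only grows after rejection).

Positions may end above the cap where a read was accepted for the sake of
a neighbouring low-depth position; that slack is intended.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .align import primary_alignment
from .formats import Alignment, Read


@dataclass
class DepthProfile:
    """Integer retained-read depth per position, per target contig."""

    depths: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, target_id: str) -> np.ndarray:
        return self.depths[target_id]

    def mean(self, target_id: str) -> float:
        return float(self.depths[target_id].mean())

    def max(self, target_id: str) -> int:
        return int(self.depths[target_id].max())


@dataclass
class SubsampleReport:
    n_mapped: int = 0
    n_unmapped_retained: int = 0
    n_retained: int = 0
    n_rejected: int = 0
    per_target: dict[str, dict] = field(default_factory=dict)


def compute_depth(
    alignments: Sequence[Alignment],
    target_lengths: Mapping[str, int],
) -> DepthProfile:
    """Per-position depth: the number of alignments whose target interval
    contains the position.  The caller is responsible for passing one
    primary alignment per read (see :func:`primary_by_read`)."""
    deltas = {
        t: np.zeros(l + 1, dtype=np.int32) for t, l in target_lengths.items()
    }
    for a in alignments:
        if a.target_id not in deltas:
            raise KeyError(f"unknown target id {a.target_id!r}")
        deltas[a.target_id][a.tstart] += 1
        deltas[a.target_id][a.tend] -= 1
    return DepthProfile(
        depths={t: np.cumsum(d[:-1]).astype(np.int32) for t, d in deltas.items()}
    )


def primary_by_read(
    alignments_by_read: Mapping[str, Sequence[Alignment]],
) -> dict[str, Alignment]:
    """One primary (longest-chain) alignment per mapped read."""
    out = {}
    for rid, alns in alignments_by_read.items():
        p = primary_alignment(alns)
        if p is not None:
            out[rid] = p
    return out


def subsample_to_cap(
    reads: Sequence[Read],
    alignments_by_read: Mapping[str, Sequence[Alignment]],
    target_lengths: Mapping[str, int],
    cap: int = 50,
) -> tuple[list[str], DepthProfile, SubsampleReport]:
    """Greedy depth-capped subsampling; returns (retained read ids, final
    retained-depth profile, report).

    Unmapped reads are always retained: they may cover genomic regions
    absent from the current reference -- exactly the regions debiasing is
    meant to recover.  The report flags how many those were.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    primaries = primary_by_read(alignments_by_read)
    read_ids = [r.id for r in reads]

    before = compute_depth(
        [primaries[r] for r in read_ids if r in primaries], target_lengths
    )
    order = sorted(
        (r for r in read_ids if r in primaries),
        key=lambda r: (
            primaries[r].target_id,
            primaries[r].tstart,
            -(primaries[r].tend - primaries[r].tstart),
            r,
        ),
    )
    depth = {t: np.zeros(l, dtype=np.int32) for t, l in target_lengths.items()}
    retained_mapped: set[str] = set()
    for rid in order:
        a = primaries[rid]
        span = depth[a.target_id][a.tstart : a.tend]
        if (span < cap).any():
            span += 1
            retained_mapped.add(rid)

    retained = [
        r for r in read_ids if r not in primaries or r in retained_mapped
    ]
    report = SubsampleReport(
        n_mapped=len(primaries),
        n_unmapped_retained=len(read_ids) - len(primaries),
        n_retained=len(retained),
        n_rejected=len(read_ids) - len(retained),
    )
    after = DepthProfile(depths=depth)
    for t in target_lengths:
        report.per_target[t] = {
            "mean_before": round(before.mean(t), 2),
            "max_before": before.max(t),
            "mean_after": round(after.mean(t), 2),
            "max_after": after.max(t),
        }
    return retained, after, report
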