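"""Long-read quality filtering: headcrop, then length and mean-quality
thresholds (defaults: crop 75 bp, keep reads >= 1000 bp with mean quality
>= Q10).  Thresholds are inclusive -- reads *below* them are removed, so
boundary reads survive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .formats import PipelineConfig, Read, ReadTruth


@dataclass
class FilterReport:
    n_input: int = 0
    n_kept: int = 0
    n_too_short: int = 0
    n_low_quality: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_too_short + self.n_low_quality


def headcrop(read: Read, n: int) -> Read:
    """Remove the first ``n`` bases (and qualities); simulation truth
    junction offsets are shifted by -n and clipped to the remaining read."""
    if n < 0:
        raise ValueError("headcrop must be >= 0")
    if n == 0 or not read.seq:
        return read
    seq = read.seq[n:]
    quals = read.quals[n:] if read.quals is not None else None
    truth = read.truth
    if truth is not None:
        junctions = tuple(
            j - n for j in truth.junctions if 0 < j - n < len(seq)
        )
        intervals = []
        crop_left = n
        for s, e, strand in truth.intervals:
            seg = e - s
            if crop_left >= seg:
                crop_left -= seg
                continue
            if strand == "+":
                intervals.append((s + crop_left, e, strand))
            else:
                intervals.append((s, e - crop_left, strand))
            crop_left = 0
        truth = ReadTruth(intervals=tuple(intervals), junctions=junctions)
    if not seq:
        truth = None
    return Read(
        id=read.id, seq=seq, quals=quals,
        source_sag=read.source_sag, truth=truth,
    )


def mean_quality(read: Read) -> float:
    """Phred-scaled mean error probability: -10*log10(mean 10^(-q/10)).

    This probability-space mean weighs low-quality stretches more heavily
    than an arithmetic mean of Phred scores would.
    """
    if not read.seq:
        raise ValueError("mean_quality of an empty read is undefined")
    if read.quals is None:
        raise ValueError(f"read {read.id} has no qualities")
    q = np.asarray(read.quals, dtype=float)
    return float(-10.0 * np.log10(np.mean(10.0 ** (-q / 10.0))))


def filter_reads(
    reads: Sequence[Read], config: PipelineConfig | None = None
) -> tuple[list[Read], FilterReport]:
    """Headcrop each read, then keep it iff length >= min_len and mean
    quality >= min_q.  Order preserved; report counts sum to the input."""
    cfg = config or PipelineConfig()
    report = FilterReport(n_input=len(reads))
    kept: list[Read] = []
    for read in reads:
        r = headcrop(read, cfg.headcrop)
        if len(r.seq) < cfg.min_len:
            report.n_too_short += 1
            continue
        # epsilon keeps the inclusive boundary robust to log-space rounding
        if r.quals is not None and mean_quality(r) < cfg.min_q - 1e-9:
            report.n_low_quality += 1
            continue
        kept.append(r)
    report.n_kept = len(kept)
    return kept, report
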