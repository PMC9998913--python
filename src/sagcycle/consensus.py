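"""Pileup majority consensus over a backbone sequence.

Reads (or read segments) are placed approximately on the backbone, each is
re-aligned to its local window with a banded edit-distance alignment, and
the alignment paths are accumulated into per-column base/deletion votes and
per-junction single-base insertion votes.  A majority rule then rewrites
the backbone.  The same engine serves two callers with different
thresholds:

* assembler consensus over a read layout (min_cov=1, min_frac=0.5): any
  majority wins, zero-coverage columns keep the backbone base;
* short-read polishing (min_cov=4, min_frac=0.7): conservative -- a
  position is only touched with real evidence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np

_CIG_RE = re.compile(r"(\d+)([=XIDM])")
_IDX_BASE = "ACGT"
_BASE_CODE_ARR = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE_ARR[ord(_b)] = _i


@dataclass(frozen=True)
class Placement:
    """A sequence believed to match backbone[start:end] approximately."""

    seq: str
    start: int
    end: int


class Pileup:
    def __init__(self, length: int):
        self.base = np.zeros((length, 4), dtype=np.int32)
        self.dele = np.zeros(length, dtype=np.int32)
        self.cov = np.zeros(length, dtype=np.int32)
        # votes for inserting a single base *before* backbone column i
        self.ins = np.zeros((length + 1, 4), dtype=np.int32)
        self.ins_cov = np.zeros(length + 1, dtype=np.int32)


def _accumulate(
    pile: Pileup, backbone: str, placement: Placement, pad: int
) -> bool:
    """Align one placed sequence to its padded backbone window and add its
    votes; returns False when the alignment failed badly."""
    lo = max(0, placement.start - pad)
    hi = min(len(backbone), placement.end + pad)
    window = backbone[lo:hi]
    if not window or not placement.seq:
        return False
    res = edlib.align(placement.seq, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return False
    t = lo + res["locations"][0][0]
    q = 0
    codes = _BASE_CODE_ARR[
        np.frombuffer(placement.seq.encode(), dtype=np.uint8)
    ]
    first = True
    for num, op in _CIG_RE.findall(res["cigar"]):
        n = int(num)
        if op in "=XM":
            run = codes[q : q + n]
            ok = run < 4
            np.add.at(pile.base, (np.arange(t, t + n)[ok], run[ok]), 1)
            pile.cov[t : t + n] += 1
            q += n
            t += n
        elif op == "D":  # in backbone, absent from read: deletion votes
            pile.dele[t : t + n] += 1
            pile.cov[t : t + n] += 1
            t += n
        elif op == "I":  # in read, absent from backbone
            if not first and codes[q] < 4:  # leading I is clipping artifact
                pile.ins[t, codes[q]] += 1
            q += n
        first = False
    return True


def _spanning_cov(pile: Pileup) -> None:
    """Insertion coverage: reads spanning the junction between columns
    i-1 and i, approximated by min of the neighbouring column coverages."""
    c = pile.cov
    pile.ins_cov[0] = c[0] if len(c) else 0
    pile.ins_cov[-1] = c[-1] if len(c) else 0
    if len(c) > 1:
        pile.ins_cov[1:-1] = np.minimum(c[:-1], c[1:])


def pileup_consensus(
    backbone: str,
    placements: Sequence[Placement],
    min_cov: int = 1,
    min_frac: float = 0.5,
    pad: int = 200,
) -> str:
    """One round of pileup majority over ``backbone``.

    A column with coverage < min_cov keeps its backbone base.  Otherwise
    the base is replaced by the majority base when its vote fraction is
    >= min_frac (strictly > 1/2 always holds at min_frac >= 0.5 with the
    argmax tie-break to the backbone base); a deletion or single-base
    insertion is applied when supported by >= min_frac of spanning reads.
    """
    if not backbone:
        return backbone
    pile = Pileup(len(backbone))
    for p in placements:
        _accumulate(pile, backbone, p, pad)
    _spanning_cov(pile)

    out: list[str] = []
    n = len(backbone)
    base_tot = pile.base.sum(axis=1)
    best_idx = pile.base.argmax(axis=1)
    best_votes = pile.base.max(axis=1)
    ins_best = pile.ins.argmax(axis=1)
    ins_votes = pile.ins.max(axis=1)
    for i in range(n):
        cov = int(pile.cov[i])
        icov = int(pile.ins_cov[i])
        if icov >= min_cov and ins_votes[i] >= min_frac * icov and ins_votes[i] > 0:
            out.append(_IDX_BASE[ins_best[i]])
        if cov < min_cov:
            out.append(backbone[i])
            continue
        if pile.dele[i] >= min_frac * cov and pile.dele[i] > best_votes[i]:
            continue  # majority says this backbone base does not exist
        if best_votes[i] > 0 and best_votes[i] >= min_frac * cov:
            out.append(_IDX_BASE[best_idx[i]])
        else:
            out.append(backbone[i])
    return "".join(out)
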