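"""Short-read polishing of consensus contigs and N-gap filling.

Polishing maps short reads (k=21, w=5 minimizers), builds a pileup per
contig, and applies conservative majority corrections: a base is replaced
only at coverage >= 4 with >= 70% agreement, and single-base indels need
the same support among spanning reads.  Clean input is therefore a fixed
point.  Circular contigs get an extra seam pass at a half rotation so
corrections can span the origin, and are emitted in canonical rotation.

Gap filling replaces maximal N-runs when a short-read contig anchors on
both flanks (>= 500 bp at >= 99% identity by default) in consistent
orientation with a plausible span; ambiguous fillers are left alone and
logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import edlib

from .align import build_index, map_read
from .circular import canonical_rotation, circularize
from .consensus import Placement, pileup_consensus
from .formats import Assembly, Contig, PipelineConfig, Read, revcomp

POLISH_K = 21
POLISH_W = 5
POLISH_MIN_COV = 4
POLISH_MIN_FRAC = 0.7
POLISH_MIN_READ_LEN = 50


@dataclass
class GapFillReport:
    n_gaps: int = 0
    n_filled: int = 0
    n_ambiguous: int = 0
    n_unspanned: int = 0
    events: list[dict] = field(default_factory=list)


def _placements_for(
    contig: Contig, reads: Sequence[Read], index
) -> list[Placement]:
    """Map each read and convert its best chain on this contig into a
    clipped placement: the query interval is extended to the full read
    where the target permits, so votes never include unaligned overhang."""
    placements: list[Placement] = []
    L = len(contig.seq)
    for r in reads:
        for a in map_read(r, index, refine_identity=False):
            if a.target_id != contig.id:
                continue
            qs, qe, ts, te = a.qstart, a.qend, a.tstart, a.tend
            if a.strand == "+":
                ext = min(qs, ts)
                qs, ts = qs - ext, ts - ext
                ext = min(a.qlen - qe, L - te)
                qe, te = qe + ext, te + ext
                seq = r.seq[qs:qe]
            else:
                ext = min(a.qlen - qe, ts)
                qe, ts = qe + ext, ts - ext
                ext = min(qs, L - te)
                qs, te = qs - ext, te + ext
                seq = revcomp(r.seq[qs:qe])
            if qe - qs >= POLISH_MIN_READ_LEN // 2:
                placements.append(Placement(seq, ts, te))
    return placements


def _polish_linear(
    seq: str, contig_id: str, reads: Sequence[Read]
) -> str:
    index = build_index([(contig_id, seq)], k=POLISH_K, w=POLISH_W)
    placements = _placements_for(Contig(contig_id, seq), reads, index)
    return pileup_consensus(
        seq, placements, min_cov=POLISH_MIN_COV, min_frac=POLISH_MIN_FRAC,
        pad=30,
    )


def polish(
    contigs: Assembly | Sequence[Contig],
    short_reads: Sequence[Read],
    rounds: int = 2,
) -> Assembly:
    """Pileup-majority polishing, ``rounds`` passes per contig."""
    if isinstance(contigs, Assembly):
        contig_list = contigs.contigs
        cycle_index = contigs.cycle_index
        provenance = dict(contigs.provenance)
    else:
        contig_list = list(contigs)
        cycle_index = 0
        provenance = {}
    reads = [r for r in short_reads if len(r.seq) >= POLISH_MIN_READ_LEN]
    out: list[Contig] = []
    for c in contig_list:
        seq = c.seq
        for _ in range(max(rounds, 0)):
            new = _polish_linear(seq, c.id, reads)
            if c.circular and len(new) >= 2:
                h = len(new) // 2
                rotated = new[h:] + new[:h]
                rotated = _polish_linear(rotated, c.id, reads)
                new = rotated  # rotation is irrelevant: canonicalized below
            if new == seq:
                break
            seq = new
        if c.circular:
            seq = canonical_rotation(seq)
        out.append(Contig(id=c.id, seq=seq, circular=c.circular))
    provenance["polished_rounds"] = rounds
    return Assembly(contigs=out, cycle_index=cycle_index,
                    provenance=provenance)


def finish_assembly(
    consensus: Assembly,
    short_reads: Sequence[Read],
    sr_contigs: Sequence[tuple[str, str]] | None = None,
    config: PipelineConfig | None = None,
    rounds: int = 2,
) -> tuple[Assembly, GapFillReport | None]:
    """Polish, re-attempt circularization, and (optionally) fill gaps.

    Circularity is re-tested after polishing because residual consensus
    noise concentrated at contig ends -- typically single-coverage unitig
    margins -- can push an end-to-end overlap just past the identity
    threshold before polishing; once polished, the overlap is clean.
    Newly circularized contigs get one extra polish round so the seam is
    corrected too.
    """
    cfg = config or PipelineConfig()
    polished = polish(consensus, short_reads, rounds=rounds)
    out: list[Contig] = []
    any_closed = False
    for c in polished.contigs:
        if not c.circular:
            seq, circ = circularize(
                c.seq, cfg.circular_min_overlap, cfg.circular_min_identity
            )
            if circ:
                any_closed = True
                out.append(Contig(id=c.id, seq=seq, circular=True))
                continue
        out.append(c)
    result = Assembly(contigs=out, cycle_index=polished.cycle_index,
                     provenance=dict(polished.provenance))
    if any_closed:
        result = polish(result, short_reads, rounds=1)
    gap_report = None
    if sr_contigs:
        result, gap_report = gap_fill(
            result, sr_contigs,
            min_flank=cfg.gapfill_min_flank,
            min_identity=cfg.gapfill_min_identity,
        )
    return result, gap_report


# --------------------------------------------------------------------------- #
# gap filling
# --------------------------------------------------------------------------- #

def _n_runs(seq: str) -> list[tuple[int, int]]:
    runs = []
    i = 0
    while i < len(seq):
        if seq[i] == "N":
            j = i
            while j < len(seq) and seq[j] == "N":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _locate(pattern: str, text: str, max_dist: int):
    """Best locations of ``pattern`` inside ``text`` within max_dist."""
    if not pattern or not text:
        return None
    res = edlib.align(pattern, text, mode="HW", task="locations", k=max_dist)
    if res["editDistance"] < 0:
        return None
    return res


def gap_fill(
    contigs: Assembly | Sequence[Contig],
    sr_contigs: Sequence[tuple[str, str]],
    min_flank: int = 500,
    min_identity: float = 0.99,
) -> tuple[Assembly, GapFillReport]:
    """Replace N-runs with short-read contig sequence anchored on both
    flanks.  Never touches non-N bases; ambiguous gaps (multiple
    consistent fillers with different sequences) stay unfilled."""
    if isinstance(contigs, Assembly):
        contig_list = contigs.contigs
        cycle_index = contigs.cycle_index
    else:
        contig_list = list(contigs)
        cycle_index = 0
    report = GapFillReport()
    out: list[Contig] = []
    for c in contig_list:
        seq = c.seq
        # process right-to-left so coordinates stay valid after splices
        for (s, e) in reversed(_n_runs(seq)):
            report.n_gaps += 1
            nrun = e - s
            left = seq[max(0, s - min_flank) : s]
            right = seq[e : e + min_flank]
            if "N" in left or "N" in right or len(left) < min_flank or len(
                right
            ) < min_flank:
                report.n_unspanned += 1
                report.events.append(
                    {"contig": c.id, "gap": [s, e], "status": "short_flank"}
                )
                continue
            max_dist = int(min_flank * (1 - min_identity)) + 1
            fillers: list[str] = []
            for sr_id, sr_seq in sr_contigs:
                for orient, oseq in (("+", sr_seq), ("-", revcomp(sr_seq))):
                    lres = _locate(left, oseq, max_dist)
                    rres = _locate(right, oseq, max_dist)
                    if lres is None or rres is None:
                        continue
                    l_end = lres["locations"][0][1] + 1
                    r_start = rres["locations"][0][0]
                    span = r_start - l_end
                    if span < 0 or span > 2 * max(nrun, 1):
                        continue
                    fillers.append(oseq[l_end:r_start])
            unique = sorted(set(fillers))
            if not fillers:
                report.n_unspanned += 1
                report.events.append(
                    {"contig": c.id, "gap": [s, e], "status": "unspanned"}
                )
            elif len(unique) > 1:
                report.n_ambiguous += 1
                report.events.append(
                    {"contig": c.id, "gap": [s, e], "status": "ambiguous",
                     "n_candidates": len(unique)}
                )
            else:
                seq = seq[:s] + unique[0] + seq[e:]
                report.n_filled += 1
                report.events.append(
                    {"contig": c.id, "gap": [s, e], "status": "filled",
                     "filler_len": len(unique[0])}
                )
        out.append(Contig(id=c.id, seq=seq, circular=c.circular))
    return (
        Assembly(contigs=out, cycle_index=cycle_index,
                 provenance={"stage": "gap_fill"}),
        report,
    )
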