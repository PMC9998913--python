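"""Consensus construction from the intermediate assemblies of a run.

Each debias/reassemble cycle leaves an intermediate assembly whose contig
ends fall at different genomic positions.  The consensus stage picks the
representative assembly (fewest contigs), then stitches its contigs
together wherever two of their ends co-locate on a single contig of
another cycle's assembly, splicing the linking sequence from that donor.
No external reference genome is involved: the donors are the run's own
intermediate assemblies.  A join that would close a chain onto itself is
treated as evidence of circularity; every output contig is additionally
tested for a direct end-to-end self-overlap.

Join geometry.  An anchor is a representative contig end located on a
donor contig (>= 1 kb, >= 95% identity, reaching within 200 bp of the
contig end).  On the donor's forward strand a link reads

    [image of contig A] --gap--> [image of contig B]

where A's gap-facing end is its tail if its image is forward (else its
head), and symmetrically for B.  A chain that exits a contig through a
link's left side therefore walks the donor left-to-right (gap spliced
forward); through the right side, right-to-left (gap reverse-complemented).
Slightly overlapping images (up to 2 kb) trim the incoming contig instead
of splicing a gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .align import build_index, map_read
from .circular import canonical_rotation, circularize
from .formats import Assembly, Contig, revcomp

MIN_ANCHOR_LEN = 1000      # bp of a representative end on the donor
MIN_ANCHOR_IDENTITY = 0.95
END_SLACK = 200            # how far from a contig end an anchor may start
MAX_END_OVERLAP = 2000     # donor images may overlap this much (trimmed)


@dataclass
class Join:
    left_contig: str
    left_end: str            # 'head' | 'tail'
    right_contig: str
    right_end: str
    donor_cycle: int
    donor_contig: str
    anchor_len: int
    identity: float
    accepted: bool
    reason: str = ""


@dataclass
class ScaffoldReport:
    joins: list[Join] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return sum(j.accepted for j in self.joins)


def select_representative(assemblies: Sequence[Assembly]) -> Assembly:
    """The assembly with the fewest contigs; ties broken by largest total
    length, then by highest cycle index."""
    non_empty = [a for a in assemblies if a.n_contigs > 0]
    if not non_empty:
        raise ValueError("all assemblies are empty")
    return min(
        non_empty,
        key=lambda a: (a.n_contigs, -a.total_length, -a.cycle_index),
    )


@dataclass(frozen=True)
class _Anchor:
    contig: str
    end: str                  # 'head' | 'tail'
    donor: str
    dstart: int
    dend: int
    orient: str               # image orientation of the contig on the donor
    length: int
    identity: float


def _faces_right(a: _Anchor) -> bool:
    return (a.orient == "+" and a.end == "tail") or (
        a.orient == "-" and a.end == "head"
    )


def _faces_left(a: _Anchor) -> bool:
    return (a.orient == "+" and a.end == "head") or (
        a.orient == "-" and a.end == "tail"
    )


def _end_anchors(rep_contigs: Sequence[Contig], donor: Assembly) -> list[_Anchor]:
    idx = build_index([(c.id, c.seq) for c in donor.contigs])
    anchors: list[_Anchor] = []
    for c in rep_contigs:
        for a in map_read((c.id, c.seq), idx, refine_identity=True):
            if a.qspan < MIN_ANCHOR_LEN or a.identity_est < MIN_ANCHOR_IDENTITY:
                continue
            head_reached = a.qstart <= END_SLACK
            tail_reached = a.qlen - a.qend <= END_SLACK
            # extrapolate the image to the full contig extent so junction
            # coordinates are exact up to local divergence (minimizer
            # chains stop ~k bp short of the true boundary)
            if a.strand == "+":
                ds = max(0, a.tstart - a.qstart)
                de = min(a.tlen, a.tend + (a.qlen - a.qend))
            else:
                ds = max(0, a.tstart - (a.qlen - a.qend))
                de = min(a.tlen, a.tend + a.qstart)
            if head_reached:
                anchors.append(_Anchor(c.id, "head", a.target_id, ds, de,
                                       a.strand, a.qspan, a.identity_est))
            if tail_reached:
                anchors.append(_Anchor(c.id, "tail", a.target_id, ds, de,
                                       a.strand, a.qspan, a.identity_est))
    return anchors


@dataclass(frozen=True)
class _Link:
    a: _Anchor                # left image on the donor (faces right)
    b: _Anchor                # right image on the donor (faces left)
    donor_cycle: int
    score: int

    @property
    def trim(self) -> int:
        return max(0, self.a.dend - self.b.dstart)

    def gap_coords(self) -> tuple[int, int]:
        return self.a.dend, max(self.b.dstart, self.a.dend)


def _candidate_links(anchors: list[_Anchor], donor_cycle: int) -> list[_Link]:
    links: list[_Link] = []
    by_donor: dict[str, list[_Anchor]] = {}
    for a in anchors:
        by_donor.setdefault(a.donor, []).append(a)
    for _, group in sorted(by_donor.items()):
        group = sorted(group, key=lambda x: (x.dstart, x.dend))
        for i, a in enumerate(group):
            if not _faces_right(a):
                continue
            for b in group:
                if b is a:
                    continue
                if a.contig == b.contig and a.end == b.end:
                    continue
                if not _faces_left(b):
                    continue
                if b.dstart < a.dend - MAX_END_OVERLAP or b.dstart < a.dstart:
                    continue
                links.append(
                    _Link(a=a, b=b, donor_cycle=donor_cycle,
                          score=min(a.length, b.length))
                )
    return links


def scaffold(
    representative: Assembly,
    others: Sequence[Assembly],
    circular_min_overlap: int = 500,
    circular_min_identity: float = 0.95,
) -> tuple[Assembly, ScaffoldReport]:
    """Stitch representative contigs using the other intermediate
    assemblies.  Joins are accepted greedily by descending anchor length
    and must be mutually consistent (each contig end used at most once);
    conflicting links are logged.  Unjoined contigs pass through.
    """
    report = ScaffoldReport()
    already_circular = [c for c in representative.contigs if c.circular]
    linear = [c for c in representative.contigs if not c.circular]

    links: list[_Link] = []
    for donor in others:
        if donor.n_contigs == 0 or not linear:
            continue
        anchors = _end_anchors(linear, donor)
        links.extend(_candidate_links(anchors, donor.cycle_index))
    links.sort(
        key=lambda l: (-l.score, l.donor_cycle, l.a.contig, l.a.end,
                       l.b.contig, l.b.end)
    )

    used_ends: set[tuple[str, str]] = set()
    accepted: list[_Link] = []
    closing: list[_Link] = []
    parent: dict[str, str] = {c.id: c.id for c in linear}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for l in links:
        ea = (l.a.contig, l.a.end)
        eb = (l.b.contig, l.b.end)
        j = Join(
            left_contig=l.a.contig, left_end=l.a.end,
            right_contig=l.b.contig, right_end=l.b.end,
            donor_cycle=l.donor_cycle, donor_contig=l.a.donor,
            anchor_len=l.score, identity=min(l.a.identity, l.b.identity),
            accepted=False,
        )
        if ea in used_ends or eb in used_ends:
            j.reason = "conflict: end already used by a longer-anchored join"
            report.joins.append(j)
            continue
        if find(l.a.contig) == find(l.b.contig):
            # same chain: this link closes it into a circle
            used_ends.update((ea, eb))
            closing.append(l)
            j.accepted = True
            j.reason = "closes chain into a circle"
            report.joins.append(j)
            continue
        used_ends.update((ea, eb))
        parent[find(l.a.contig)] = find(l.b.contig)
        accepted.append(l)
        j.accepted = True
        report.joins.append(j)

    seqs = {c.id: c.seq for c in linear}
    donor_by_cycle = {a.cycle_index: a for a in others}

    def gap_seq(l: _Link) -> str:
        donor = donor_by_cycle[l.donor_cycle]
        dseq = next(c.seq for c in donor.contigs if c.id == l.a.donor)
        gs, ge = l.gap_coords()
        return dseq[gs:ge]

    by_end: dict[tuple[str, str], _Link] = {}
    for l in accepted + closing:
        by_end[(l.a.contig, l.a.end)] = l
        by_end[(l.b.contig, l.b.end)] = l

    def open_end(node: tuple[str, str], right: bool) -> tuple[str, str]:
        cid, orient = node
        if right:
            return cid, "tail" if orient == "+" else "head"
        return cid, "head" if orient == "+" else "tail"

    visited: set[str] = set()
    chains: list[list[tuple[str, str]]] = []
    for c in sorted(linear, key=lambda c: (-len(c.seq), c.id)):
        if c.id in visited:
            continue
        chain: list[tuple[str, str]] = [(c.id, "+")]
        visited.add(c.id)
        for right in (True, False):
            while True:
                end = open_end(chain[-1] if right else chain[0], right)
                l = by_end.get(end)
                if l is None or l in closing:
                    break
                other = (
                    (l.b.contig, l.b.end)
                    if (l.a.contig, l.a.end) == end
                    else (l.a.contig, l.a.end)
                )
                ocid, oend = other
                if ocid in visited:
                    break
                if right:
                    chain.append((ocid, "+" if oend == "head" else "-"))
                else:
                    chain.insert(0, (ocid, "+" if oend == "tail" else "-"))
                visited.add(ocid)
        chains.append(chain)

    out: list[Contig] = []
    n_out = 0
    for chain in chains:
        parts: list[str] = []
        for i, (cid, orient) in enumerate(chain):
            seq = seqs[cid] if orient == "+" else revcomp(seqs[cid])
            if i > 0:
                left = chain[i - 1]
                lend = open_end(left, right=True)
                l = by_end[lend]
                forward = (l.a.contig, l.a.end) == lend
                g = gap_seq(l)
                parts.append(g if forward else revcomp(g))
                if l.trim:
                    seq = seq[l.trim :]
            parts.append(seq)
        merged = "".join(parts)
        # a closing link on this chain's open ends marks it circular
        circ_link = None
        re_end = open_end(chain[-1], right=True)
        le_end = open_end(chain[0], right=False)
        l = by_end.get(re_end)
        if l is not None and l in closing:
            ends = {(l.a.contig, l.a.end), (l.b.contig, l.b.end)}
            if ends == {re_end, le_end}:
                circ_link = l
        n_out += 1
        if circ_link is not None:
            forward = (circ_link.a.contig, circ_link.a.end) == re_end
            g = gap_seq(circ_link)
            merged = merged + (g if forward else revcomp(g))
            if circ_link.trim:
                merged = merged[: len(merged) - circ_link.trim]
            out.append(
                Contig(id=f"consensus_{n_out:04d}",
                       seq=canonical_rotation(merged), circular=True)
            )
        else:
            out.append(Contig(id=f"consensus_{n_out:04d}", seq=merged))

    final: list[Contig] = []
    for c in out:
        if c.circular:
            final.append(c)
            continue
        seq, circ = circularize(
            c.seq, circular_min_overlap, circular_min_identity
        )
        final.append(Contig(id=c.id, seq=seq, circular=circ))
    for i, c in enumerate(already_circular):
        final.append(
            Contig(id=f"consensus_circ_{i:04d}", seq=c.seq, circular=True)
        )
    final = [
        Contig(id=f"consensus_{i:04d}", seq=c.seq, circular=c.circular)
        for i, c in enumerate(
            sorted(final, key=lambda c: (-len(c.seq), c.id))
        )
    ]
    result = Assembly(
        contigs=final,
        cycle_index=max(
            (a.cycle_index for a in [representative, *others]), default=0
        ),
        provenance={
            "stage": "scaffold_consensus",
            "representative_cycle": representative.cycle_index,
        },
    )
    return result, report
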