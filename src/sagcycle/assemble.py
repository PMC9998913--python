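"""Greedy overlap-layout-consensus assembler for single-cell long reads.

The assembler is deliberately minimal and fully deterministic:

1. all-vs-all minimizer overlaps;
2. contained reads dropped;
3. best-buddy dovetail graph: each read end keeps its single
   highest-scoring dovetail, and an edge survives only if it is the best
   for both ends it connects (this subsumes transitive-edge removal --
   every surviving end has degree <= 1);
4. unitig traversal of the resulting paths/cycles, with a layout built
   from the overlap coordinates;
5. pileup-majority consensus over the layout (two rounds);
6. end-to-end self-overlap detection marks circular unitigs, trimming the
   duplicated end and rotating to canonical form.

Repeats longer than a read fragment the assembly; the debias/reassemble
cycle plus consensus scaffolding, not the assembler itself, is the
mechanism for improving contiguity.  Reads are processed in sorted-id
order and all tie-breaks are lexicographic, so the output depends only on
the read set, never on input order or timing; the seed argument is
accepted for interface compatibility but nothing here draws random
numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

from .align import Overlap, all_vs_all, build_index, map_read
from .circular import circularize
from .consensus import Placement, pileup_consensus
from .formats import Assembly, Contig, Read, revcomp

CONSENSUS_ROUNDS = 2
DEDUP_IDENTITY = 0.95     # contig absorbed if this similar over 95% length


# --------------------------------------------------------------------------- #
# graph construction
# --------------------------------------------------------------------------- #

def _contained_reads(overlaps: Sequence[Overlap]) -> set[str]:
    contained: set[str] = set()
    for o in overlaps:
        a = o.aln
        if o.kind == "contained_query":
            # mutual containment (near-identical reads): keep smaller id
            if a.qlen == a.tlen and a.query_id < a.target_id:
                contained.add(a.target_id)
            else:
                contained.add(a.query_id)
        elif o.kind == "contained_target":
            contained.add(a.target_id)
    return contained


def _oriented_interval(
    start: int, end: int, length: int, orient: str
) -> tuple[int, int]:
    if orient == "+":
        return start, end
    return length - end, length - start


@dataclass(frozen=True)
class _Edge:
    """Dovetail edge U -> V between oriented reads: U's oriented suffix
    overlaps V's oriented prefix."""

    u: tuple[str, str]          # (read id, orientation)
    v: tuple[str, str]
    u_start: int                # overlap start in U's oriented coords
    v_start: int                # overlap start in V's oriented coords
    score: int                  # overlap length


def _edges_of_overlap(o: Overlap, lens: dict[str, int]) -> list[_Edge]:
    """The two mirror-oriented edges implied by one dovetail overlap."""
    a = o.aln
    A, B = a.query_id, a.target_id
    la, lb = lens[A], lens[B]
    score = min(a.qspan, a.tspan)
    qf = (a.qstart, a.qend)
    tf = (a.tstart, a.tend)
    out: list[_Edge] = []

    def edge(u, uo, v, vo):
        us = _oriented_interval(*qf, la, uo)[0] if u == A else \
            _oriented_interval(*tf, lb, uo)[0]
        vs = _oriented_interval(*qf, la, vo)[0] if v == A else \
            _oriented_interval(*tf, lb, vo)[0]
        out.append(_Edge((u, uo), (v, vo), us, vs, score))

    if a.strand == "+":
        if o.query_suffix:      # A suffix ~ B prefix
            edge(A, "+", B, "+")
            edge(B, "-", A, "-")
        else:                   # B suffix ~ A prefix
            edge(B, "+", A, "+")
            edge(A, "-", B, "-")
    else:
        if o.query_suffix:      # A suffix ~ B suffix
            edge(A, "+", B, "-")
            edge(B, "+", A, "-")
        else:                   # A prefix ~ B prefix
            edge(A, "-", B, "+")
            edge(B, "-", A, "+")
    return out


def _read_end(node: tuple[str, str], outgoing: bool) -> tuple[str, str]:
    """Map an oriented node's in/out side to a physical read end."""
    rid, orient = node
    if outgoing:                 # the oriented suffix
        return rid, "tail" if orient == "+" else "head"
    return rid, "head" if orient == "+" else "tail"


def _best_buddy_edges(
    overlaps: Sequence[Overlap],
    lens: dict[str, int],
    contained: set[str],
) -> dict[tuple[str, str], _Edge]:
    """Keep, per oriented node, the single mutually-best outgoing dovetail.

    Scores are overlap lengths; ties break lexicographically by the
    partner (read id, orientation) so the graph is order-independent.
    """
    candidates: list[_Edge] = []
    for o in overlaps:
        if o.kind != "dovetail":
            continue
        a = o.aln
        if a.query_id in contained or a.target_id in contained:
            continue
        candidates.extend(_edges_of_overlap(o, lens))

    def rank(e: _Edge):
        return (-e.score, e.v[0], e.v[1])

    best_out: dict[tuple[str, str], _Edge] = {}
    for e in sorted(candidates, key=lambda e: (e.u, rank(e))):
        if e.u not in best_out:
            best_out[e.u] = e
    # mutuality: V's prefix end is the suffix end of V's mirror node, so
    # the edge survives only if that node's best choice is the mirror edge
    kept: dict[tuple[str, str], _Edge] = {}
    for e in best_out.values():
        partner_best = best_out.get((e.v[0], _flip_orient(e.v[1])))
        if (
            partner_best is not None
            and partner_best.v == (e.u[0], _flip_orient(e.u[1]))
            and partner_best.score == e.score
        ):
            kept[e.u] = e
    return kept


def _flip_orient(o: str) -> str:
    return "-" if o == "+" else "+"


# --------------------------------------------------------------------------- #
# traversal and layout
# --------------------------------------------------------------------------- #

def _mirror(node: tuple[str, str]) -> tuple[str, str]:
    return node[0], _flip_orient(node[1])


def _unitig_paths(
    edges: dict[tuple[str, str], _Edge], read_ids: Sequence[str]
) -> list[tuple[list[tuple[str, str]], list[_Edge], bool]]:
    """Maximal unbranched paths / cycles over the oriented best-buddy
    graph; each physical read is used once.  Returns (oriented node list,
    edge list, is_cycle) tuples with deterministic starting points."""
    indeg: dict[tuple[str, str], _Edge] = {e.v: e for e in edges.values()}
    used: set[str] = set()
    paths: list[tuple[list[tuple[str, str]], list[_Edge], bool]] = []
    for rid in sorted(read_ids):
        if rid in used:
            continue
        start = (rid, "+")
        seen = {start}
        is_cycle = False
        while True:  # walk back to the path head (or around a cycle)
            prev = indeg.get(start)
            if prev is None:
                break
            if prev.u in seen or prev.u[0] in used:
                is_cycle = prev.u in seen
                break
            start = prev.u
            seen.add(start)
        if is_cycle:
            # deterministic cycle anchor: smallest read id on the cycle
            anchor_rid = min(n[0] for n in seen)
            start = next(n for n in seen if n[0] == anchor_rid)
        nodes = [start]
        path_edges: list[_Edge] = []
        used.add(start[0])
        cur = start
        while True:
            e = edges.get(cur)
            if e is None:
                break
            if e.v == start and is_cycle:
                path_edges.append(e)  # closing edge of the cycle
                break
            if e.v[0] in used:
                break
            path_edges.append(e)
            cur = e.v
            nodes.append(cur)
            used.add(cur[0])
        paths.append((nodes, path_edges, is_cycle))
    return paths


def _oriented_seq(read_seqs: dict[str, str], node: tuple[str, str]) -> str:
    s = read_seqs[node[0]]
    return s if node[1] == "+" else revcomp(s)


def _layout_path(
    nodes: list[tuple[str, str]],
    path_edges: list[_Edge],
    read_seqs: dict[str, str],
    is_cycle: bool,
) -> tuple[str, list[Placement]]:
    """Build the draft backbone and approximate read placements from the
    overlap coordinates.  For cycles the closing edge is dropped: the
    resulting linear draft carries a duplicated end that circularize()
    trims later."""
    backbone_parts: list[str] = []
    placements: list[Placement] = []
    offset = 0
    cur_len = 0
    for i, node in enumerate(nodes):
        seq = _oriented_seq(read_seqs, node)
        if i == 0:
            backbone_parts.append(seq)
            cur_len = len(seq)
            placements.append(Placement(seq, 0, len(seq)))
            offset = 0
            continue
        e = path_edges[i - 1]
        offset = offset + e.u_start - e.v_start
        if offset < 0:
            offset = 0
        end = offset + len(seq)
        if end > cur_len:
            backbone_parts.append(seq[cur_len - offset :])
            cur_len = end
        placements.append(Placement(seq, offset, end))
    return "".join(backbone_parts), placements


# --------------------------------------------------------------------------- #
# public interface
# --------------------------------------------------------------------------- #

def _deduplicate(contigs: list[Contig]) -> list[Contig]:
    """Drop contigs essentially contained in a larger contig (>=95% of
    their length mapped at >=95% identity); removes leftover fragments of
    regions already represented."""
    if len(contigs) <= 1:
        return contigs
    contigs = sorted(contigs, key=lambda c: (-len(c.seq), c.id))
    kept: list[Contig] = []
    for c in contigs:
        absorbed = False
        for big in kept:
            idx = build_index([(big.id, big.seq)])
            alns = map_read((c.id, c.seq), idx, refine_identity=True)
            covered = sum(
                a.qspan for a in alns if a.identity_est >= DEDUP_IDENTITY
            )
            # chain ends stop ~k bp short of the true match boundary
            from .align import DEFAULT_K

            if covered + 2 * DEFAULT_K >= 0.95 * len(c.seq):
                absorbed = True
                break
        if not absorbed:
            kept.append(c)
    return kept


def assemble(
    reads: Sequence[Read],
    genome_size_hint: int = 0,
    min_overlap: int = 500,
    seed: int = 0,
    cycle_index: int = 0,
    circular_min_overlap: int = 500,
    circular_min_identity: float = 0.95,
    consensus_rounds: int = CONSENSUS_ROUNDS,
) -> Assembly:
    """Assemble reads into unitig contigs with pileup consensus.

    ``genome_size_hint`` is recorded in provenance and used only as a
    sanity reference; the assembler does not scale anything by it.
    Deterministic for a given read set regardless of input order.
    """
    provenance = {
        "min_overlap": min_overlap,
        "genome_size_hint": genome_size_hint,
        "seed": seed,
        "n_reads": len(reads),
    }
    # reads below the minimum overlap length can never join the graph
    reads = [r for r in reads if len(r.seq) >= min_overlap]
    if not reads:
        return Assembly(contigs=[], cycle_index=cycle_index,
                        provenance=provenance)
    reads = sorted(reads, key=lambda r: r.id)
    read_seqs = {r.id: r.seq for r in reads}
    overlaps = all_vs_all(reads, min_overlap=min_overlap)
    contained = _contained_reads(overlaps)
    remaining = [r.id for r in reads if r.id not in contained]
    lens = {r.id: len(r.seq) for r in reads}
    edges = _best_buddy_edges(overlaps, lens, contained)
    paths = _unitig_paths(edges, remaining)

    # place contained reads on their container's unitig for the pileup
    container_of: dict[str, Overlap] = {}
    for o in overlaps:
        a = o.aln
        if o.kind == "contained_query" and a.query_id in contained:
            cur = container_of.get(a.query_id)
            if cur is None or a.qspan > cur.aln.qspan:
                container_of[a.query_id] = o
        elif o.kind == "contained_target" and a.target_id in contained:
            f = o.flip()
            cur = container_of.get(a.target_id)
            if cur is None or f.aln.qspan > cur.aln.qspan:
                container_of[a.target_id] = f

    contigs: list[Contig] = []
    for ci, (nodes, path_edges, is_cycle) in enumerate(paths):
        backbone, placements = _layout_path(
            nodes, path_edges, read_seqs, is_cycle
        )
        # add contained reads whose container is on this unitig
        pos_of = {
            n[0]: (p, n[1]) for n, p in zip(nodes, placements)
        }
        for rid, o in sorted(container_of.items()):
            a = o.aln
            host = pos_of.get(a.target_id)
            if host is None:
                continue
            host_place, host_orient = host
            seq = read_seqs[rid]
            ts, te = _oriented_interval(
                a.tstart, a.tend, lens[a.target_id], host_orient
            )
            start = host_place.start + ts
            end = host_place.start + te
            same = (a.strand == "+") == (host_orient == "+")
            placements.append(
                Placement(seq if same else revcomp(seq), start, end)
            )
        consensus = backbone
        for _ in range(max(consensus_rounds, 0)):
            new = pileup_consensus(consensus, placements, min_cov=1,
                                   min_frac=0.5)
            if new == consensus:
                break
            consensus = new
        seq, circ = circularize(
            consensus, circular_min_overlap, circular_min_identity
        )
        contigs.append(Contig(id=f"ctg{ci:04d}", seq=seq, circular=circ))

    contigs = _deduplicate([c for c in contigs if c.seq])
    contigs = [
        Contig(id=f"contig_{i:04d}", seq=c.seq, circular=c.circular)
        for i, c in enumerate(
            sorted(contigs, key=lambda c: (-len(c.seq), c.id))
        )
    ]
    return Assembly(contigs=contigs, cycle_index=cycle_index,
                    provenance=provenance)


# --------------------------------------------------------------------------- #
# pluggable assembler contract
# --------------------------------------------------------------------------- #

class AssemblerContract(Protocol):
    """Anything that turns reads + genome-size hint into an Assembly."""

    def run(self, reads: Sequence[Read], hint: int) -> Assembly: ...


class BuiltinAssembler:
    """Adapter over :func:`assemble`, the default engine."""

    def __init__(self, **kwargs):
        self.kwargs = kwargs

    def run(self, reads: Sequence[Read], hint: int) -> Assembly:
        return assemble(reads, genome_size_hint=hint, **self.kwargs)


class ExternalAssemblerUnavailable(RuntimeError):
    pass


class ExternalAssembler:
    """Placeholder adapter for an external assembler binary; raises a
    declared error when the binary is missing rather than silently
    falling back."""

    def __init__(self, binary: str):
        self.binary = binary

    def run(self, reads: Sequence[Read], hint: int) -> Assembly:
        import shutil

        if shutil.which(self.binary) is None:
            raise ExternalAssemblerUnavailable(
                f"external assembler unavailable: {self.binary!r} not on PATH"
            )
        raise NotImplementedError(
            f"adapter for {self.binary!r} is a stub: plug in a converter "
            "from its output to Assembly"
        )
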