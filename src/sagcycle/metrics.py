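"""Assembly-quality metrics against a truth genome, depth-bias statistics,
and composition/identity-based strain grouping.

``genome_fraction`` / ``duplication_ratio`` follow the usual
reference-based definitions: percent of truth positions covered by aligned
contig blocks (chains >= 1 kb at >= 90% identity), and total aligned
assembly bases over covered truth positions.  Circular truth genomes are
handled by mapping against the doubled sequence with positions counted
modulo the genome length.

Strain grouping applies the pairwise rule used for single-cell genome
pools: two genomes belong to the same strain when ANI > 95%, tetra-
nucleotide frequency correlation > 90%, and (when available) single-copy
marker gene homology > 99%; groups are the single-linkage closure of
passing pairs.  Thresholds are strict inequalities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .align import build_index, map_read
from .formats import Assembly, PipelineConfig

GF_MIN_CHAIN = 1000
GF_MIN_IDENTITY = 0.90


def _truth_parts(truth) -> tuple[str, bool]:
    if isinstance(truth, str):
        return truth, False
    return truth.seq, bool(getattr(truth, "circular", False))


def _aligned_blocks(
    assembly: Assembly, truth
) -> tuple[np.ndarray, int]:
    """Covered-position mask over the truth genome and total aligned
    assembly bases (union of query intervals per contig)."""
    seq, circular = _truth_parts(truth)
    if not seq:
        raise ValueError("truth genome is empty")
    L = len(seq)
    text = seq * 2 if circular else seq
    index = build_index([("truth", text)])
    covered = np.zeros(L, dtype=bool)
    aligned_bases = 0
    for c in assembly.contigs:
        qcov: list[tuple[int, int]] = []
        for a in map_read((c.id, c.seq), index, refine_identity=True):
            if a.qspan < GF_MIN_CHAIN or a.identity_est < GF_MIN_IDENTITY:
                continue
            # extrapolate chain ends to the full block extent (minimizer
            # chains stop ~k bp short of the true match boundary); the
            # extension is bounded by the room left on both sequences
            if a.strand == "+":
                ovh_l, ovh_r = a.qstart, a.qlen - a.qend
            else:
                ovh_l, ovh_r = a.qlen - a.qend, a.qstart
            ext_l = min(ovh_l, a.tstart)
            ext_r = min(ovh_r, a.tlen - a.tend)
            ts = a.tstart - ext_l
            te = a.tend + ext_r
            if a.strand == "+":
                qcov.append((a.qstart - ext_l, a.qend + ext_r))
            else:
                qcov.append((a.qstart - ext_r, a.qend + ext_l))
            if circular:
                idx = np.arange(ts, te) % L
                covered[idx] = True
            else:
                covered[ts:te] = True
        # union of query intervals so a contig never double-counts itself
        qcov.sort()
        last = -1
        for s, e in qcov:
            s = max(s, last)
            if e > s:
                aligned_bases += e - s
                last = e
    return covered, aligned_bases


def genome_fraction(assembly: Assembly, truth) -> float:
    """Percent of truth positions covered by >= 1 aligned contig block."""
    covered, _ = _aligned_blocks(assembly, truth)
    return float(100.0 * covered.mean())


def duplication_ratio(assembly: Assembly, truth) -> float:
    """Total aligned assembly bases / truth positions covered at least
    once; > 1 indicates redundant contigs."""
    covered, aligned = _aligned_blocks(assembly, truth)
    n_cov = int(covered.sum())
    if n_cov == 0:
        raise ValueError("no truth positions covered; ratio undefined")
    return aligned / n_cov


def assembly_identity(assembly: Assembly, truth) -> float:
    """Length-weighted mean identity of aligned contig blocks vs truth."""
    seq, circular = _truth_parts(truth)
    text = seq * 2 if circular else seq
    index = build_index([("truth", text)])
    num = den = 0.0
    for c in assembly.contigs:
        for a in map_read((c.id, c.seq), index, refine_identity=True):
            if a.qspan < GF_MIN_CHAIN or a.identity_est < GF_MIN_IDENTITY:
                continue
            num += a.identity_est * a.qspan
            den += a.qspan
    return num / den if den else 0.0


def nxx(
    assembly: Assembly | Sequence[int],
    x: float = 50.0,
    genome_size: int | None = None,
) -> int:
    """N50-style statistic: the largest contig length L such that contigs
    >= L sum to >= x% of the assembly size (or of ``genome_size`` for the
    NG variant)."""
    if isinstance(assembly, Assembly):
        lengths = sorted((len(c.seq) for c in assembly.contigs), reverse=True)
    else:
        lengths = sorted((int(v) for v in assembly), reverse=True)
    if not lengths:
        return 0
    total = genome_size if genome_size is not None else sum(lengths)
    need = x / 100.0 * total
    acc = 0
    for l in lengths:
        acc += l
        if acc >= need:
            return l
    return 0


def depth_bias_stats(depths: np.ndarray | Mapping[str, np.ndarray]) -> dict:
    """Breadth, mean, max/median ratio and Gini coefficient of a depth
    profile (all contigs concatenated when a mapping is given)."""
    if isinstance(depths, Mapping):
        arr = np.concatenate([np.asarray(v) for v in depths.values()])
    else:
        arr = np.asarray(depths)
    if arr.size == 0:
        raise ValueError("empty depth profile")
    arr = arr.astype(float)
    mean = float(arr.mean())
    med = float(np.median(arr))
    s = np.sort(arr)
    n = arr.size
    gini = 0.0
    if s.sum() > 0:
        gini = float(
            (2.0 * np.sum((np.arange(1, n + 1)) * s)) / (n * s.sum())
            - (n + 1) / n
        )
    return {
        "breadth": float((arr > 0).mean()),
        "mean": mean,
        "max_median_ratio": float(arr.max() / med) if med > 0 else math.inf,
        "gini": gini,
    }


# --------------------------------------------------------------------------- #
# composition and identity
# --------------------------------------------------------------------------- #

def _canonical_4mer_table() -> tuple[np.ndarray, int]:
    """Map each of the 256 4-mer codes to a canonical class index
    (strand-collapsed); 136 classes."""
    def rc(code: int) -> int:
        out = 0
        for _ in range(4):
            out = (out << 2) | (3 - (code & 3))
            code >>= 2
        return out

    canon = {}
    table = np.zeros(256, dtype=np.int64)
    for code in range(256):
        key = min(code, rc(code))
        if key not in canon:
            canon[key] = len(canon)
        table[code] = canon[key]
    return table, len(canon)


_T4, _N_CANON = _canonical_4mer_table()
_BASE4 = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE4[ord(_b)] = _i


def tnf_vector(seq: str) -> np.ndarray:
    """Strand-canonical tetranucleotide frequency vector (136-dim)."""
    if len(seq) < 2000:
        raise ValueError("sequence must be >= 2 kb for TNF statistics")
    arr = _BASE4[np.frombuffer(seq.encode(), dtype=np.uint8)]
    win = np.lib.stride_tricks.sliding_window_view(arr, 4)
    ok = (win < 4).all(axis=1)
    codes = (
        win[:, 0].astype(np.int64) * 64
        + win[:, 1] * 16
        + win[:, 2] * 4
        + win[:, 3]
    )[ok]
    if codes.size < 100:
        raise ValueError("fewer than 100 counted 4-mers")
    counts = np.bincount(_T4[codes], minlength=_N_CANON).astype(float)
    return counts / counts.sum()


def tnf_correlation(seq_a: str, seq_b: str) -> float:
    """Pearson correlation of canonical 4-mer frequency vectors."""
    va, vb = tnf_vector(seq_a), tnf_vector(seq_b)
    return float(np.corrcoef(va, vb)[0, 1])


@dataclass(frozen=True)
class AniResult:
    ani: float                  # percent; nan when undefined
    mapped_fraction: float
    defined: bool


def fragment_ani(
    genome_a: str, genome_b: str, frag: int = 3000
) -> AniResult:
    """Fragment-mapping average nucleotide identity: split A into
    ``frag``-sized pieces, map each to B, average the identities of the
    mapped pieces (percent)."""
    if len(genome_a) < 2 * frag:
        raise ValueError("genome A shorter than two fragments")
    index = build_index([("B", genome_b)])
    idents: list[float] = []
    n_frags = 0
    for s in range(0, len(genome_a) - frag + 1, frag):
        n_frags += 1
        piece = genome_a[s : s + frag]
        alns = map_read((f"f{s}", piece), index, refine_identity=True)
        best = max((a for a in alns), key=lambda a: a.qspan, default=None)
        if best is not None and best.qspan >= frag // 2:
            idents.append(best.identity_est)
    if not idents:
        return AniResult(ani=float("nan"), mapped_fraction=0.0, defined=False)
    return AniResult(
        ani=100.0 * float(np.mean(idents)),
        mapped_fraction=len(idents) / n_frags,
        defined=True,
    )


# --------------------------------------------------------------------------- #
# strain grouping
# --------------------------------------------------------------------------- #

def group_strains(
    pairwise: Mapping[tuple[str, str], Mapping[str, float]],
    config: PipelineConfig | None = None,
) -> list[set[str]]:
    """Single-linkage strain groups over pairs passing ALL provided
    thresholds (ani > 95, tnf > 0.90, marker > 99 when present; strict).

    The table must be symmetric: when both (a, b) and (b, a) are present
    they must agree; ids only seen in keys still form singleton groups.
    """
    cfg = config or PipelineConfig()
    ids: set[str] = set()
    edges: dict[frozenset, Mapping[str, float]] = {}
    for (a, b), vals in pairwise.items():
        ids.update((a, b))
        if a == b:
            continue
        key = frozenset((a, b))
        if key in edges:
            prev = edges[key]
            for field in ("ani", "tnf", "marker"):
                if (field in prev) != (field in vals) or (
                    field in prev
                    and not math.isclose(prev[field], vals[field],
                                         rel_tol=1e-9, abs_tol=1e-9)
                ):
                    raise ValueError(
                        f"asymmetric pairwise table for pair {a!r}/{b!r}"
                    )
        else:
            edges[key] = vals

    parent = {i: i for i in sorted(ids)}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for key, vals in sorted(edges.items(), key=lambda kv: sorted(kv[0])):
        if vals.get("ani", -math.inf) <= cfg.ani_threshold:
            continue
        if vals.get("tnf", -math.inf) <= cfg.tnf_threshold:
            continue
        if "marker" in vals and vals["marker"] <= cfg.marker_threshold:
            continue
        a, b = sorted(key)
        parent[find(a)] = find(b)

    groups: dict[str, set[str]] = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    return sorted(groups.values(), key=lambda g: sorted(g)[0])
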