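"""Synthetic truth genomes and single-cell MDA-style reads.

Multiple displacement amplification (MDA) of a single bacterial cell
produces long DNA with two characteristic artifacts: strongly uneven
(heavy-tailed) amplification across the genome with contiguous unamplified
regions, and chimeric molecules joining non-adjacent (possibly inverted)
genomic segments.  This module models both phenomenologically -- amplicon
windows with lognormal heights plus contiguous dropout, and two-segment
chimeras -- and tracks exact ground truth per read so every downstream
stage can be tested without external data.

A single-cell product typically covers only 40-60% of its genome, so the
pooled-SAG helper draws per-cell breadths from that range and pools the
cells' reads, mirroring how multiple MDA products of one strain are
sequenced together to cover the full genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .formats import Read, ReadTruth, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# default error-type split: substitutions dominate, indels in equal parts
ERROR_SPLIT = (0.6, 0.2, 0.2)  # sub : ins : del
DEFAULT_CHIMERA_RATE = 0.01    # per read; a free parameter of the model


@dataclass(frozen=True)
class TruthGenome:
    seq: str
    circular: bool
    seed: int

    def __post_init__(self) -> None:
        if len(self.seq) < 1000:
            raise ValueError("truth genome must be >= 1000 bp")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class BiasProfile:
    """Per-position amplification weight plus a dropout mask (True =
    unamplified).  Dropout positions always have weight zero."""

    weights: np.ndarray
    dropout_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.weights.sum() <= 0:
            raise ValueError("bias profile weights must sum > 0")
        if np.any(self.weights[self.dropout_mask] != 0):
            raise ValueError("dropout positions must have zero weight")

    @property
    def breadth(self) -> float:
        return float(1.0 - self.dropout_mask.mean())


def simulate_genome(length: int, gc: float, seed: int,
                    circular: bool = True) -> TruthGenome:
    """An i.i.d. random genome with P(G) + P(C) = gc."""
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = _BASES[rng.choice(4, size=length, p=p)].tobytes().decode()
    return TruthGenome(seq=seq, circular=circular, seed=seed)


def make_bias_profile(
    genome: TruthGenome,
    n_amplicons: int = 16,
    skew: float = 1.5,
    target_breadth: float = 1.0,
    seed: int = 0,
) -> BiasProfile:
    """MDA amplification bias as amplicon tiles plus contiguous dropout.

    ``n_amplicons`` random cut points partition the genome into contiguous
    amplicon windows, each amplified with its own lognormal(0, skew)
    efficiency; a small uniform floor models weak background
    amplification.  Tiling (rather than scattered windows) guarantees
    every position belongs to some amplicon while keeping the full
    heavy-tailed skew of the lognormal heights.  Contiguous dropout
    segments -- long chunks, L/16 to L/6, mirroring how unamplified
    regions appear as large missing blocks rather than scattered holes --
    are then zeroed until the non-dropout fraction matches
    ``target_breadth`` (within one segment-placement rounding, well inside
    +/-0.02).
    """
    if not 0.0 < target_breadth <= 1.0:
        raise ValueError("target_breadth must be in (0, 1]")
    if n_amplicons < 1:
        raise ValueError("n_amplicons must be >= 1")
    rng = np.random.default_rng(seed)
    L = len(genome)
    cuts = np.sort(rng.integers(0, L, size=n_amplicons))
    heights = rng.lognormal(mean=0.0, sigma=skew, size=n_amplicons)
    weights = np.empty(L)
    for i in range(n_amplicons):
        lo = int(cuts[i])
        hi = int(cuts[(i + 1) % n_amplicons]) if i + 1 < n_amplicons else None
        if hi is None:  # last tile wraps to the first cut
            weights[lo:] = heights[i]
            weights[: int(cuts[0])] = heights[i]
        else:
            weights[lo:hi] = heights[i]
    # background amplification floor: ~10% of the mean tile efficiency, so
    # no amplified region is ever sampled at exactly zero rate while the
    # heavy upper tail of the lognormal is untouched
    weights += 0.1 * float(np.mean(heights))

    dropout = np.zeros(L, dtype=bool)
    need = int(round((1.0 - target_breadth) * L))
    seg_lo, seg_hi = max(L // 16, 1), max(L // 6, 2)
    while int(dropout.sum()) < need:
        remaining = need - int(dropout.sum())
        seg = int(min(rng.integers(seg_lo, seg_hi), remaining))
        s = int(rng.integers(0, L))
        newly = ~dropout[s : s + seg]
        # clip so we never overshoot the target
        take = np.nonzero(newly)[0][:remaining]
        dropout[s + take] = True
    weights[dropout] = 0.0
    if weights.sum() <= 0:
        weights[~dropout] = 1.0
    return BiasProfile(weights=weights, dropout_mask=dropout)


def _inject_errors(
    seq: str, error_rate: float, rng: np.random.Generator
) -> str:
    """Substitution/insertion/deletion errors at ``error_rate`` per base,
    split 60:20:20."""
    if error_rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    u = rng.random(len(arr))
    ev = u < error_rate
    if not ev.any():
        return seq
    kind = rng.random(len(arr))  # drawn for all positions: keeps streams simple
    subs = ev & (kind < ERROR_SPLIT[0])
    ins = ev & (kind >= ERROR_SPLIT[0]) & (kind < ERROR_SPLIT[0] + ERROR_SPLIT[1])
    dels = ev & ~subs & ~ins
    # substitutions: shift by 1-3 in base space so the base always changes
    code = np.full(256, 0, np.uint8)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    c = code[arr]
    shift = rng.integers(1, 4, size=len(arr))
    sub_base = _BASES[(c + shift) % 4]
    arr = np.where(subs, sub_base, arr)
    ins_base = _BASES[rng.integers(0, 4, size=len(arr))]
    pieces: list[bytes] = []
    prev = 0
    idx = np.nonzero(ins | dels)[0]
    for i in idx.tolist():
        if ins[i]:
            pieces.append(arr[prev : i + 1].tobytes())
            pieces.append(ins_base[i : i + 1].tobytes())
        else:  # deletion
            pieces.append(arr[prev:i].tobytes())
        prev = i + 1
    pieces.append(arr[prev:].tobytes())
    return b"".join(pieces).decode()


def _draw_segment(
    genome: TruthGenome,
    profile: BiasProfile,
    length: int,
    cum_weights: np.ndarray,
    rng: np.random.Generator,
) -> tuple[str, tuple[int, int, str]]:
    """Draw one amplicon segment: start position proportional to weight,
    truncated at the first downstream dropout position (the amplicon does
    not exist there); circular genomes wrap the origin."""
    L = len(genome)
    u = rng.random() * cum_weights[-1]
    start = int(np.searchsorted(cum_weights, u, side="right"))
    start = min(start, L - 1)
    if genome.circular:
        end = start + length
        idxs = np.arange(start, end) % L
        drop = profile.dropout_mask[idxs]
        hit = np.nonzero(drop)[0]
        if len(hit):
            end = start + int(hit[0])
        if end <= start:
            end = start + 1
        seq = (genome.seq * 2)[start:end] if end > L else genome.seq[start:end]
        if end > 2 * L:  # pathological tiny genome; clamp
            end = 2 * L
        return seq, (start, end, "+")
    end = min(start + length, L)
    drop = profile.dropout_mask[start:end]
    hit = np.nonzero(drop)[0]
    if len(hit):
        end = start + int(hit[0])
    if end <= start:
        end = start + 1
    return genome.seq[start:end], (start, end, "+")


def sample_long_reads(
    genome: TruthGenome,
    profile: BiasProfile,
    mean_depth: float,
    read_len_mean: int = 5000,
    read_len_sd: int = 1000,
    error_rate: float = 0.0,
    chimera_rate: float = DEFAULT_CHIMERA_RATE,
    seed: int = 0,
    id_prefix: str = "lr",
    source_sag: str | None = None,
) -> list[Read]:
    """MDA-style long reads: starts proportional to amplification weight,
    two-segment chimeras at ``chimera_rate`` (second segment in either
    orientation), indel-capable errors, and full truth tracking."""
    if len(profile.weights) != len(genome):
        raise ValueError("profile length != genome length")
    if not 0 <= error_rate < 1 or not 0 <= chimera_rate < 1:
        raise ValueError("rates must be in [0, 1)")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    rng = np.random.default_rng(seed)
    L = len(genome)
    n_reads = int(round(mean_depth * L / read_len_mean))
    cum = np.cumsum(profile.weights)
    phred = 40 if error_rate == 0 else max(
        2, int(round(-10 * np.log10(error_rate)))
    )
    reads: list[Read] = []
    for i in range(n_reads):
        total_len = max(300, int(round(rng.normal(read_len_mean, read_len_sd))))
        if rng.random() < chimera_rate:
            f = rng.uniform(0.2, 0.8)
            len_a = max(100, int(round(total_len * f)))
            len_b = max(100, total_len - len_a)
            seq_a, iv_a = _draw_segment(genome, profile, len_a, cum, rng)
            seq_b, iv_b = _draw_segment(genome, profile, len_b, cum, rng)
            inverted = bool(rng.random() < 0.5)
            if inverted:
                seq_b = revcomp(seq_b)
                iv_b = (iv_b[0], iv_b[1], "-")
            err_a = _inject_errors(seq_a, error_rate, rng)
            err_b = _inject_errors(seq_b, error_rate, rng)
            seq = err_a + err_b
            junction = len(err_a)
            truth = ReadTruth(intervals=(iv_a, iv_b), junctions=(junction,))
        else:
            raw, iv = _draw_segment(genome, profile, total_len, cum, rng)
            seq = _inject_errors(raw, error_rate, rng)
            truth = ReadTruth(intervals=(iv,), junctions=())
        reads.append(
            Read(
                id=f"{id_prefix}{i:06d}",
                seq=seq,
                quals=(phred,) * len(seq),
                source_sag=source_sag,
                truth=truth,
            )
        )
    return reads


def sample_short_reads(
    genome: TruthGenome,
    depth: float,
    read_len: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
    id_prefix: str = "sr",
) -> list[Read]:
    """Uniform unbiased short reads (no chimeras), both strands."""
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    L = len(genome)
    n_reads = int(round(depth * L / read_len))
    phred = 40 if error_rate == 0 else max(
        2, int(round(-10 * np.log10(error_rate)))
    )
    hi = L if genome.circular else max(L - read_len, 1)
    starts = rng.integers(0, hi, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    doubled = genome.seq * 2 if genome.circular else genome.seq
    reads: list[Read] = []
    for i in range(n_reads):
        s = int(starts[i])
        raw = doubled[s : s + read_len]
        strand = "-" if strands[i] else "+"
        seq = _inject_errors(raw, error_rate, rng)
        if strand == "-":
            seq = revcomp(seq)
        reads.append(
            Read(
                id=f"{id_prefix}{i:06d}",
                seq=seq,
                quals=(phred,) * len(seq),
                truth=ReadTruth(intervals=((s, s + len(raw), strand),)),
            )
        )
    return reads


def pooled_sag_long_reads(
    genome: TruthGenome,
    n_sags: int,
    pooled_mean_depth: float,
    breadth_range: tuple[float, float] = (0.4, 0.6),
    min_union_breadth: float = 0.99,
    min_pooled_cov: int | None = None,
    skew: float = 1.5,
    read_len_mean: int = 5000,
    read_len_sd: int = 1000,
    error_rate: float = 0.01,
    chimera_rate: float = DEFAULT_CHIMERA_RATE,
    seed: int = 0,
    max_redraws: int = 200,
) -> tuple[list[Read], list[BiasProfile]]:
    """Pool reads from ``n_sags`` single-cell products of one strain.

    Each cell gets its own bias profile with breadth drawn uniformly from
    ``breadth_range``; profiles are redrawn (deterministically) until the
    union of amplified regions reaches ``min_union_breadth``.  When
    ``min_pooled_cov`` is set, draws are additionally repeated until every
    genome position is covered by at least that many pooled reads -- the
    study-design precondition for a closable genome: a pool whose reads do
    not contain the whole genome can never assemble into a closed circle,
    and such pools are exactly the ones a practitioner would re-pool.
    """
    rng = np.random.default_rng(seed)
    L = len(genome)
    per_sag_depth = pooled_mean_depth / n_sags
    for attempt in range(max_redraws):
        profiles = []
        for s in range(n_sags):
            b = float(rng.uniform(*breadth_range))
            profiles.append(
                make_bias_profile(
                    genome, skew=skew, target_breadth=b,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
        union = np.zeros(L, dtype=bool)
        for p in profiles:
            union |= ~p.dropout_mask
        if union.mean() < min_union_breadth:
            continue
        reads = []
        for s, prof in enumerate(profiles):
            reads.extend(
                sample_long_reads(
                    genome, prof, per_sag_depth,
                    read_len_mean=read_len_mean, read_len_sd=read_len_sd,
                    error_rate=error_rate, chimera_rate=chimera_rate,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    id_prefix=f"sag{s}_", source_sag=f"sag{s}",
                )
            )
        if min_pooled_cov is not None:
            # raw coverage floor, plus an overlap-tiling check: intervals
            # shrunk by ~min_overlap/2 per side must still cover every
            # position, so consecutive reads overlap enough for an
            # overlap-layout chain to pass through.  Chimeric reads are
            # excluded: the pipeline removes them, so they cannot be
            # counted on to carry coverage
            margin = 275
            cov = np.zeros(L, dtype=np.int32)
            shrunk = np.zeros(L, dtype=np.int32)
            for r in reads:
                if r.truth is None or r.truth.junctions:
                    continue
                for s0, e0, _ in r.truth.intervals:
                    for lo, hi, arr in (
                        (s0, e0, cov),
                        (s0 + margin, e0 - margin, shrunk),
                    ):
                        if hi <= lo:
                            continue
                        if hi <= L:
                            arr[lo:hi] += 1
                        else:
                            arr[lo:] += 1
                            arr[: hi % L] += 1
            if int(cov.min()) < min_pooled_cov or int(shrunk.min()) < 1:
                continue
        return reads, profiles
    raise RuntimeError(
        f"no pool met the coverage gates in {max_redraws} draws"
    )


def truth_breadth(reads: Sequence[Read], genome_len: int) -> float:
    """Fraction of genome positions covered by >= 1 truth interval."""
    cov = np.zeros(genome_len, dtype=bool)
    for r in reads:
        if r.truth is None:
            continue
        for s, e, _ in r.truth.intervals:
            if e <= genome_len:
                cov[s:e] = True
            else:  # wrapped interval on a circular genome
                cov[s:] = True
                cov[: e % genome_len] = True
    return float(cov.mean())


def write_truth(reads: Sequence[Read], path: str | Path) -> None:
    """BED-like TSV: one line per origin interval (read, segment index,
    start, end, strand) plus one per junction (read, 'junction', offset)."""
    with open(path, "w") as fh:
        fh.write("#read\tkind\tcol1\tcol2\tcol3\n")
        for r in reads:
            if r.truth is None:
                continue
            for i, (s, e, strand) in enumerate(r.truth.intervals):
                fh.write(f"{r.id}\tinterval{i}\t{s}\t{e}\t{strand}\n")
            for j in r.truth.junctions:
                fh.write(f"{r.id}\tjunction\t{j}\t.\t.\n")


def read_truth(path: str | Path) -> dict[str, ReadTruth]:
    intervals: dict[str, list[tuple[int, int, str]]] = {}
    junctions: dict[str, list[int]] = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        rid, kind, a, b, c = line.split("\t")
        if kind == "junction":
            junctions.setdefault(rid, []).append(int(a))
        else:
            intervals.setdefault(rid, []).append((int(a), int(b), c))
    out = {}
    for rid in set(intervals) | set(junctions):
        out[rid] = ReadTruth(
            intervals=tuple(intervals.get(rid, ())),
            junctions=tuple(junctions.get(rid, ())),
        )
    return out
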