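"""Domain types and readers/writers for the standard formats the pipeline touches.

Conventions used throughout the package: all coordinates are 0-based,
half-open, on the forward strand of the target sequence; FASTQ qualities
are Phred+33; PAF (12 mandatory columns) is the on-disk alignment dialect.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

log = logging.getLogger("sagcycle")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class ReadTruth:
    """Simulation ground truth attached to a synthetic read.

    ``intervals`` are origin intervals on the truth genome, one per read
    segment, as (start, end, strand); for reads sampled across the origin of
    a circular genome ``end`` may exceed the genome length (coordinates are
    understood modulo the genome length).  ``junctions`` are chimeric
    junction offsets on the read itself, strictly inside (0, len(read)).
    """

    intervals: tuple[tuple[int, int, str], ...] = ()
    junctions: tuple[int, ...] = ()


@dataclass(frozen=True)
class Read:
    """A sequencing read (long or short) with optional qualities and truth."""

    id: str
    seq: str
    quals: tuple[int, ...] | None = None
    source_sag: str | None = None
    truth: ReadTruth | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read id must be non-empty")
        if self.quals is not None and len(self.quals) != len(self.seq):
            raise ValueError(
                f"read {self.id}: {len(self.quals)} qualities for "
                f"{len(self.seq)} bases"
            )
        if self.truth is not None:
            for j in self.truth.junctions:
                if not 0 < j < len(self.seq):
                    raise ValueError(
                        f"read {self.id}: junction offset {j} outside "
                        f"(0, {len(self.seq)})"
                    )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Alignment:
    """A query-to-target mapping with 0-based half-open coordinates.

    ``identity_est`` is the base-level identity of the aligned spans
    (matches / alignment columns); ``n_anchor_bases`` counts query positions
    covered by exact k-mer anchors of the chain that produced the alignment.
    """

    query_id: str
    target_id: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tlen: int
    tstart: int
    tend: int
    n_anchor_bases: int = 0
    identity_est: float = 1.0
    mapq_proxy: int = 0
    block_len: int = 0  # PAF col 11; 0 = derive from spans on write

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise ValueError(
                f"query interval [{self.qstart},{self.qend}) out of bounds "
                f"for length {self.qlen}"
            )
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise ValueError(
                f"target interval [{self.tstart},{self.tend}) out of bounds "
                f"for length {self.tlen}"
            )
        if not 0.0 < self.identity_est <= 1.0:
            raise ValueError(f"identity_est {self.identity_est} not in (0,1]")

    @property
    def qspan(self) -> int:
        return self.qend - self.qstart

    @property
    def tspan(self) -> int:
        return self.tend - self.tstart


@dataclass
class Contig:
    id: str
    seq: str
    circular: bool = False

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Assembly:
    """A set of contigs with circularity flags and provenance cycle index.

    Contigs are kept sorted by descending length (ties by id) so that
    serialization and representative selection are deterministic.
    """

    contigs: list[Contig] = field(default_factory=list)
    cycle_index: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError("contig ids must be unique")
        self.contigs.sort(key=lambda c: (-len(c.seq), c.id))

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)


@dataclass
class PipelineConfig:
    """Tunable parameters of the debias/assemble cycle, with the defaults
    used for the workflow's reference run (read filter -q 10 -l 1000
    --headcrop 75, 50x depth cap, four debias cycles)."""

    min_len: int = 1000
    min_q: float = 10.0
    headcrop: int = 75
    depth_cap: int = 50
    max_cycles: int = 4
    genome_size_hint: int = 0
    convergence_tol: float = 0.001
    seed: int = 0
    circular_min_overlap: int = 500
    circular_min_identity: float = 0.95
    gapfill_min_flank: int = 500
    gapfill_min_identity: float = 0.99
    ani_threshold: float = 95.0
    tnf_threshold: float = 0.90
    marker_threshold: float = 99.0

    def __post_init__(self) -> None:
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")
        for name in ("min_len", "headcrop", "depth_cap", "circular_min_overlap",
                     "gapfill_min_flank"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("circular_min_identity", "gapfill_min_identity"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.convergence_tol < 0:
            raise ValueError("convergence_tol must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat key=value config file; unknown keys are rejected."""
        kwargs: dict = {}
        valid = {f: t for f, t in cls.__annotations__.items()}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key=value")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in valid:
                raise FormatError(f"{path}:{lineno}: unknown key {key!r}")
            typ = float if valid[key] == "float" else int
            kwargs[key] = typ(val)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{k}={getattr(self, k)}" for k in self.__annotations__]
        Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------- #
# FASTQ / FASTA
# --------------------------------------------------------------------------- #

def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> list[Read]:
    """Read a plain or gzipped FASTQ file; qualities decoded as Phred+33."""
    reads: list[Read] = []
    with _open_text(path) as fh:
        try:
            for rec_idx, (title, seq, qual) in enumerate(
                FastqGeneralIterator(fh)
            ):
                if len(seq) != len(qual):
                    raise FormatError(
                        f"{path}: record {rec_idx + 1} (near line "
                        f"{4 * rec_idx + 1}): sequence/quality length mismatch"
                    )
                rid = title.split()[0]
                quals = tuple(ord(c) - 33 for c in qual)
                reads.append(Read(id=rid, seq=seq.upper(), quals=quals))
        except ValueError as exc:  # malformed record from the parser
            raise FormatError(
                f"{path}: near line {4 * len(reads) + 1}: {exc}"
            ) from exc
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            quals = r.quals if r.quals is not None else (30,) * len(r.seq)
            qstr = "".join(chr(min(q, 93) + 33) for q in quals)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qstr}\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) pairs, case folded to upper."""
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            rid = title.split()[0]
            if rid in seen:
                raise FormatError(f"{path}: duplicate sequence id {rid!r}")
            seen.add(rid)
            records.append((rid, seq.upper()))
    return records


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | Path, line_width: int = 80
) -> None:
    with _open_text(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def read_assembly_fasta(path: str | Path, cycle_index: int = 0) -> Assembly:
    """Read contigs from FASTA, honouring ``circular=true|false`` header
    tokens emitted by :func:`write_assembly_fasta`."""
    contigs = []
    with _open_text(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            fields = title.split()
            circular = any(f == "circular=true" for f in fields[1:])
            contigs.append(Contig(fields[0], seq.upper(), circular))
    return Assembly(contigs=contigs, cycle_index=cycle_index)


def write_assembly_fasta(
    assembly: Assembly, path: str | Path, line_width: int = 80
) -> None:
    with _open_text(path, "wt") as fh:
        for c in assembly.contigs:
            fh.write(f">{c.id} circular={'true' if c.circular else 'false'}\n")
            for i in range(0, len(c.seq), line_width):
                fh.write(c.seq[i : i + line_width] + "\n")


# --------------------------------------------------------------------------- #
# PAF
# --------------------------------------------------------------------------- #

_PAF_INT_COLS = (1, 2, 3, 6, 7, 8, 9, 10, 11)


def read_paf(path: str | Path) -> list[Alignment]:
    """Read the 12 mandatory PAF columns into Alignments.

    Residue matches (col 10) are mapped onto ``n_anchor_bases`` and
    identity is matches / alignment block length (col 11).
    """
    alignments: list[Alignment] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected >=12 columns, got {len(cols)}"
                )
            try:
                ints = {i: int(cols[i]) for i in _PAF_INT_COLS}
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate field: {exc}"
                ) from exc
            if cols[4] not in "+-":
                raise FormatError(
                    f"{path}:{lineno}: strand must be '+' or '-', "
                    f"got {cols[4]!r}"
                )
            block = max(ints[10], 1)
            alignments.append(
                Alignment(
                    query_id=cols[0], qlen=ints[1], qstart=ints[2],
                    qend=ints[3], strand=cols[4], target_id=cols[5],
                    tlen=ints[6], tstart=ints[7], tend=ints[8],
                    n_anchor_bases=ints[9],
                    identity_est=min(max(ints[9] / block, 1e-9), 1.0),
                    mapq_proxy=ints[11],
                    block_len=ints[10],
                )
            )
    return alignments


def write_paf(alignments: Iterable[Alignment], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for a in alignments:
            block = a.block_len if a.block_len > 0 else max(a.qspan, a.tspan)
            matches = (
                a.n_anchor_bases
                if a.block_len > 0
                else int(round(a.identity_est * block))
            )
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        a.query_id, a.qlen, a.qstart, a.qend, a.strand,
                        a.target_id, a.tlen, a.tstart, a.tend,
                        matches, block, a.mapq_proxy,
                    )
                )
                + "\n"
            )


# --------------------------------------------------------------------------- #
# misc
# --------------------------------------------------------------------------- #

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def setup_logging(level: int = logging.INFO) -> None:
    if not log.handlers:
        h = logging.StreamHandler()
        h.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        log.addHandler(h)
    log.setLevel(level)
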