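"""The iterative debias/reassemble loop with convergence stop and
consensus scaffolding.

Cycle 0 assembles the QC-filtered reads directly (chimeras trimmed from
read-vs-read overlap support).  Every later cycle maps the *full* filtered
pool against the previous cycle's assembly, subsamples reads over the
depth cap, trims chimeras against that reference, and reassembles.  The
loop stops early when the assembly's total length changes by no more than
``convergence_tol`` (relative), and always after ``max_cycles`` debias
cycles.  All intermediate assemblies are kept: the consensus is built by
scaffolding the representative (fewest-contig) assembly with the others.

Reads are remapped from the full filtered pool each cycle rather than
from the previous cycle's subsample: each cycle's reference covers more
of the genome, so reads discarded earlier can become informative again.

The whole loop is deterministic given the config: identical inputs and
seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .align import all_vs_all, build_index, map_read
from .assemble import assemble
from .chimera import trim_with_overlaps, trim_with_reference
from .debias import subsample_to_cap
from .formats import (
    Assembly,
    PipelineConfig,
    Read,
    write_assembly_fasta,
)
from .qc import filter_reads
from .scaffold import ScaffoldReport, scaffold, select_representative

log = logging.getLogger("sagcycle")


@dataclass
class CycleState:
    cycle_index: int
    retained_read_ids: list[str]
    assembly: Assembly
    converged: bool = False
    debias_report: dict = field(default_factory=dict)
    trim_report: dict = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return self.assembly.total_length


@dataclass
class ScalaResult:
    cycles: list[CycleState]
    consensus: Assembly
    config: PipelineConfig
    scaffold_report: ScaffoldReport | None = None
    filter_report: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "config": {
                k: getattr(self.config, k)
                for k in self.config.__annotations__
            },
            "filter": self.filter_report,
            "cycles": [
                {
                    "cycle": s.cycle_index,
                    "reads_retained": len(s.retained_read_ids),
                    "n_contigs": s.assembly.n_contigs,
                    "total_length": s.total_length,
                    "converged": s.converged,
                    "debias": s.debias_report,
                    "trim": s.trim_report,
                }
                for s in self.cycles
            ],
            "consensus": {
                "n_contigs": self.consensus.n_contigs,
                "total_length": self.consensus.total_length,
                "circular": [c.circular for c in self.consensus.contigs],
            },
            "scaffold_joins_accepted": (
                self.scaffold_report.n_accepted
                if self.scaffold_report
                else 0
            ),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.summary(), indent=2, sort_keys=True) + "\n"
        )


def run_cycle(
    reads: Sequence[Read],
    reference: Assembly | None,
    config: PipelineConfig,
    cycle_index: int = 0,
) -> CycleState:
    """One assembly cycle: either the initial overlap-trimmed assembly
    (no reference) or map -> depth-cap subsample -> reference-mode chimera
    trim -> reassemble.  Reads must already be QC-filtered."""
    try:
        if reference is None or reference.n_contigs == 0:
            retained = [r.id for r in reads]
            overlaps = all_vs_all(reads, min_overlap=config.circular_min_overlap)
            trimmed, trim_rep = trim_with_overlaps(
                reads, overlaps, min_fragment=config.min_len
            )
            debias_rep: dict = {}
        else:
            index = build_index(
                [(c.id, c.seq) for c in reference.contigs]
            )
            alns_by_read = {
                r.id: map_read(r, index, refine_identity=False)
                for r in sorted(reads, key=lambda r: r.id)
            }
            target_lengths = {
                c.id: len(c.seq) for c in reference.contigs
            }
            retained, _, sub_rep = subsample_to_cap(
                reads, alns_by_read, target_lengths, cap=config.depth_cap
            )
            retained_set = set(retained)
            kept_reads = [r for r in reads if r.id in retained_set]
            trimmed, trim_rep = trim_with_reference(
                kept_reads, alns_by_read, min_fragment=config.min_len,
                circular_targets=frozenset(
                    c.id for c in reference.contigs if c.circular
                ),
            )
            debias_rep = {
                "n_mapped": sub_rep.n_mapped,
                "n_unmapped_retained": sub_rep.n_unmapped_retained,
                "n_retained": sub_rep.n_retained,
                "n_rejected": sub_rep.n_rejected,
                "per_target": sub_rep.per_target,
            }
        asm = assemble(
            trimmed,
            genome_size_hint=config.genome_size_hint,
            seed=config.seed,
            cycle_index=cycle_index,
            circular_min_overlap=config.circular_min_overlap,
            circular_min_identity=config.circular_min_identity,
        )
        log.info(
            "cycle %d: %d reads retained, %d contigs, total %d bp",
            cycle_index, len(retained), asm.n_contigs, asm.total_length,
        )
        return CycleState(
            cycle_index=cycle_index,
            retained_read_ids=sorted(retained),
            assembly=asm,
            debias_report=debias_rep,
            trim_report={
                "n_with_breakpoints": trim_rep.n_with_breakpoints,
                "n_breakpoints": trim_rep.n_breakpoints,
                "n_fragments_kept": trim_rep.n_fragments_kept,
                "n_fragments_dropped": trim_rep.n_fragments_dropped,
            },
        )
    except Exception as exc:
        raise RuntimeError(f"cycle {cycle_index} failed: {exc}") from exc


def run_scala(
    reads: Sequence[Read],
    config: PipelineConfig | None = None,
) -> ScalaResult:
    """Full loop: QC filter, Cycle 0, then up to ``max_cycles`` debias
    cycles with the relative-length convergence stop, then consensus
    scaffolding over all intermediate assemblies."""
    cfg = config or PipelineConfig()
    filtered, frep = filter_reads(reads, cfg)
    states: list[CycleState] = [run_cycle(filtered, None, cfg, 0)]
    for k in range(1, cfg.max_cycles + 1):
        prev = states[-1]
        if prev.assembly.n_contigs == 0:
            break
        state = run_cycle(filtered, prev.assembly, cfg, k)
        states.append(state)
        prev_len = prev.total_length
        delta = abs(state.total_length - prev_len) / max(prev_len, 1)
        if delta <= cfg.convergence_tol:
            state.converged = True
            break

    non_empty = [s.assembly for s in states if s.assembly.n_contigs > 0]
    if non_empty:
        rep = select_representative(non_empty)
        others = [a for a in non_empty if a is not rep]
        consensus, srep = scaffold(
            rep, others,
            circular_min_overlap=cfg.circular_min_overlap,
            circular_min_identity=cfg.circular_min_identity,
        )
    else:
        consensus = Assembly(contigs=[], cycle_index=0)
        srep = None
    return ScalaResult(
        cycles=states,
        consensus=consensus,
        config=cfg,
        scaffold_report=srep,
        filter_report={
            "n_input": frep.n_input,
            "n_kept": frep.n_kept,
            "n_too_short": frep.n_too_short,
            "n_low_quality": frep.n_low_quality,
        },
    )


def write_run_outputs(result: ScalaResult, out_dir: str | Path) -> None:
    """Per-cycle FASTAs, final consensus FASTA and a JSON run summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in result.cycles:
        write_assembly_fasta(s.assembly, out / f"cycle{s.cycle_index}.fasta")
    write_assembly_fasta(result.consensus, out / "consensus.fasta")
    result.to_json(out / "run_summary.json")
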