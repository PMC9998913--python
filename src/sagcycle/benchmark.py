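"""The package's reference end-to-end scenario.

A 50 kb circular genome at 37% GC (the GC of the gut anaerobe the method
was built around) is sequenced as five pooled single-cell MDA products:
per-cell breadth drawn from 40-60%, lognormal depth skew sigma=1.5, pooled
mean depth 40x, 1% read error, 1% chimeras, plus 50x error-free 150 bp
short reads for polishing.  Pools are redrawn deterministically until
their reads actually contain the whole genome at assemblable overlap (see
``pooled_sag_long_reads``); a pool that misses part of the genome cannot
close a circle and would be re-pooled at the bench, not assembled.

``run_end_to_end`` executes the full workflow (filter, cycle-0 assembly,
debias/reassemble cycles, consensus scaffolding, polish, circularize) and
returns the measurements the workflow is judged by.
"""

from __future__ import annotations

from dataclasses import dataclass

from .circular import canonical_rotation
from .finishing import finish_assembly
from .formats import Assembly, PipelineConfig, Read
from .metrics import assembly_identity, duplication_ratio, genome_fraction
from .pipeline import ScalaResult, run_scala
from .simulate import (
    TruthGenome,
    pooled_sag_long_reads,
    sample_short_reads,
    simulate_genome,
)

GENOME_LEN = 50_000
GC = 0.37
N_SAGS = 5
POOLED_DEPTH = 40.0
BREADTH_RANGE = (0.4, 0.6)
SKEW = 1.5
ERROR_RATE = 0.01
CHIMERA_RATE = 0.01
SHORT_DEPTH = 50.0
SHORT_LEN = 150
MIN_POOLED_COV = 3


@dataclass
class Scenario:
    genome: TruthGenome
    long_reads: list[Read]
    short_reads: list[Read]
    seed: int


@dataclass
class EndToEndResult:
    scenario: Scenario
    scala: ScalaResult
    final: Assembly
    genome_fraction_cycle0: float
    genome_fraction_final: float
    identity_final: float
    duplication_final: float
    exact_match: bool

    @property
    def n_contigs_final(self) -> int:
        return self.final.n_contigs

    @property
    def n_circular_final(self) -> int:
        return sum(c.circular for c in self.final.contigs)


def build_scenario(seed: int) -> Scenario:
    """Deterministic scenario instance; all randomness derives from seed."""
    genome = simulate_genome(GENOME_LEN, GC, seed=7 * seed + 1,
                             circular=True)
    long_reads, _ = pooled_sag_long_reads(
        genome, n_sags=N_SAGS, pooled_mean_depth=POOLED_DEPTH,
        breadth_range=BREADTH_RANGE, min_union_breadth=0.99,
        min_pooled_cov=MIN_POOLED_COV, skew=SKEW,
        error_rate=ERROR_RATE, chimera_rate=CHIMERA_RATE,
        seed=7 * seed + 2,
    )
    short_reads = sample_short_reads(
        genome, depth=SHORT_DEPTH, read_len=SHORT_LEN, seed=7 * seed + 3
    )
    return Scenario(genome=genome, long_reads=long_reads,
                    short_reads=short_reads, seed=seed)


def run_end_to_end(seed: int, config: PipelineConfig | None = None) -> EndToEndResult:
    sc = build_scenario(seed)
    cfg = config or PipelineConfig(
        depth_cap=50, max_cycles=4, genome_size_hint=GENOME_LEN, seed=seed
    )
    scala = run_scala(sc.long_reads, cfg)
    final, _ = finish_assembly(scala.consensus, sc.short_reads, config=cfg)
    gf0 = genome_fraction(scala.cycles[0].assembly, sc.genome)
    gff = genome_fraction(final, sc.genome)
    ident = assembly_identity(final, sc.genome)
    dup = duplication_ratio(final, sc.genome) if gff > 0 else float("nan")
    exact = (
        final.n_contigs == 1
        and final.contigs[0].circular
        and final.contigs[0].seq == canonical_rotation(sc.genome.seq)
    )
    return EndToEndResult(
        scenario=sc, scala=scala, final=final,
        genome_fraction_cycle0=gf0, genome_fraction_final=gff,
        identity_final=ident, duplication_final=dup, exact_match=exact,
    )
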