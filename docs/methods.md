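# Methods

## Problem and approach

Multiple displacement amplification (MDA) of a single bacterial cell
produces micrograms of high-molecular-weight DNA from femtograms of
template, which makes long-read sequencing of single cells possible — but
the amplification is neither uniform nor faithful. Two artifact classes
dominate: *coverage bias* (some genomic regions amplified orders of
magnitude more than others, with large contiguous regions not amplified at
all, so a single cell typically yields only 40–60% of its genome) and
*chimeras* (molecules that join non-adjacent, possibly inverted, genomic
segments). Assembling such reads directly yields fragmented, incomplete,
partially misjoined drafts.

`sagcycle` implements an iterative workflow that pools the long reads of
several single-cell products of one strain and alternates between
assembly and mapping-based *depth debiasing*:

1. **QC filter** — drop the first 75 bases of every read, then remove
   reads shorter than 1 kb or with probability-space mean quality below
   Q10 (thresholds inclusive: boundary reads survive).
2. **Cycle 0** — detect chimeras from all-vs-all overlap support, split
   them, and assemble the reads into intermediate reference contigs.
3. **Cycles 1…N** — map the *full* filtered pool against the previous
   assembly; subsample reads so that no reference position retains more
   than a depth cap (default 50×); trim chimeras against the reference;
   reassemble. Stop early when the assembly's total length changes by at
   most `convergence_tol` (default 0.1%), and always after `max_cycles`
   (default 4) debias cycles.
4. **Consensus scaffolding** — choose the intermediate assembly with the
   fewest contigs as representative and stitch its contigs together
   wherever two of their ends co-locate on a single contig of another
   cycle's assembly, splicing the linking sequence from that donor. No
   external reference genome is used at any point.
5. **Finishing** — polish with short reads from the same cells (pileup
   majority), re-attempt circularization, and fill N-gaps with short-read
   contigs when available.

Each cycle's reads are drawn from the full filtered pool rather than the
previous cycle's subsample: every new reference covers more of the
genome, so reads discarded earlier can become informative again.

## Why debiasing helps

The depth cap does not add information; it removes the excess that drowns
out the scarce. Assemblers (and our consensus stage) weight evidence by
depth, and extreme depth ratios (hot regions can exceed 100× while unique
regions sit at 3–5×) distort overlap selection and bury low-coverage
joins. Capping retained depth at 50× equalizes the evidence landscape, so
each reassembly extends further into the under-amplified territory. The
convergence criterion — total assembly length stable to 0.1% — detects
when additional cycles stop adding sequence.

The subsampling rule is a greedy sweep over primary alignments sorted by
(target, start, −length, read id): a read is retained iff at least one
position in its span still has retained depth below the cap. Two exact
guarantees follow: **P1**, every position's final depth is at least
min(cap, its unsubsampled depth) — the sweep can never starve a position;
**P2**, every rejected read lies entirely in saturated territory.
Positions may exceed the cap where a read was kept for a neighbouring
low-depth position; that slack is intentional. Unmapped reads are always
retained: they may cover regions the current reference lacks, which are
exactly the regions debiasing is meant to recover.

## Built-in mapper and assembler

The mapper indexes (w=10, k=15) minimizers of the canonical strand,
collects shared minimizers as anchors, and chains them per (target,
strand) within a 500 bp diagonal band. Chain spans become alignments;
identity is computed by a banded edit-distance alignment (edlib) over the
chained spans, because anchor density systematically underestimates
identity on noisy reads and every downstream decision threshold (scaffold
anchors ≥ 95%, gap filling ≥ 99%, genome fraction ≥ 90%) needs real
identities. Chain ends stop up to ~k bp short of the true match
boundary; consumers that need exact boundaries (scaffolding, metrics)
extrapolate to the full query extent, bounded by the room left on both
sequences.

The assembler is a deliberately minimal overlap-layout-consensus engine:
all-vs-all overlaps, contained-read removal, a mutual best-buddy dovetail
graph (each read end keeps its single best partner, and an edge survives
only if both ends choose it — which leaves every end with degree ≤ 1 and
makes separate transitive-edge removal unnecessary), unitig traversal,
and a pileup-majority consensus (two rounds of per-read banded
realignment to the layout backbone). A unitig whose end duplicates its
start (≥ 500 bp at ≥ 95% identity, verified end-to-end) is closed,
trimmed, and rotated to canonical form — the lexicographically smaller of
the least rotations of the two strands — so circular-genome equality is
plain string equality. Repeats longer than a read fragment the assembly;
the debias/scaffold cycle, not the assembler, is the mechanism for
contiguity. Everything is processed in sorted-id order with lexicographic
tie-breaks: the output depends only on the read *set*, never input order,
and no stage draws random numbers, so a fixed seed reproduces the output
byte for byte.

## Chimera detection

Two modes:

* **Overlap mode** (cycle 0): per read, count how many other reads span
  each position by ≥ 100 bp on both sides. An interior zero-support run
  flanked by supported regions marks a junction — but only runs ≥ 120 bp:
  a shorter dip is the span-margin shadow of a thin-but-real bridge
  between two read groups, whereas a true junction shadows the full
  ±100 bp margin. Unsupported *end* runs longer than 250 bp are trimmed
  off (junk tails of undetected chimeric ends).
* **Reference mode** (cycles ≥ 1): adjacent mappings of one read are
  discordant if they hit different targets or strands, jump forward by
  more than 1 kb beyond the query gap, or jump *backward* by more than
  100 bp — the fold-back signature of re-copied template, which must be
  caught at any magnitude. Discordance is waived when the read simply
  runs off one contig end onto another contig's start (reference
  fragmentation) or wraps the origin of a circular reference contig.
  Unmapped interior stretches cut a read only when the reference
  coordinates jump forward past more sequence than the query skipped;
  a read carrying sequence the reference *lacks* is never cut — those
  reads are the point of the debiasing cycle.

Fragments shorter than 1 kb after splitting are discarded (matching the
read-length filter).

## Polishing and gap filling

Polishing maps short reads with (w=5, k=21) minimizers, clips each read
to its mapped extent, realigns it to its local window, and accumulates
per-column base/deletion votes plus single-base insertion votes. A
position changes only at coverage ≥ 4 with ≥ 70% agreement, so clean
input is a fixed point. Circular contigs get an extra pass at a half
rotation so corrections can span the origin, and are emitted in canonical
rotation. Circularization is re-attempted after polishing: residual
consensus noise concentrated at single-coverage unitig margins can hold a
true end overlap just below the identity gate until polishing cleans it.

Gap filling replaces a maximal N-run when one short-read contig matches
both flanks (default ≥ 500 bp at ≥ 99% identity) in consistent
orientation with an implied span within 2× the run length; multiple
candidates with different filler sequences leave the gap untouched and
logged. Non-N bases are never altered.

## Synthetic MDA model

The simulator is phenomenological: it reproduces the observable
statistics the pipeline must overcome, not phi29 branching mechanics.

* **Amplification bias**: random cut points partition the genome into
  amplicon tiles, each with a lognormal(0, σ) efficiency over a uniform
  background floor of 10% of the mean tile efficiency. Tiling (rather
  than scattered amplicon windows) guarantees every position belongs to
  an amplicon while preserving the full heavy upper tail — at σ=2 the
  95th-percentile/median weight ratio is ≈ e^(1.645·2) ≈ 27. The floor
  models weak background amplification and keeps the coldest tile at
  roughly a tenth of the mean sampling rate.
* **Dropout**: contiguous segments (length L/16–L/6) are zeroed until the
  amplified fraction matches the target breadth, mirroring how
  unamplified regions appear as large missing blocks.
* **Reads**: start positions are drawn proportional to weight; a read
  truncates at the first dropout position it meets (an unamplified region
  has no template), and wraps the origin of circular genomes. With
  probability `chimera_rate` a read is the concatenation of two
  independently drawn segments, the second in either orientation, with
  the junction offset recorded exactly. Errors are injected per base at
  `error_rate`, split 60:20:20 substitution:insertion:deletion. Each read
  carries its origin interval(s) and junction offset(s) as ground truth,
  and identical seeds give byte-identical FASTQ and truth files.
* **Pooling**: each cell draws its own breadth from the configured range;
  pools are redrawn (deterministically, bounded) until the dropout-mask
  union reaches the configured floor and — when a minimum pooled coverage
  is requested — until the non-chimeric reads cover every position at
  that depth with ≥ ~500 bp tiling overlap. The gate encodes a study
  design precondition: a pool whose reads do not contain the whole genome
  at assemblable overlap cannot close a circle and would be re-pooled at
  the bench, not assembled. Chimeric reads are excluded from the gate
  because the pipeline removes them.

What the simulator does **not** model: per-base quality variation within
a read (flat Q per read), multi-strain mixtures, systematic GC-dependent
bias, adapter/barcode remnants, and real nanopore homopolymer error
structure. Passing tests therefore demonstrate the pipeline's logic under
controlled MDA-like artifact statistics, not its performance on any
particular instrument's data.

## Reference scenario and problem sizes

The end-to-end benchmark (`sagcycle.benchmark`) uses a 50 kb circular
genome at 37% GC — desk-scale for a workflow whose field targets are
3–5 Mb gut anaerobe chromosomes — with 5 pooled cells, breadths 40–60%,
skew σ=1.5, 40× pooled depth, 1% read error, 1% chimeras, and 50× clean
150 bp short reads. At these sizes a complete run (filter, 2–5 assembly
cycles, scaffold, polish) takes well under a minute on one core. Property
measurements use 200 random subsampler instances, 500 chimeric plus 500
clean reads, and a 20 kb exactness genome; these sizes make every check a
few seconds while keeping the binomial error bars far from the asserted
margins.

## Numerical and design choices

* Coordinates are 0-based half-open on the forward target strand
  everywhere; PAF is the on-disk alignment dialect; FASTQ is Phred+33.
* Mean read quality is the Phred-scaled mean error *probability*, which
  penalizes low-quality stretches more than an arithmetic mean of Phred
  scores; the two differ by under one Phred unit for typical reads, and
  the boundary comparison carries a 1e-9 epsilon against log-space
  rounding.
* "Total length did not change" is implemented as relative tolerance
  1e-3 (configurable; 0 restores literal equality), because consensus
  jitter of a few bases per cycle is expected.
* Representative selection: fewest contigs, then largest total length,
  then latest cycle.
* Scaffold joins are accepted greedily by descending anchor length under
  an each-end-used-once constraint with union-find cycle refusal; the one
  permitted cycle-closing link per chain marks that chain circular.
  Donor-image overlaps up to 2 kb are resolved by trimming the incoming
  contig rather than splicing.
* The headcrop step is one-time preprocessing: applying the full filter
  twice would crop twice, so idempotence holds for (and is tested on)
  the threshold rules.
* Degenerate inputs: empty read sets produce empty assemblies, not
  errors; empty FASTQ files parse to empty lists; zero-coverage polish
  positions are untouched.

## Known limitations

* The assembler is unitig-only; repeats longer than a read break
  contigs, and no repeat resolution is attempted.
* Chimeras whose second segment starts within ~1 kb downstream of the
  first (same strand) are indistinguishable from reads with a small
  deletion and are not detected; their effect is absorbed by consensus
  majority.
* Overlap-mode chimera detection cannot distinguish a unique true bridge
  from a junction when no third read spans the region; the 120 bp
  interior-run floor trades a small recall loss for not cutting unique
  bridges.
* The depth cap is global and per-position; no per-contig or windowed
  cap is offered.
* `fragment_ani` is a fragment-mapping approximation adequate for
  same-species comparisons; it is not a drop-in for alignment-based ANI
  tools at low identity.
* Marker-gene completeness/contamination is not computed (it requires
  curated HMM databases); the strain-grouping rule accepts precomputed
  marker homology values, and "completeness" in this package's tests
  always means genome fraction against a known truth sequence.
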