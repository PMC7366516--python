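# Methods

## The data model

A *homology map* is the unit of input: for one taxon, a list of segment
assignments "ancestral chromosome (region) ↔ descendant chromosome (region)"
plus the diploid number 2n. Ancestral labels live in one of two
interconvertible schemes — PAK (Putative Avian Ancestral Karyotype, PAK1–15,
2n = 80) and chicken (GGA) — related by the fixed table PAK1–15 ↔ GGA1, 2, 3,
4q, 5, 6, 7, 8, 9, 4p, 10, 11, 12, 13, 14. Chicken chromosome 4 is the one
non-trivial case: taken whole it corresponds to *two* ancestral elements
(PAK4 = GGA4q, PAK10 = GGA4p), so GGA→PAK conversion expands an unqualified
GGA4 assignment into both. Arm and proximal/distal qualifiers are recorded
faithfully but **event detection operates at whole-descendant-chromosome
resolution**, because that is the level at which painting evidence is
reported; chromosome coordinates are never used. Unidentifiable
microchromosomes (a bare "micro" in a published table) form a reserved label
class: each such entry is a distinct element, two "micro" entries never
co-localise, and the class never enters character coding.

Detection rules:

* **fusion** — a descendant chromosome carrying homologies to ≥ 2 distinct
  ancestral chromosomes; the event's participants are the full ancestral set
  on that chromosome.
* **fission** — an ancestral chromosome assigned to ≥ 2 distinct descendant
  chromosomes, annotated with the descendant count.

## Character coding

Characters are binary presence/absence states over taxa:

* a **fusion-association** character is a canonical participant *set*
  (a triple fusion is one character, not three pairs). Presence is scored by
  superset: a chromosome carrying {PAK6, PAK7, PAK11} also exhibits the
  {PAK6, PAK7} association, matching how associations are reported in the
  painting literature.
* a **fission-pattern** character is a pair (ancestral chromosome,
  descendant count), present when the count matches *exactly*. Successive
  fission states (2, 3, 4 products) are therefore distinct characters rather
  than an ordered series — binary coding cannot express the ordering, and the
  source data report each taxon's realised count, not a fission count per
  branch.
* **inversion** and other qualitative characters have no machine-checkable
  predicate at painting resolution; they can be appended manually
  (`CharacterMatrix.with_character`) but are never auto-coded.

A taxon scores `?` whenever any chromosome in a character's definition has no
assignment in its map (un-assayed ≠ absent); this is how outgroups behave for
microchromosome characters. Two coding modes exist: automatic coding from
maps (the deterministic scheme above) and loading an explicit user-supplied
NEXUS/PHYLIP matrix; the packaged `reconstructed_matrix.nex` is of the second
kind, derived from the first plus two manually supplied micro-fusion
characters (see the data README — it is a reconstruction, and statistics
computed from it describe the reconstruction only).

## Parsimony engine

Tree length uses Fitch's algorithm for unordered binary characters, with all
characters of a matrix packed two bits per character into a single Python
integer per node; one evaluation is a handful of bitwise operations per
internal node, independent of character count. `?` enters as the full state
set {0, 1} (union semantics) and never forces a change. Multifurcating trees
(consensus topologies) are scored by Hartigan's generalisation, which equals
Fitch on binary trees; this slower per-character path also provides the
per-character step vectors for the ensemble statistics.

Statistics, with mᵢ the minimum conceivable steps of character i (1 if
variable over observed states, else 0), Mᵢ its steps on a star tree
(min of the two observed state counts), and L the tree length:
CI = Σmᵢ/L (defined as 1.0 when L = 0), HI = 1 − CI,
RI = (ΣMᵢ − L)/(ΣMᵢ − Σmᵢ), reported as undefined when ΣMᵢ = Σmᵢ.

Search:

* **exhaustive** — recursive stepwise insertion enumerating all (2n−5)!!
  unrooted binary topologies (10,395 for the 8-taxon problems this package
  targets; refused above a configurable 10 taxa), returning every optimal
  tree. This is the oracle for the heuristic.
* **heuristic** — random-addition-sequence stepwise addition (greedy
  placement, ties broken by the seeded RNG) followed by TBR hill climbing
  that keeps a pool of all equally parsimonious trees and explores each
  equal-length plateau to closure; 10 addition replicates by default,
  unlimited tree buffer, results pooled and deduplicated by topology
  (canonical bipartition sets). All tie-breaking flows from the seed or a
  canonical edge ordering, never from ambient hash order, so runs are
  bit-for-bit reproducible. Known limitation: equally parsimonious trees can
  occupy disconnected TBR "islands"; a replicate only enumerates the islands
  it lands on, so on random matrices the full MP set is recovered in roughly
  96–98% of cases (the optimum *length* is reached far more reliably).
* **bootstrap** — characters resampled with replacement to the original
  count; per replicate the configured search runs (default: a fast heuristic
  profile with 2 addition replicates, adequate for resampled 8-taxon
  matrices) and the splits of the replicate's strict consensus are counted
  once each, making the per-replicate contribution deterministic. Support is
  the percentage of replicates containing a split, reported on 0–100; a
  matrix with no informative characters is flagged as degenerate.

Consensus trees (strict and majority-rule with threshold ≥ 0.5) are built
from compatible split sets; outgroup rooting places the root on the edge
separating outgroup from ingroup, falling back with a warning to the edge
that best separates them when the outgroup is not monophyletic.
Robinson–Foulds distance is the symmetric difference of internal bipartition
sets. dendropy handles all Newick/NEXUS/PHYLIP parsing; dendropy's own RF and
consensus implementations serve as independent cross-checks in the test
suite, never as the implementation.

## The simulator and what it does (not) emulate

`karyosim` evolves a template of 15 macrochromosomes (10 elementary blocks
each) plus 25 microchromosome pairs (2 blocks each; 2n = 80 in total) along a
rooted tree with branch lengths. Per branch and event type the event count is
Poisson(rate × length); defaults are 0.5 fusions, 0.5 fissions and 0.25
inversions per unit branch length, chosen so a unit-depth 8-taxon tree yields
matrices of roughly the size real painting datasets reach (a few dozen
characters). Fusions are tandem concatenations of two uniformly chosen
chromosomes (painting cannot distinguish centric from tandem fusion, so the
distinction is not modelled); fissions split a uniformly chosen multi-block
chromosome at a uniform internal block boundary; inversions reverse a
contiguous block run in place and are invisible to whole-chromosome homology
maps — deliberately mirroring the real data's blindness to intrachromosomal
rearrangement. Simulated micros carry extended ancestral indices (PAK16…), so
micro/macro fusions — the mechanism that drives diploid-number reduction in
real parrot karyotypes — are identifiable and codable, unlike in real tables.

`allow_breakpoint_reuse=False` (default, "clean mode") restricts every
ancestral chromosome to at most one fusion/fission across the whole
simulation (ineligible draws are resampled, then dropped with a log entry).
In this mode three oracle identities hold exactly and are enforced by tests:
detection on tip maps reproduces the event log; the automatically coded
matrix equals the truth matrix column for column; and the truth matrix is
homoplasy-free (CI = 1.0) on the true tree. With reuse enabled, chained
fusions, re-fissions and genuine homoplasy become possible; the truth matrix
then scores an event present at a tip only if no later event on that tip's
path undid its junction.

What the simulator does *not* emulate: sequence evolution, repeat
accumulation and W-chromosome amplification, flow-sorting artefacts,
arm-level assignment noise, and probe-sensitivity differences. Passing the
end-to-end tests therefore demonstrates correctness of detection, coding and
inference given faithful whole-chromosome homology calls — not robustness to
the wet-lab error modes of real painting data.

## Study-scale calibration of the recovery experiment

The topology-recovery experiment uses a fixed balanced 8-taxon tree with
internal branch lengths 4.5 and terminal lengths 0.25 (the two root-adjacent
branches carry 2.25 each, forming one unrooted internal edge of total 4.5).
At the default rates each internal edge then expects ≈ 4.5 interchromosomal
events, and the expected label consumption (≈ 37 of the 40 available
ancestral elements in clean mode) stays within budget. Because the criterion
of interest is inference *given adequate signal*, each dataset is drawn with
`simulate_conditioned`, which redraws (with derived seeds) until every
internal edge of the true tree carries at least 3 fusion/fission events —
realising, not merely expecting, a per-edge floor of three clean informative
characters. Under that condition the strict consensus of the heuristic's MP
trees matches the true tree essentially always; unconditioned draws fail in
a few percent of runs purely through Poisson zeros on an edge.

## Numerical and degenerate-input conventions

* Matrices must have at least one observed state per character; columns of
  all-`?` are rejected at construction.
* `exhaustive_search` needs ≥ 3 taxa, `heuristic_search` and TBR ≥ 4;
  building a matrix from 2 taxa warns but proceeds.
* A fission draw hitting a single-block chromosome is resampled (logged),
  as is any clean-mode draw without pristine participants.
* Bootstrap with `replicates=1` is legal and yields supports in {0, 100}.
* Seeds: every stochastic entry point (heuristic search, bootstrap,
  simulation, the pipeline config) takes an explicit integer seed; derived
  seeds are drawn below 2³¹.
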