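"""Simulate karyotype evolution (fusion/fission/inversion) along a tree.

The simulator starts from an avian-ancestor-like template — macrochromosomes
PAK1..PAK15 plus a pool of microchromosomes, 2n = 80 by default — and walks a
rooted tree with branch lengths, drawing Poisson numbers of events per branch
and type.  Chromosomes are sequences of elementary blocks, each labelled by
its ancestral chromosome of origin, so fissions can occur inside a pristine
ancestral chromosome (at any block boundary) and every tip karyotype can be
re-expressed as a painting-style homology map against the ancestral labels.

Event semantics:

* **fusion** — tandem concatenation of two uniformly chosen chromosomes
  (centric vs tandem is not distinguished; painting cannot resolve it);
* **fission** — split of a uniformly chosen multi-block chromosome at a
  uniformly chosen internal block boundary;
* **inversion** — in-place reversal of a contiguous block run; invisible to
  whole-chromosome homology maps, hence never a coded character.

With ``allow_breakpoint_reuse=False`` (the default, "clean mode") every
ancestral chromosome participates in at most one fusion or fission over the
whole simulation; events that cannot find pristine participants are resampled
and finally dropped with a log message.  In this mode each realised event
marks exactly one clade of the true tree, detection from the tip maps recovers
the event log exactly, and the truth matrix is homoplasy-free (CI = 1 on the
true tree).  Simulated microchromosomes carry extended ancestral indices
(PAK16, PAK17, ...) so that micro/macro fusions — the mechanism that drives
diploid-number reduction in real parrot karyotypes — are fully identifiable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .coding import CharacterMatrix, RearrangementCharacter, STATE_CODES
from .homology import HomologyMap, SegmentAssignment
from .labels import PAK, ChromosomeLabel
from .trees import Phylotree

logger = logging.getLogger(__name__)

Block = tuple[int, int]          # (ancestral number, part index)
Segment = tuple[int, int, int]   # (ancestral number, part index, orientation)
Chromosome = tuple[Segment, ...]

_MAX_RESAMPLE = 100


@dataclass(frozen=True)
class AncestralTemplate:
    """The starting karyotype: PAK-like macros plus a microchromosome pool."""

    n_macro: int = 15
    n_micro: int = 25
    macro_blocks: int = 10
    micro_blocks: int = 2

    def __post_init__(self) -> None:
        if self.n_macro < 1 or self.n_micro < 0:
            raise ValueError("template needs at least one macrochromosome")

    @property
    def diploid_number(self) -> int:
        return 2 * (self.n_macro + self.n_micro)

    @property
    def ancestral_numbers(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_macro + self.n_micro + 1))

    def is_micro(self, ancestral: int) -> bool:
        return ancestral > self.n_macro

    def genome(self) -> list[Chromosome]:
        chroms = []
        for a in self.ancestral_numbers:
            nb = self.micro_blocks if self.is_micro(a) else self.macro_blocks
            chroms.append(tuple((a, p, 1) for p in range(1, nb + 1)))
        return chroms


@dataclass(frozen=True)
class EvolutionModel:
    """Expected events per unit branch length, per event type."""

    fusion_rate: float = 0.5
    fission_rate: float = 0.5
    inversion_rate: float = 0.25
    seed: Optional[int] = None
    allow_breakpoint_reuse: bool = False

    def __post_init__(self) -> None:
        if min(self.fusion_rate, self.fission_rate, self.inversion_rate) < 0:
            raise ValueError("rates must be non-negative")
        if self.fusion_rate == self.fission_rate == self.inversion_rate == 0:
            logger.warning("all rates are zero; the simulation is degenerate")


@dataclass(frozen=True)
class SimEvent:
    """One realised rearrangement on one branch of the true tree."""

    index: int                 # global order of application
    kind: str                  # fusion | fission | inversion
    branch: str                # id of the child node of the branch
    participants: frozenset[ChromosomeLabel]
    adjacency: Optional[tuple[Block, Block]]  # created (fusion) / removed (fission)
    payload: dict = field(default_factory=dict, compare=False)


@dataclass
class SimulationResult:
    """Tip maps, true tree, per-branch event log, and tip genomes."""

    template: AncestralTemplate
    model: EvolutionModel
    newick: str
    true_tree: Phylotree
    taxa: tuple[str, ...]
    tip_genomes: dict[str, list[Chromosome]]
    tip_maps: tuple[HomologyMap, ...]
    events: tuple[SimEvent, ...]
    tip_paths: dict[str, tuple[str, ...]]  # root-to-tip branch (child-node) ids

    def events_on_path(self, taxon: str) -> list[SimEvent]:
        path = set(self.tip_paths[taxon])
        return [e for e in self.events if e.branch in path]


def _anc_label(a: int) -> ChromosomeLabel:
    return ChromosomeLabel(PAK, a)


def _labels_of(chrom: Chromosome) -> set[int]:
    return {seg[0] for seg in chrom}


def _apply_fusion(genome: list[Chromosome], i: int, j: int) -> Chromosome:
    left, right = genome[i], genome[j]
    fused = left + right
    for k in sorted((i, j), reverse=True):
        del genome[k]
    genome.append(fused)
    return fused


def _apply_fission(genome: list[Chromosome], i: int, cut: int
                   ) -> tuple[Chromosome, Chromosome]:
    chrom = genome[i]
    left, right = chrom[:cut], chrom[cut:]
    del genome[i]
    genome.append(left)
    genome.append(right)
    return left, right


def _apply_inversion(genome: list[Chromosome], i: int, a: int, b: int) -> None:
    chrom = list(genome[i])
    run = [(anc, p, -o) for (anc, p, o) in reversed(chrom[a:b + 1])]
    genome[i] = tuple(chrom[:a] + run + chrom[b + 1:])


def _boundary_blocks(left: Chromosome, right: Chromosome) -> tuple[Block, Block]:
    return (left[-1][:2], right[0][:2])


class _Simulator:
    def __init__(self, model: EvolutionModel, template: AncestralTemplate,
                 rng: np.random.Generator):
        self.model = model
        self.template = template
        self.rng = rng
        self.used_labels: set[int] = set()   # clean-mode bookkeeping
        self.used_boundaries: set[frozenset[Block]] = set()
        self.events: list[SimEvent] = []
        self.counter = 0

    # -- eligibility --------------------------------------------------------
    def _pristine(self, chrom: Chromosome) -> bool:
        return not (_labels_of(chrom) & self.used_labels)

    def _mark(self, chrom: Chromosome) -> None:
        self.used_labels |= _labels_of(chrom)

    # -- event draws --------------------------------------------------------
    def _draw_fusion(self, genome: list[Chromosome]):
        clean = not self.model.allow_breakpoint_reuse
        for _ in range(_MAX_RESAMPLE):
            if len(genome) < 2:
                return None
            i, j = self.rng.choice(len(genome), size=2, replace=False)
            i, j = int(i), int(j)
            if clean and not (self._pristine(genome[i]) and
                              self._pristine(genome[j])):
                continue
            return i, j
        return None

    def _draw_fission(self, genome: list[Chromosome]):
        clean = not self.model.allow_breakpoint_reuse
        for _ in range(_MAX_RESAMPLE):
            i = int(self.rng.integers(len(genome)))
            chrom = genome[i]
            if len(chrom) < 2:
                continue  # no internal boundary: resample
            if clean and not self._pristine(chrom):
                continue
            cut = int(self.rng.integers(1, len(chrom)))
            boundary = frozenset(_boundary_blocks(chrom[:cut], chrom[cut:]))
            if clean and boundary in self.used_boundaries:
                continue
            return i, cut
        return None

    # -- branch -------------------------------------------------------------
    def evolve_branch(self, genome: list[Chromosome], length: float,
                      branch_id: str) -> None:
        r = self.model
        kinds = (["fusion"] * int(self.rng.poisson(r.fusion_rate * length))
                 + ["fission"] * int(self.rng.poisson(r.fission_rate * length))
                 + ["inversion"] * int(self.rng.poisson(r.inversion_rate * length)))
        self.rng.shuffle(kinds)
        for kind in kinds:
            if kind == "fusion":
                draw = self._draw_fusion(genome)
                if draw is None:
                    logger.info("branch %s: fusion dropped (no eligible "
                                "participants)", branch_id)
                    continue
                i, j = draw
                participants = frozenset(
                    _anc_label(a) for a in _labels_of(genome[i]) | _labels_of(genome[j]))
                left, right = genome[i], genome[j]
                if not self.model.allow_breakpoint_reuse:
                    self._mark(left)
                    self._mark(right)
                adjacency = _boundary_blocks(left, right)
                self.used_boundaries.add(frozenset(adjacency))
                _apply_fusion(genome, i, j)
                self._log(kind, branch_id, participants, adjacency,
                          {"left": left, "right": right})
            elif kind == "fission":
                draw = self._draw_fission(genome)
                if draw is None:
                    logger.info("branch %s: fission dropped (no eligible "
                                "chromosome/boundary)", branch_id)
                    continue
                i, cut = draw
                chrom = genome[i]
                participants = frozenset(_anc_label(a) for a in _labels_of(chrom))
                if not self.model.allow_breakpoint_reuse:
                    self._mark(chrom)
                adjacency = _boundary_blocks(chrom[:cut], chrom[cut:])
                self.used_boundaries.add(frozenset(adjacency))
                _apply_fission(genome, i, cut)
                self._log(kind, branch_id, participants, adjacency,
                          {"chrom": chrom, "cut": cut})
            else:
                i = int(self.rng.integers(len(genome)))
                chrom = genome[i]
                a = int(self.rng.integers(len(chrom)))
                b = int(self.rng.integers(a, len(chrom)))
                participants = frozenset(
                    _anc_label(x) for x in {s[0] for s in chrom[a:b + 1]})
                _apply_inversion(genome, i, a, b)
                self._log(kind, branch_id, participants, None,
                          {"chrom": chrom, "span": (a, b)})

    def _log(self, kind, branch_id, participants, adjacency, payload):
        self.events.append(SimEvent(
            index=self.counter, kind=kind, branch=branch_id,
            participants=participants, adjacency=adjacency, payload=payload))
        self.counter += 1


def _tip_map(taxon: str, genome: Sequence[Chromosome]) -> HomologyMap:
    ordered = sorted(genome, key=lambda c: (-len(c), c))
    assignments = []
    for num, chrom in enumerate(ordered, start=1):
        seen: list[int] = []
        for seg in chrom:
            if seg[0] not in seen:
                seen.append(seg[0])
        for anc in seen:
            assignments.append(SegmentAssignment(
                taxon=taxon, ancestral=_anc_label(anc),
                descendant=ChromosomeLabel(taxon, num),
                evidence="inferred"))
    return HomologyMap(taxon, 2 * len(genome), tuple(assignments))


def simulate(tree: "str | dendropy.Tree", model: EvolutionModel,
             template: AncestralTemplate | None = None) -> SimulationResult:
    """Evolve the template along ``tree`` (rooted Newick with branch lengths).

    Per branch and event type the number of events is Poisson(rate x length).
    Fully reproducible for a fixed ``model.seed``.
    """
    template = template or AncestralTemplate()
    if isinstance(tree, dendropy.Tree):
        dtree = tree
    else:
        dtree = dendropy.Tree.get(data=str(tree), schema="newick",
                                  preserve_underscores=True)
    newick = dtree.as_string(schema="newick").strip()
    for edge in dtree.preorder_edge_iter():
        if edge.head_node is not dtree.seed_node and edge.length is None:
            raise ValueError("every branch of the input tree needs a length")
    rng = np.random.default_rng(model.seed)
    sim = _Simulator(model, template, rng)

    # stable ids for branches: leaf label, or a preorder internal id
    ids: dict[int, str] = {}
    internal = 0
    for nd in dtree.preorder_node_iter():
        if nd.is_leaf():
            ids[id(nd)] = nd.taxon.label
        else:
            ids[id(nd)] = f"node{internal}"
            internal += 1

    genomes: dict[int, list[Chromosome]] = {id(dtree.seed_node): template.genome()}
    tip_genomes: dict[str, list[Chromosome]] = {}
    tip_paths: dict[str, tuple[str, ...]] = {}
    paths: dict[int, tuple[str, ...]] = {id(dtree.seed_node): ()}
    for nd in dtree.preorder_node_iter():
        if nd is dtree.seed_node:
            continue
        parent = nd.parent_node
        genome = [c for c in genomes[id(parent)]]
        branch_id = ids[id(nd)]
        sim.evolve_branch(genome, float(nd.edge.length), branch_id)
        genomes[id(nd)] = genome
        paths[id(nd)] = paths[id(parent)] + (branch_id,)
        if nd.is_leaf():
            tip_genomes[nd.taxon.label] = genome
            tip_paths[nd.taxon.label] = paths[id(nd)]

    taxa = tuple(sorted(tip_genomes))
    maps = tuple(_tip_map(t, tip_genomes[t]) for t in taxa)
    true_tree = Phylotree.from_dendropy(dtree, taxa=taxa)
    return SimulationResult(
        template=template, model=model, newick=newick, true_tree=true_tree,
        taxa=taxa, tip_genomes=tip_genomes, tip_maps=maps,
        events=tuple(sim.events), tip_paths=tip_paths)


def internal_edge_event_counts(result: SimulationResult) -> dict[int, int]:
    """Interchromosomal (fusion/fission) event counts per internal edge of
    the unrooted true tree, keyed by canonical split mask.

    The two branches flanking a rooted tree's root mark the same unrooted
    split and are counted together.  Used to check that a simulated dataset
    carries enough clean character signal per edge to identify the topology.
    """
    n = len(result.taxa)
    full = (1 << n) - 1
    branch_mask: dict[str, int] = {}
    for i, t in enumerate(result.taxa):
        for b in result.tip_paths[t]:
            branch_mask[b] = branch_mask.get(b, 0) | (1 << i)
    counts = {m: 0 for m in result.true_tree.splits()}
    for ev in result.events:
        if ev.kind == "inversion":
            continue
        mask = branch_mask.get(ev.branch, 0)
        if mask & 1:
            mask = full ^ mask
        if mask in counts:
            counts[mask] += 1
    return counts


def simulate_conditioned(tree: "str | dendropy.Tree", model: EvolutionModel,
                         template: AncestralTemplate | None = None,
                         min_events_per_internal_edge: int = 3,
                         max_attempts: int = 200) -> SimulationResult:
    """Simulate, redrawing (with derived seeds) until every internal edge of
    the true tree carries at least ``min_events_per_internal_edge``
    fusion/fission events — i.e. until the dataset realises the intended
    per-edge character signal, not merely its expectation."""
    from dataclasses import replace as _replace
    base = model.seed if model.seed is not None else 0
    for attempt in range(max_attempts):
        m = _replace(model, seed=(base + attempt * 1_000_003) % (2 ** 31))
        result = simulate(tree, m, template)
        counts = internal_edge_event_counts(result)
        if counts and min(counts.values()) >= min_events_per_internal_edge:
            return result
    raise RuntimeError(
        f"no simulation met the per-edge signal floor in {max_attempts} tries; "
        "increase branch lengths or rates")


# ---------------------------------------------------------------------------
# Truth matrix
# ---------------------------------------------------------------------------

def _undone_at_tip(event: SimEvent, later: list[SimEvent]) -> bool:
    if event.adjacency is None:
        return False
    boundary = frozenset(event.adjacency)
    for ev in later:
        if ev.adjacency is None:
            continue
        if frozenset(ev.adjacency) == boundary:
            if event.kind == "fusion" and ev.kind == "fission":
                return True
            if event.kind == "fission" and ev.kind == "fusion":
                return True
    return False


def truth_matrix(result: SimulationResult) -> CharacterMatrix:
    """Binary matrix scoring each simulated interchromosomal event per tip.

    An event is present at a tip iff it lies on the root-to-tip path and is
    not undone by a later event on that path (a fission at the exact fusion
    junction, or a re-fusion at the exact fission breakpoint).  Inversions are
    excluded: they are invisible at homology-map resolution.
    """
    taxa = list(result.taxa)
    chars: list[RearrangementCharacter] = []
    cols: list[list[int]] = []
    seen_ids: set[str] = set()
    for ev in result.events:
        if ev.kind == "inversion":
            continue
        if ev.kind == "fusion":
            base = "fus_" + "+".join(str(p) for p in sorted(ev.participants))
            kind = "fusion-association"
            count = None
        else:
            anc = next(iter(ev.participants)) if len(ev.participants) == 1 \
                else sorted(ev.participants)[0]
            base = f"fis_{anc}_ev{ev.index}"
            kind = "fission-pattern"
            count = 2
        char_id = base if base not in seen_ids else f"{base}_ev{ev.index}"
        seen_ids.add(char_id)
        definition = ev.participants if kind == "fusion-association" \
            else frozenset([sorted(ev.participants)[0]])
        chars.append(RearrangementCharacter(
            id=char_id, kind=kind, definition=definition,
            descendant_count=count, label=str(ev)))
        col = []
        for t in taxa:
            path = result.tip_paths[t]
            if ev.branch not in path:
                col.append(0)
                continue
            later = [e for e in result.events_on_path(t) if e.index > ev.index]
            col.append(0 if _undone_at_tip(ev, later) else 1)
        cols.append(col)
    states = (np.array(cols, dtype=np.int8).T if cols
              else np.zeros((len(taxa), 0), dtype=np.int8))
    return CharacterMatrix(taxa, chars, states)
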