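"""Binary rearrangement characters and the taxa x characters matrix.

Interchromosomal rearrangements observed in homology maps are coded as binary
presence/absence characters:

* a **fusion-association** character is a canonical set of ancestral
  chromosomes found together on one descendant chromosome (e.g. the PAK8/PAK9
  association).  Characters are individuated by the *full* participant set —
  a triple fusion is one character, not three pairs — but presence is scored
  by superset, so a chromosome carrying {PAK6, PAK7, PAK11} also exhibits the
  {PAK6, PAK7} association.
* a **fission-pattern** character is a pair (ancestral chromosome, descendant
  count): the state of having that ancestral element distributed over exactly
  that many descendant chromosomes.
* **inversion** and **other-discrete** characters have no machine-checkable
  predicate at painting resolution; their states must be supplied explicitly.

The missing state ``?`` is assigned whenever any ancestral chromosome a
character depends on has no assignment in a taxon's map (un-assayed, not
absent).  Characters whose definition touches an unidentifiable
microchromosome ("micro" entries in published tables) are never auto-coded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .homology import HomologyMap, detect_fissions, detect_fusions
from .labels import ChromosomeLabel, GGA, PAK

logger = logging.getLogger(__name__)

CHARACTER_KINDS = ("fusion-association", "fission-pattern", "inversion",
                   "other-discrete")

#: integer codes used in the state grid
STATE_CODES = {"0": 0, "1": 1, "?": -1}
MISSING = -1


@dataclass(frozen=True)
class RearrangementCharacter:
    """One discrete binary character with an optional membership predicate."""

    id: str
    kind: str
    definition: frozenset[ChromosomeLabel] = frozenset()
    descendant_count: Optional[int] = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in CHARACTER_KINDS:
            raise ValueError(f"unknown character kind {self.kind!r}")
        if self.kind == "fission-pattern" and (
                len(self.definition) != 1 or not self.descendant_count):
            raise ValueError("a fission-pattern needs one chromosome and a count")


def _char_sort_key(ch: RearrangementCharacter):
    nums = sorted((p.number or 0) for p in ch.definition)
    return (CHARACTER_KINDS.index(ch.kind), nums[0] if nums else 0, len(nums),
            nums, ch.descendant_count or 0)


def _fusion_character(participants: frozenset[ChromosomeLabel]) -> RearrangementCharacter:
    names = "+".join(str(p) for p in sorted(participants))
    pretty = "/".join(str(p) for p in sorted(participants))
    return RearrangementCharacter(
        id=f"fus_{names}", kind="fusion-association", definition=participants,
        label=f"{pretty} association")


def _fission_character(anc: ChromosomeLabel, k: int) -> RearrangementCharacter:
    return RearrangementCharacter(
        id=f"fis_{anc}_x{k}", kind="fission-pattern",
        definition=frozenset([anc]), descendant_count=k,
        label=f"{anc} fission into {k}")


def _common_scheme(maps: Sequence[HomologyMap]) -> str | None:
    schemes = set()
    for m in maps:
        schemes |= m.ancestral_schemes()
    if len(schemes) <= 1:
        return next(iter(schemes)) if schemes else None
    if schemes <= {PAK, GGA}:
        return PAK  # mixed but interconvertible: normalise to the ancestral scheme
    raise ValueError(f"maps use unconvertible ancestral schemes {schemes}")


def _normalised(maps: Sequence[HomologyMap]) -> list[HomologyMap]:
    scheme = _common_scheme(maps)
    if scheme is None:
        return list(maps)
    mixed = any(m.ancestral_schemes() - {scheme} for m in maps)
    if mixed:
        return [m.to_scheme(PAK) for m in maps]
    return list(maps)


def enumerate_characters(maps: Sequence[HomologyMap]) -> list[RearrangementCharacter]:
    """Deterministic union of every fusion participant-set and every
    (ancestral chromosome, descendant-count) fission pattern observed in any
    map, ordered by kind then lowest participating chromosome number.

    Characters touching unidentifiable microchromosomes are skipped.
    """
    if len(maps) < 2:
        raise ValueError("character enumeration needs at least two maps")
    maps = _normalised(maps)
    fusion_sets: set[frozenset[ChromosomeLabel]] = set()
    fission_patterns: set[tuple[ChromosomeLabel, int]] = set()
    for m in maps:
        for ev in detect_fusions(m):
            if any(p.is_micro_unknown for p in ev.participants):
                continue
            fusion_sets.add(ev.participants)
        for ev in detect_fissions(m):
            anc = next(iter(ev.participants))
            fission_patterns.add((anc, ev.descendant_count))
    chars = [_fusion_character(s) for s in fusion_sets]
    chars += [_fission_character(a, k) for a, k in fission_patterns]
    chars.sort(key=_char_sort_key)
    return chars


def score_taxon(map_: HomologyMap, character: RearrangementCharacter) -> str:
    """Score one taxon for one character: ``"1"`` if the defining event is
    observed, ``"0"`` if all involved chromosomes are assayed and the event is
    absent, ``"?"`` if any involved chromosome has no assignment."""
    if character.kind in ("inversion", "other-discrete"):
        return "?"  # no predicate at painting resolution; states are supplied
    if map_.ancestral_schemes() - {next(iter(character.definition)).scheme}:
        map_ = map_.to_scheme(next(iter(character.definition)).scheme)
    if any(not map_.has_ancestral(p) for p in character.definition):
        return "?"
    if character.kind == "fusion-association":
        want = {(p.scheme, p.number) for p in character.definition}
        for ev in detect_fusions(map_):
            have = {(p.scheme, p.number) for p in ev.participants}
            if want <= have:
                return "1"
        return "0"
    anc = next(iter(character.definition))
    k = len(map_.descendants_of(anc))
    return "1" if k == character.descendant_count else "0"


@dataclass
class CharacterMatrix:
    """Taxa x binary characters with missing states, over symbols {0, 1, ?}."""

    taxa: list[str]
    characters: list[RearrangementCharacter]
    states: np.ndarray  # int8, shape (ntaxa, nchar), values {0, 1, -1}

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.taxa), len(self.characters)):
            raise ValueError(
                f"state grid {self.states.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.characters)} characters")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        ids = [c.id for c in self.characters]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate character ids")
        if self.ncharacters and bool(np.any((self.states == MISSING).all(axis=0))):
            raise ValueError("every character must have at least one observed state")

    # -- basic accessors ----------------------------------------------------
    @property
    def ntaxa(self) -> int:
        return len(self.taxa)

    @property
    def ncharacters(self) -> int:
        return len(self.characters)

    def state(self, taxon: str, char_id: str) -> str:
        i = self.taxa.index(taxon)
        j = [c.id for c in self.characters].index(char_id)
        return {0: "0", 1: "1", MISSING: "?"}[int(self.states[i, j])]

    def column(self, char_id: str) -> np.ndarray:
        j = [c.id for c in self.characters].index(char_id)
        return self.states[:, j].copy()

    def row_string(self, taxon: str) -> str:
        i = self.taxa.index(taxon)
        return "".join({0: "0", 1: "1", MISSING: "?"}[int(v)]
                       for v in self.states[i])

    # -- editing ------------------------------------------------------------
    def drop_character(self, char_id: str) -> "CharacterMatrix":
        ids = [c.id for c in self.characters]
        if char_id not in ids:
            raise KeyError(f"no character with id {char_id!r}")
        j = ids.index(char_id)
        return CharacterMatrix(
            list(self.taxa),
            self.characters[:j] + self.characters[j + 1:],
            np.delete(self.states, j, axis=1))

    def with_character(self, character: RearrangementCharacter,
                       states: Mapping[str, str]) -> "CharacterMatrix":
        """Append a manually supplied character (states keyed by taxon)."""
        col = np.full(self.ntaxa, MISSING, dtype=np.int8)
        for taxon, sym in states.items():
            col[self.taxa.index(taxon)] = STATE_CODES[sym]
        return CharacterMatrix(
            list(self.taxa), self.characters + [character],
            np.column_stack([self.states, col]) if self.ncharacters
            else col.reshape(-1, 1))

    def subset_taxa(self, taxa: Sequence[str]) -> "CharacterMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        keep_states = self.states[idx]
        keep = [j for j in range(self.ncharacters)
                if bool(np.any(keep_states[:, j] != MISSING))]
        return CharacterMatrix(list(taxa), [self.characters[j] for j in keep],
                               keep_states[:, keep])


def build_matrix(maps: Sequence[HomologyMap]) -> CharacterMatrix:
    """Code every map against the deterministic union of observed characters.

    The result is independent of input map order up to the canonical character
    ordering; taxa appear in input order.
    """
    if len(maps) < 3:
        logger.warning("building a matrix from %d taxa; tree inference needs >= 3",
                       len(maps))
    chars = enumerate_characters(maps)
    maps_n = _normalised(maps)
    states = np.array(
        [[STATE_CODES[score_taxon(m, c)] for c in chars] for m in maps_n],
        dtype=np.int8).reshape(len(maps), len(chars))
    keep = [j for j in range(len(chars)) if bool(np.any(states[:, j] != MISSING))]
    return CharacterMatrix([m.taxon for m in maps],
                           [chars[j] for j in keep], states[:, keep])


def classify_characters(matrix: CharacterMatrix) -> list[str]:
    """Per-character class: ``constant``, ``uninformative`` (variable but
    autapomorphic), or ``informative`` (each state in >= 2 taxa, missing
    excluded)."""
    out = []
    for j in range(matrix.ncharacters):
        col = matrix.states[:, j]
        n0 = int(np.sum(col == 0))
        n1 = int(np.sum(col == 1))
        if n0 and n1:
            out.append("informative" if min(n0, n1) >= 2 else "uninformative")
        else:
            out.append("constant")
    return out


def classification_counts(matrix: CharacterMatrix) -> dict[str, int]:
    classes = classify_characters(matrix)
    return {k: classes.count(k) for k in ("constant", "uninformative", "informative")}
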