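"""Homology maps from comparative chromosome painting, and event detection.

A homology map records, for one painted species, which descendant chromosome
regions hybridise to which ancestral (PAK or chicken/GGA) probes.  From such a
map two kinds of interchromosomal rearrangement are directly observable at
whole-chromosome resolution:

* **fusion** — one descendant chromosome carries homology to two or more
  distinct ancestral chromosomes (a "syntenic association", e.g. GGA8/GGA9
  on one chromosome);
* **fission** — one ancestral chromosome is distributed over two or more
  distinct descendant chromosomes.

Arm-level qualifiers (p, q, proximal/distal) are recorded faithfully but event
detection deliberately operates per whole descendant chromosome, because
painting evidence in the literature is reported at that level.  Inversions are
invisible to whole-chromosome homology and are never inferred here.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .labels import (
    GGA,
    MICRO_UNKNOWN,
    PAK,
    ChromosomeLabel,
    _normalise_region,
    gga_to_pak,
    micro_unknown,
    pak_to_gga,
    parse_label,
)

logger = logging.getLogger(__name__)

EVIDENCE_CLASSES = ("whole-chromosome-paint", "BAC", "reciprocal-paint", "inferred")

REQUIRED_COLUMNS = (
    "taxon", "ancestral_chr", "ancestral_region", "descendant_chr",
    "descendant_region", "evidence", "diploid_number",
)


class HomologyError(ValueError):
    """Raised for malformed or internally inconsistent homology data."""


@dataclass(frozen=True)
class SegmentAssignment:
    """One painted homology: an ancestral chromosome (region) seen on a
    descendant chromosome (region) of ``taxon``."""

    taxon: str
    ancestral: ChromosomeLabel
    descendant: ChromosomeLabel
    evidence: str = "whole-chromosome-paint"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.ancestral.scheme not in (PAK, GGA, MICRO_UNKNOWN):
            raise HomologyError(
                f"ancestral label must be PAK/GGA (or micro), got {self.ancestral}"
            )
        # descendant labels are species-local; "GGA" is tolerated because for
        # the chicken taxon itself the local scheme IS the GGA numbering
        if self.descendant.scheme == PAK:
            raise HomologyError(
                f"descendant label must be species-local, got {self.descendant}"
            )
        if self.evidence not in EVIDENCE_CLASSES:
            raise HomologyError(f"unknown evidence class {self.evidence!r}")


def _desc_key(label: ChromosomeLabel):
    """Identity of a descendant chromosome, region-stripped.

    Unidentified micros compare by uid: two bare "micro" entries are distinct
    chromosomes unless stated otherwise.
    """
    return (label.scheme, label.number, label.uid)


def _anc_key(label: ChromosomeLabel):
    return (label.scheme, label.number, label.uid)


@dataclass(frozen=True)
class RearrangementEvent:
    """A detected (or simulated) interchromosomal rearrangement."""

    kind: str  # "fusion" | "fission" | "inversion"
    participants: frozenset[ChromosomeLabel]  # ancestral side, region-stripped
    locus: ChromosomeLabel | None = None      # descendant chromosome (fusions)
    descendant_count: int | None = None       # number of products (fissions)
    descendants: tuple[ChromosomeLabel, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind == "fusion" and len(self.participants) < 2:
            raise HomologyError("a fusion needs at least two participants")
        if self.kind == "fission":
            if len(self.participants) != 1:
                raise HomologyError("a fission has exactly one participant")
            if self.descendant_count is None or self.descendant_count < 2:
                raise HomologyError("a fission occupies >= 2 descendant chromosomes")

    def __str__(self) -> str:
        names = "/".join(str(p) for p in sorted(self.participants))
        if self.kind == "fusion":
            return f"fusion {names} on {self.locus}"
        if self.kind == "fission":
            return f"fission {names} into {self.descendant_count}"
        return f"{self.kind} {names}"


@dataclass
class HomologyMap:
    """All segment assignments for one taxon, plus its diploid number (2n)."""

    taxon: str
    diploid_number: int
    assignments: tuple[SegmentAssignment, ...] = ()

    def __post_init__(self) -> None:
        if self.diploid_number <= 0 or self.diploid_number % 2:
            raise HomologyError(
                f"{self.taxon}: diploid number must be a positive even integer, "
                f"got {self.diploid_number}"
            )
        self.assignments = tuple(self.assignments)
        seen = set()
        for a in self.assignments:
            if a.taxon != self.taxon:
                raise HomologyError(
                    f"assignment taxon {a.taxon!r} does not match map {self.taxon!r}"
                )
            key = (_anc_key(a.ancestral), a.ancestral.region,
                   _desc_key(a.descendant), a.descendant.region)
            if key in seen:
                raise HomologyError(
                    f"{self.taxon}: duplicate assignment {a.ancestral} -> {a.descendant}"
                )
            seen.add(key)

    # -- scheme conversion --------------------------------------------------
    def ancestral_schemes(self) -> set[str]:
        return {a.ancestral.scheme for a in self.assignments
                if not a.ancestral.is_micro_unknown}

    def to_scheme(self, scheme: str) -> "HomologyMap":
        """Re-express ancestral labels in ``scheme`` ("PAK" or "GGA").

        Chicken chromosome 4 taken whole expands into its two ancestral
        elements (PAK4 + PAK10) on the same descendant chromosome.
        """
        if scheme not in (PAK, GGA):
            raise ValueError("conversion target must be 'PAK' or 'GGA'")
        out: list[SegmentAssignment] = []
        for a in self.assignments:
            if a.ancestral.is_micro_unknown or a.ancestral.scheme == scheme:
                out.append(a)
            elif a.ancestral.scheme == PAK:
                out.append(replace(a, ancestral=pak_to_gga(a.ancestral)))
            else:
                for pak_label in gga_to_pak(a.ancestral):
                    out.append(replace(a, ancestral=pak_label))
        # the expansion can create exact duplicates (e.g. GGA4p and GGA4q rows
        # that collapse onto GGA4 when converting the other way); keep first
        uniq, seen = [], set()
        for a in out:
            key = (_anc_key(a.ancestral), a.ancestral.region,
                   _desc_key(a.descendant), a.descendant.region)
            if key not in seen:
                seen.add(key)
                uniq.append(a)
        return HomologyMap(self.taxon, self.diploid_number, tuple(uniq))

    # -- queries ------------------------------------------------------------
    def descendants_of(self, ancestral: ChromosomeLabel) -> tuple[ChromosomeLabel, ...]:
        """Distinct descendant chromosomes (region-stripped, first-seen order)
        carrying homology to ``ancestral`` (region-ignored)."""
        want = _anc_key(ancestral.chromosome)
        seen, out = set(), []
        for a in self.assignments:
            if _anc_key(a.ancestral.chromosome) == want:
                k = _desc_key(a.descendant)
                if k not in seen:
                    seen.add(k)
                    out.append(a.descendant.chromosome)
        return tuple(out)

    def ancestral_chromosomes(self) -> tuple[ChromosomeLabel, ...]:
        seen, out = set(), []
        for a in self.assignments:
            k = _anc_key(a.ancestral.chromosome)
            if k not in seen:
                seen.add(k)
                out.append(a.ancestral.chromosome)
        return tuple(out)

    def has_ancestral(self, ancestral: ChromosomeLabel) -> bool:
        return len(self.descendants_of(ancestral)) > 0


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

def count_descendant_pairs(map_: HomologyMap, ancestral: ChromosomeLabel) -> int:
    """Number of distinct descendant chromosome pairs carrying homology to
    ``ancestral``; 0 when the probe is absent from the map."""
    return len(map_.descendants_of(ancestral))


def detect_fusions(map_: HomologyMap) -> tuple[RearrangementEvent, ...]:
    """One fusion event per descendant chromosome carrying >= 2 distinct
    ancestral homologies, ordered by descendant chromosome number."""
    by_desc: dict[tuple, tuple[ChromosomeLabel, list[ChromosomeLabel]]] = {}
    for a in map_.assignments:
        k = _desc_key(a.descendant)
        locus, ancs = by_desc.setdefault(k, (a.descendant.chromosome, []))
        anc = a.ancestral.chromosome
        if _anc_key(anc) not in {_anc_key(x) for x in ancs}:
            ancs.append(anc)
    events = []
    for locus, ancs in by_desc.values():
        if len(ancs) >= 2:
            events.append(RearrangementEvent(
                kind="fusion", participants=frozenset(ancs), locus=locus))
    events.sort(key=lambda e: (e.locus.number is None, e.locus.number or 0,
                               e.locus.uid))
    return tuple(events)


def detect_fissions(map_: HomologyMap) -> tuple[RearrangementEvent, ...]:
    """One fission event per ancestral chromosome distributed over >= 2
    descendant chromosomes, annotated with the descendant count."""
    events = []
    for anc in map_.ancestral_chromosomes():
        if anc.is_micro_unknown:
            continue
        desc = map_.descendants_of(anc)
        if len(desc) >= 2:
            events.append(RearrangementEvent(
                kind="fission", participants=frozenset([anc]),
                descendant_count=len(desc), descendants=desc))
    events.sort(key=lambda e: (next(iter(e.participants)).scheme,
                               next(iter(e.participants)).number or 0))
    return tuple(events)


# ---------------------------------------------------------------------------
# TSV serialisation
# ---------------------------------------------------------------------------

def parse_homology_tsv(path: str | Path) -> tuple[HomologyMap, ...]:
    """Read homology maps from a tab-separated table.

    Required columns (header row): taxon, ancestral_chr, ancestral_region,
    descendant_chr, descendant_region, evidence, diploid_number.  Lines
    starting with ``#`` are comments.  An optional ``provenance`` column is
    preserved.  One map is returned per distinct taxon, in first-appearance
    order; within a map, row order is preserved.
    """
    path = Path(path)
    rows: list[tuple[int, dict[str, str]]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = next(csv.reader([line], delimiter="\t"))
            if header is None:
                header = [f.strip() for f in fields]
                missing = [c for c in REQUIRED_COLUMNS if c not in header]
                if missing:
                    raise HomologyError(
                        f"{path}: header is missing required columns {missing}")
                continue
            rows.append((lineno, dict(zip(header, (f.strip() for f in fields)))))
    if header is None:
        raise HomologyError(f"{path}: no header row found")

    per_taxon: dict[str, list[SegmentAssignment]] = {}
    diploid: dict[str, int] = {}
    for lineno, rec in rows:
        try:
            taxon = rec["taxon"]
            anc_txt = rec["ancestral_chr"]
            if anc_txt.lower() in (MICRO_UNKNOWN, "mic"):
                anc = micro_unknown()
            else:
                anc = parse_label(anc_txt,
                                  region=rec.get("ancestral_region") or "whole")
            desc_txt = rec["descendant_chr"]
            if desc_txt.lower() in (MICRO_UNKNOWN, "mic"):
                desc = micro_unknown()
            else:
                desc = parse_label(desc_txt,
                                   region=rec.get("descendant_region") or "whole")
            evidence = rec.get("evidence") or "whole-chromosome-paint"
            assignment = SegmentAssignment(
                taxon=taxon, ancestral=anc, descendant=desc, evidence=evidence,
                provenance=rec.get("provenance", ""))
            two_n = int(rec["diploid_number"])
        except (HomologyError, ValueError) as exc:
            raise HomologyError(f"{path}:{lineno}: {exc}") from exc
        if taxon in diploid and diploid[taxon] != two_n:
            raise HomologyError(
                f"{path}:{lineno}: conflicting diploid number for {taxon} "
                f"({diploid[taxon]} vs {two_n})")
        diploid[taxon] = two_n
        per_taxon.setdefault(taxon, []).append(assignment)

    maps = []
    for taxon, assignments in per_taxon.items():
        try:
            maps.append(HomologyMap(taxon, diploid[taxon], tuple(assignments)))
        except HomologyError as exc:
            raise HomologyError(f"{path}: {exc}") from exc
    if not maps:
        logger.warning("%s: header only, no assignments parsed", path)
    for m in maps:
        if not m.assignments:
            logger.warning("%s: taxon %s has no assignments", path, m.taxon)
    return tuple(maps)


def write_homology_tsv(maps: Iterable[HomologyMap], path: str | Path) -> None:
    """Write maps in the same TSV dialect that :func:`parse_homology_tsv` reads."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(list(REQUIRED_COLUMNS) + ["provenance"])
        for m in maps:
            for a in m.assignments:
                anc = ("micro" if a.ancestral.is_micro_unknown
                       else f"{a.ancestral.scheme}{a.ancestral.number}")
                desc = ("micro" if a.descendant.is_micro_unknown
                        else f"{a.descendant.scheme}{a.descendant.number}")
                w.writerow([m.taxon, anc, a.ancestral.region, desc,
                            a.descendant.region, a.evidence, m.diploid_number,
                            a.provenance])
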