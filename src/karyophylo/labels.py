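"""Chromosome labels and the PAK/GGA nomenclature.

Comparative chromosome painting describes homologies against a reference
nomenclature.  Two reference schemes are in common use for birds:

* **GGA** — chicken (*Gallus gallus*) chromosome numbers, the scheme in which
  painting probes are made;
* **PAK** — the Putative Avian Ancestral Karyotype (PAK1..PAK15, 2n = 80),
  which differs from chicken only in that chicken chromosome 4 is a fusion of
  two ancestral elements (PAK4 = GGA4q, PAK10 = GGA4p).

Any other scheme string (``"MMO"``, ``"AMA"`` ...) denotes a species-local
chromosome number in the painted (descendant) karyotype.  The reserved scheme
``"micro"`` marks a microchromosome whose identity is unknown — these occur in
published tables as a bare "micro" entry and are excluded from character
coding because two "micro" entries cannot be asserted to be the same element.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import count
from typing import Optional

PAK = "PAK"
GGA = "GGA"
MICRO_UNKNOWN = "micro"

#: Region qualifiers used in homology tables.  ``whole`` is the default.
REGIONS = ("whole", "p", "q", "pq", "prox_q", "dist_q", "unknown")

# PAK number -> (GGA number, GGA region).  PAK4 and PAK10 are the two arms of
# chicken chromosome 4; all other pairs map whole-to-whole.
_PAK_TO_GGA: dict[int, tuple[int, str]] = {
    1: (1, "whole"), 2: (2, "whole"), 3: (3, "whole"),
    4: (4, "q"), 5: (5, "whole"), 6: (6, "whole"), 7: (7, "whole"),
    8: (8, "whole"), 9: (9, "whole"), 10: (4, "p"), 11: (10, "whole"),
    12: (11, "whole"), 13: (12, "whole"), 14: (13, "whole"), 15: (14, "whole"),
}

_GGA_TO_PAK: dict[tuple[int, str], int] = {
    (g, r): p for p, (g, r) in _PAK_TO_GGA.items()
}

_unknown_micro_ids = count(1)


@dataclass(frozen=True, order=True)
class ChromosomeLabel:
    """A chromosome (or chromosome region) in a named labelling scheme.

    ``number`` is ``None`` only for unidentified microchromosomes
    (scheme ``"micro"``); every other label carries a positive number.
    ``uid`` disambiguates distinct unidentified micros: two "micro" table
    entries are never the same chromosome unless explicitly stated.
    """

    scheme: str
    number: Optional[int] = None
    region: str = "whole"
    uid: int = 0

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region token {self.region!r}")
        if self.scheme == MICRO_UNKNOWN:
            if self.number is not None:
                raise ValueError("micro-unknown labels carry no number")
        elif self.number is None or self.number < 1:
            raise ValueError(f"chromosome number must be >= 1, got {self.number!r}")

    # -- predicates ---------------------------------------------------------
    @property
    def is_micro_unknown(self) -> bool:
        return self.scheme == MICRO_UNKNOWN

    @property
    def chromosome(self) -> "ChromosomeLabel":
        """The same label with the region qualifier stripped (whole chromosome)."""
        if self.region == "whole":
            return self
        return ChromosomeLabel(self.scheme, self.number, "whole", self.uid)

    # -- formatting ---------------------------------------------------------
    def __str__(self) -> str:
        if self.is_micro_unknown:
            return "micro"
        suffix = {"whole": "", "p": "p", "q": "q", "pq": "pq",
                  "prox_q": "prox-q", "dist_q": "dist-q", "unknown": "?"}[self.region]
        return f"{self.scheme}{self.number}{suffix}"


def micro_unknown() -> ChromosomeLabel:
    """A fresh, unique label for an unidentified microchromosome."""
    return ChromosomeLabel(MICRO_UNKNOWN, None, "whole", next(_unknown_micro_ids))


_LABEL_RE = re.compile(
    r"^([A-Za-z]+)(\d+)?(pq|p|q|prox[-_]?q|dist[-_]?q)?$"
)


def parse_label(text: str, region: str | None = None) -> ChromosomeLabel:
    """Parse a label string such as ``"GGA4"``, ``"MMO3q"`` or ``"micro"``.

    An explicit ``region`` argument overrides any suffix embedded in the text.
    """
    text = text.strip()
    if text.lower() in (MICRO_UNKNOWN, "mic"):
        lab = micro_unknown()
        return lab
    m = _LABEL_RE.match(text)
    if not m or m.group(2) is None:
        raise ValueError(f"cannot parse chromosome label {text!r}")
    scheme, number, suffix = m.group(1), int(m.group(2)), m.group(3)
    if region is None:
        region = _normalise_region(suffix or "whole")
    else:
        region = _normalise_region(region)
    return ChromosomeLabel(scheme, number, region)


def _normalise_region(token: str) -> str:
    token = token.strip().lower().replace("-", "_")
    aliases = {"": "whole", "w": "whole", "prox_q": "prox_q", "proxq": "prox_q",
               "dist_q": "dist_q", "distq": "dist_q", "p/q": "pq", "?": "unknown"}
    token = aliases.get(token, token)
    if token not in REGIONS:
        raise ValueError(f"unknown region token {token!r}")
    return token


def pak_to_gga(label: ChromosomeLabel) -> ChromosomeLabel:
    """Convert a PAK label to its chicken (GGA) equivalent.

    PAK numbers above 15 (extended indices used for simulated, identifiable
    microchromosomes) have no chicken equivalent and are returned unchanged.
    """
    if label.scheme != PAK:
        raise ValueError(f"expected a PAK label, got {label}")
    if label.number not in _PAK_TO_GGA:
        return label
    g, arm = _PAK_TO_GGA[label.number]
    if arm == "whole":
        return ChromosomeLabel(GGA, g, label.region)
    # PAK4 / PAK10 occupy one arm of GGA4; sub-arm qualifiers are not
    # representable and collapse to the arm itself.
    return ChromosomeLabel(GGA, g, arm)


def gga_to_pak(label: ChromosomeLabel) -> tuple[ChromosomeLabel, ...]:
    """Convert a GGA label to PAK.

    Returns a tuple because chicken chromosome 4 taken whole corresponds to
    *two* ancestral elements (PAK4 = 4q, PAK10 = 4p); every other conversion
    is one-to-one.
    """
    if label.scheme != GGA:
        raise ValueError(f"expected a GGA label, got {label}")
    if label.number == 4:
        if label.region in ("q", "prox_q", "dist_q"):
            return (ChromosomeLabel(PAK, 4, "whole"),)
        if label.region == "p":
            return (ChromosomeLabel(PAK, 10, "whole"),)
        return (ChromosomeLabel(PAK, 4, "whole"), ChromosomeLabel(PAK, 10, "whole"))
    key = (label.number, "whole")
    if key not in _GGA_TO_PAK:
        raise ValueError(f"no PAK equivalent for {label}")
    return (ChromosomeLabel(PAK, _GGA_TO_PAK[key], label.region),)
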