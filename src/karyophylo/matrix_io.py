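"""Read/write binary character matrices as NEXUS or relaxed PHYLIP.

Reading goes through dendropy's standard-data parsers (which handle
interleaved NEXUS, quoted labels, etc.); character labels, which dendropy does
not expose for standard data, are recovered from the CHARLABELS statement.
Writing emits a minimal DATA block (``datatype=standard symbols="01"
missing=? gap=-``) with CHARLABELS, or whitespace-delimited relaxed PHYLIP.
"""

from __future__ import annotations

import re
from pathlib import Path

import dendropy
import numpy as np

from .coding import MISSING, CharacterMatrix, RearrangementCharacter, STATE_CODES

_SYM_TO_CODE = {"0": 0, "1": 1, "?": MISSING, "-": MISSING}


def _generic_character(label: str) -> RearrangementCharacter:
    return RearrangementCharacter(id=label, kind="other-discrete", label=label)


def _charlabels_from_nexus(text: str) -> list[str] | None:
    m = re.search(r"charlabels\s+(.*?);", text, re.IGNORECASE | re.DOTALL)
    if not m:
        return None
    return [tok.strip("'\"") for tok in m.group(1).split()]


def _from_dendropy(dmatrix: "dendropy.StandardCharacterMatrix",
                   labels: list[str] | None) -> CharacterMatrix:
    taxa = [t.label for t in dmatrix.taxon_namespace]
    grid = []
    for t in dmatrix.taxon_namespace:
        row = [str(c) for c in dmatrix[t]]
        grid.append([_SYM_TO_CODE[s] for s in row])
    lengths = {len(r) for r in grid}
    if len(lengths) != 1:
        raise ValueError(f"ragged matrix: row lengths {sorted(lengths)}")
    nchar = lengths.pop()
    if labels is None:
        labels = [f"c{j + 1}" for j in range(nchar)]
    if len(labels) != nchar:
        raise ValueError(
            f"{len(labels)} character labels for {nchar} characters")
    chars = [_generic_character(lab) for lab in labels]
    return CharacterMatrix(taxa, chars, np.array(grid, dtype=np.int8))


def read_matrix(path: str | Path, format: str = "nexus") -> CharacterMatrix:
    """Load a binary matrix; ``format`` is ``"nexus"`` or ``"phylip"``."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if format == "nexus":
        dmatrix = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
        labels = _charlabels_from_nexus(text)
    elif format == "phylip":
        dmatrix = dendropy.StandardCharacterMatrix.get(data=text, schema="phylip")
        labels = None
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    matrix = _from_dendropy(dmatrix, labels)
    declared = re.search(r"ntax\s*=\s*(\d+)", text, re.IGNORECASE)
    if declared and int(declared.group(1)) != matrix.ntaxa:
        raise ValueError(
            f"{path}: declared NTAX={declared.group(1)} but parsed {matrix.ntaxa}")
    return matrix


def _needs_quotes(label: str) -> bool:
    return bool(re.search(r"[\s(){}\[\]/\\,;:=*'\"`+<>-]", label))


def _nexus_token(label: str) -> str:
    if _needs_quotes(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_matrix(matrix: CharacterMatrix, path: str | Path,
                 format: str = "nexus") -> None:
    """Write the matrix losslessly (taxa, character ids, states {0,1,?})."""
    path = Path(path)
    sym = {0: "0", 1: "1", MISSING: "?"}
    if format == "nexus":
        lines = ["#NEXUS", "", "BEGIN DATA;",
                 f"    DIMENSIONS NTAX={matrix.ntaxa} NCHAR={matrix.ncharacters};",
                 '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;']
        if matrix.ncharacters:
            lines.append("    CHARLABELS")
            lines.append("        " + " ".join(
                _nexus_token(c.id) for c in matrix.characters))
            lines.append("    ;")
        lines.append("    MATRIX")
        width = max((len(_nexus_token(t)) for t in matrix.taxa), default=0) + 2
        for i, t in enumerate(matrix.taxa):
            row = "".join(sym[int(v)] for v in matrix.states[i])
            lines.append(f"        {_nexus_token(t):<{width}}{row}")
        lines += ["    ;", "END;", ""]
        path.write_text("\n".join(lines), encoding="utf-8")
    elif format == "phylip":
        lines = [f"{matrix.ntaxa} {matrix.ncharacters}"]
        width = max((len(t) for t in matrix.taxa), default=0) + 2
        for i, t in enumerate(matrix.taxa):
            row = "".join(sym[int(v)] for v in matrix.states[i])
            lines.append(f"{t:<{width}}{row}")
        lines.append("")
        path.write_text("\n".join(lines), encoding="utf-8")
    else:
        raise ValueError(f"unknown matrix format {format!r}")
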