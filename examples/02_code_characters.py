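"""Code the cross-species painting table into a binary character matrix.

Every distinct fusion association and fission pattern observed in any taxon
becomes one presence/absence character; '?' marks taxa in which an involved
chromosome was never assayed.
"""

from importlib.resources import files

from karyophylo import (
    build_matrix,
    classification_counts,
    classify_characters,
    parse_homology_tsv,
)

maps = {m.taxon: m for m in parse_homology_tsv(
    files("karyophylo") / "data" / "table5_all_species.tsv")}
taxa = ["AHY", "ACH", "PFR", "AMA", "MMO", "AAE", "GGA", "TRU"]
matrix = build_matrix([maps[t] for t in taxa])

print(f"{matrix.ntaxa} taxa x {matrix.ncharacters} characters")
counts = classification_counts(matrix)
print(f"parsimony-informative: {counts['informative']}, "
      f"autapomorphic: {counts['uninformative']}, "
      f"constant: {counts['constant']}")

print("\ncharacter".ljust(24), " ".join(f"{t:>4}" for t in matrix.taxa))
classes = classify_characters(matrix)
for char, cls in zip(matrix.characters, classes):
    row = " ".join(f"{matrix.state(t, char.id):>4}" for t in matrix.taxa)
    mark = "*" if cls == "informative" else " "
    print(f"{mark}{char.id:<23}", row)
print("\n(* = informative: both states present in at least two taxa)")
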