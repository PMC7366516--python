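"""Detect fusions and fissions in the monk parakeet homology map.

Loads the packaged chicken-on-MMO painting table and lists every descendant
chromosome that carries two or more ancestral homologies (a fusion) and every
ancestral chromosome scattered over two or more descendant chromosomes (a
fission).
"""

from importlib.resources import files

from karyophylo import (
    count_descendant_pairs,
    detect_fissions,
    detect_fusions,
    parse_homology_tsv,
)
from karyophylo.labels import parse_label

(mmo,) = parse_homology_tsv(files("karyophylo") / "data" / "tables2_mmo.tsv")

print(f"{mmo.taxon}: 2n = {mmo.diploid_number}, "
      f"{len(mmo.assignments)} painted homology assignments")

print("\nFusions (syntenic associations on one MMO chromosome):")
for event in detect_fusions(mmo):
    print(f"  {event}")

print("\nFissions (one ancestral chromosome on several MMO chromosomes):")
for event in detect_fissions(mmo):
    print(f"  {event}")

for probe in ("GGA1", "GGA2"):
    n = count_descendant_pairs(mmo, parse_label(probe))
    print(f"\n{probe} paints {n} distinct MMO chromosome pairs "
          "(each extra pair is one fission product)")
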