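# Packaged homology-map fixtures

All files are UTF-8, tab-separated, in the dialect read by
`karyophylo.parse_homology_tsv` (see module docs); `#` lines are comments and
every row carries a `provenance` note quoting the table cell it transcribes.

| file | contents |
|---|---|
| `tables2_mmo.tsv` | monk parakeet (MMO, 2n = 48) vs chicken whole-chromosome paints |
| `table3_bacs.tsv` | chicken microchromosome BACs (GGA17–28) on MMO |
| `table4_ama.tsv` | scarlet macaw homologies from reciprocal MMO painting (unambiguous rows only) |
| `table5_all_species.tsv` | cross-species PAK1–PAK11 syntenic-group correspondence for twelve parrot/outgroup karyotypes |
| `reconstructed_matrix.nex` | binary character matrix derived from `table5_all_species.tsv` (see below) |

Known transcription caveats:

* The merged macro/micro row "PAK11-13 / GGA10-12" of the MMO table is
  encoded as GGA10 → {MMO9p, MMO11} only; GGA11 and GGA12 are left
  unassigned (they surface as `?` in coded characters).
* Where the running text and a table disagree (e.g. GGA4q on "MMO1q/p" in
  the text vs "1q/7q" in the table), the table is transcribed and the
  conflict noted here, per the fixed table-precedence rule.
* Microchromosomes without a chromosome number are written `micro`; each such
  entry is a distinct unidentifiable element and never participates in
  character coding.
* The **TRU block of `table5_all_species.tsv` is synthetic**: an
  ancestral-state (identity) stand-in for the thrush outgroup whose painting
  data are published elsewhere and not transcribed here.

## reconstructed_matrix.nex

**This is a reconstruction, not the original study's supplementary matrix**
(which is not redistributable here).  It is produced by
`scripts/build_reconstructed_matrix.py`: automatic fusion/fission character
coding of the eight taxa AHY, ACH, PFR, AMA, MMO, AAE, GGA, TRU from
`table5_all_species.tsv`, plus two manually supplied microchromosome-fusion
characters described in the running text (PAK5/micro shared by the macaws;
PAK10/micro shared by ACH, AMA and AAE).  It is suitable for smoke tests and
worked examples; statistics computed from it are reported as properties of
*this* matrix, not of the original one.
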