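# Monk parakeet (Myiopsitta monachus, MMO, 2n = 48) vs chicken (GGA)
# whole-chromosome paints, transcribed verbatim from the published
# correspondence table (PAK / GGA / "pairs in MMO" columns).
# The merged row "PAK11-13 / GGA10-12 / 2 pairs / 9p,11" is encoded as
# GGA10 -> {MMO9p, MMO11} only, because the accompanying text assigns
# "GGA10 (MMO 9p, 11)"; GGA11 and GGA12 are left unassigned (missing).
taxon	ancestral_chr	ancestral_region	descendant_chr	descendant_region	evidence	diploid_number	provenance
MMO	GGA1	whole	MMO3	q	whole-chromosome-paint	48	T2 PAK1
MMO	GGA1	whole	MMO4	pq	whole-chromosome-paint	48	T2 PAK1
MMO	GGA1	whole	MMO12	whole	whole-chromosome-paint	48	T2 PAK1
MMO	GGA1	whole	MMO14	q	whole-chromosome-paint	48	T2 PAK1
MMO	GGA2	whole	MMO2	whole	whole-chromosome-paint	48	T2 PAK2
MMO	GGA2	whole	MMO3	p	whole-chromosome-paint	48	T2 PAK2
MMO	GGA2	whole	MMO13	q	whole-chromosome-paint	48	T2 PAK2
MMO	GGA3	whole	MMO5	whole	whole-chromosome-paint	48	T2 PAK3
MMO	GGA3	whole	MMO7	whole	whole-chromosome-paint	48	T2 PAK3
MMO	GGA4	q	MMO1	q	whole-chromosome-paint	48	T2 PAK4
MMO	GGA4	q	MMO7	q	whole-chromosome-paint	48	T2 PAK4
MMO	GGA5	whole	MMO6	whole	whole-chromosome-paint	48	T2 PAK5
MMO	GGA6	whole	MMO9	q	whole-chromosome-paint	48	T2 PAK6
MMO	GGA6	whole	MMO10	q	whole-chromosome-paint	48	T2 PAK6
MMO	GGA7	whole	MMO9	q	whole-chromosome-paint	48	T2 PAK7
MMO	GGA7	whole	MMO10	q	whole-chromosome-paint	48	T2 PAK7
MMO	GGA8	whole	MMO8	p	whole-chromosome-paint	48	T2 PAK8
MMO	GGA9	whole	MMO8	q	whole-chromosome-paint	48	T2 PAK9
MMO	GGA4	p	MMO1	p	whole-chromosome-paint	48	T2 PAK10
MMO	GGA4	p	MMO7	q	whole-chromosome-paint	48	T2 PAK10
MMO	GGA10	whole	MMO9	p	whole-chromosome-paint	48	T2 PAK11-13 merged row; text assigns GGA10 only
MMO	GGA10	whole	MMO11	whole	whole-chromosome-paint	48	T2 PAK11-13 merged row; text assigns GGA10 only
MMO	GGA13	whole	MMO13	p	whole-chromosome-paint	48	T2 PAK14
MMO	GGA14	whole	MMO1	p	whole-chromosome-paint	48	T2 PAK15
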