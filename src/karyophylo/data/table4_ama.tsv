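# Scarlet macaw (Ara macao, AMA, 2n = 68) homologies from reciprocal
# painting with monk parakeet (MMO) probes, cross-referenced to chicken.
# Only rows whose probe-to-target pairing is unambiguous in the published
# three-way table are encoded; multi-probe rows (e.g. "MMO1 | GGA
# 4q,4p,14,23,25,28 | AMA 1p,8q + 4 micros") cannot be decomposed into
# single homology assignments and are omitted (see data README).
taxon	ancestral_chr	ancestral_region	descendant_chr	descendant_region	evidence	diploid_number	provenance
AMA	GGA2	q	AMA2	q	reciprocal-paint	68	T4 row MMO2,Z
AMA	GGA1	p	AMA1	q	reciprocal-paint	68	T4 row MMO4
AMA	GGA3	q	AMA6	whole	reciprocal-paint	68	T4 row MMO7
AMA	GGA1	q	AMA4	q	reciprocal-paint	68	T4 row MMO12
AMA	GGA2	p	AMA2	p	reciprocal-paint	68	T4 row MMO13
AMA	micro	whole	AMA2	p	reciprocal-paint	68	T4 row MMO13 (micro fused to 2p)
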