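# Chicken microchromosome BAC probes (GGA17-28, pair 20 gave no reproducible
# signal) mapped on monk parakeet (MMO) chromosomes; BAC clone in provenance.
taxon	ancestral_chr	ancestral_region	descendant_chr	descendant_region	evidence	diploid_number	provenance
MMO	GGA17	q	MMO15	q	BAC	48	CH261-42P16
MMO	GGA17	p	MMO15	q	BAC	48	CH261-113A7
MMO	GGA18	p	MMO16	p	BAC	48	CH261-60N6
MMO	GGA18	q	MMO16	q	BAC	48	CH261-72B18
MMO	GGA19	p	MMO17	p	BAC	48	CH261-10F1
MMO	GGA19	q	MMO17	p	BAC	48	CH261-50H12
MMO	GGA21	q	MMO18	q	BAC	48	CH261-122K8
MMO	GGA21	p	MMO18	p	BAC	48	CH261-83I20
MMO	GGA22	q	MMO4	p	BAC	48	CH261-18G17
MMO	GGA22	p	MMO4	q	BAC	48	CH261-40J9
MMO	GGA23	p	MMO1	p	BAC	48	CH261-191G17
MMO	GGA23	q	MMO1	p	BAC	48	CH261-90K11
MMO	GGA24	p	MMO19	p	BAC	48	CH261-103F4
MMO	GGA24	q	MMO19	q	BAC	48	CH261-65O4
MMO	GGA25	q	MMO1	p	BAC	48	CH261-127K7
MMO	GGA25	p	MMO1	p	BAC	48	CH261-59C21
MMO	GGA26	q	MMO20	q	BAC	48	CH261-170L23
MMO	GGA26	p	MMO20	p	BAC	48	CH261-186M13
MMO	GGA27	q	MMO21	p	BAC	48	CH261-28L10
MMO	GGA27	p	MMO21	q	BAC	48	CH261-66M16
MMO	GGA28	p	MMO22	p	BAC	48	CH261-64A15
MMO	GGA28	q	MMO22	q	BAC	48	CH261-72A10
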