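# Genotyping results for the 26 skeletal samples: 24-variant profiles with
# sample age class and starting template DNA amount.
# Transcribed by hand from the published multi-column table into one row per
# sample; genotype columns follow assay order (MC1R block at positions 1-11,
# then rs28777, rs16891982, rs12821256, rs4959270, rs12203592, rs1042602,
# rs1800407, rs2402130, rs12913832, rs2378249, rs12896399, rs1393350, rs683).
# template is stored verbatim as printed (the printed header says ng, while
# the accompanying text discusses reaction amounts in pg); "U" = DNA amount
# undeterminable because of PCR inhibition.  "-" = genotype not obtained.
# Genotype dialect: "C" homozygote, "G/T" heterozygote, "-" missing.
sample_id	age_class	template	N29insA	rs11547464	rs885479	rs1805008	rs1805005	rs1805006	rs1805007	rs1805009	Y152OCH	rs2228479	rs1110400	rs28777	rs16891982	rs12821256	rs4959270	rs12203592	rs1042602	rs1800407	rs2402130	rs12913832	rs2378249	rs12896399	rs1393350	rs683
S1	T/CR	0.6	C	G	C	C	G/T	C	C	G	C	G	T	A	G	A	C/A	C/T	G	G	A	C/T	T	T	C	G/T
S2	T/CR	1.7	C	G	C/T	C	G	C	C	G	C	G	T	A	G	A	C/A	C	G	G	A	C/T	T	T	C/T	G/T
S3	T/CR	1.2	C	G	C/T	C	G	C	C	G	C	G	T	A	G	G/A	C/A	C/T	G/T	G	G	C/T	T	G	C/T	G/T
S4	T/C	0.3	-	G	C	C/T	G	C	C	G	C	G	T	A	G	A	C/A	C	G/T	G	A	C	T	G/T	C	T
S5	B/C	U	C	G	C	C	G	C	C	G	C	G	T	C	C	A	C/A	C/T	G/T	G	A	C	T	T	C	G
S6	B/C	0.3	C	G	C	C	G	C	C	G	C	G	T	A	G	A	C	C	G/T	G	A	T	T	G/T	C	T
S7	B/C	0.15	-	G	C	C	G	C	C	G	C	G	T	C	C	A	C/A	C/T	G/T	G	A	C	T	T	C	G
S8	B/C	U	C	G	C	C	G	C	C	G	C	G	T	C/A	G/C	A	C/A	C	G	G	A	C/T	T	G	C	G/T
S9	B/C	0.5	C	G	C	C	G	C	C	G	C	G	T	C/A	G/C	A	C/A	C/T	G	G	A	C	T	T	C/T	G/T
S10	B/C	0.1	C	G	C	C	G	C	C	G	C	G	T	C/A	G/C	A	C	C	G	G	G/A	T	T	G/T	C/T	G/T
S11	T/2WW	0.6	C	G	C	C/T	G	C	C	G	C	G	T	A	G	A	A	C	G/T	G	A	C	T	T	C	T
S12	T/2WW	2	C	G	C	C/T	G	C	C	G	C	G	C/T	A	G	A	C	C	G	G	A	C	T	G/T	C/T	G/T
S13	T/2WW	0.3	C	G	C	C/T	G	C	C	G	C	G	T	A	G	A	A	C	G	G	A	C/T	T	T	C	G
S14	T/2WW	0.2	C	G	C	C	G	C	C	G	C	G	T	A	G	A	C/A	C	T	G	G/A	C	T	G	C/T	T
S15	T/2WW	1.2	C	G	C	C	G	C	C	G	C	G	T	A	G	A	A	C	G/T	G	G/A	C	T	G	C	G
S16	T/2WW	0.1	C	G	C	C	G	C	C	G	C	G	T	A	G	A	C/A	C	G	G	A	C	T	T	C	T
S17	T/2WW	0.8	C	G	C	C	G	C	C	G	C	G	T	A	G	A	C/A	C	G	G	A	C/T	T	G/T	C/T	G/T
S18	T/2WW	2.8	C	G	C	C/T	G	C	C	G	C	G	T	A	G	A	C/A	C	G/T	G	A	C	C/T	G/T	C/T	G/T
S19	T/2WW	0.8	C	G	C	C	G	C	C	G	C	G	T	A	G	A	A	C	G	G	A	C	T	T	C	T
S20	T/2WW	0.4	C	G	C	C	G	C	C	G	C	G	T	A	G	G/A	C	C	G/T	G	A	C/T	T	G/T	C/T	G/T
S21	T/2WW	0.3	C	G	C	C	G	C	C	G	C	G	T	A	G	A	C/A	C	G	G	A	C	T	G/T	C/T	T
S22	T/2WW	0.7	C	G	C	C	G	C	C	G	C	G	T	A	G	G	A	C	G	G	G	C	C/T	G	C	T
S23	T/2WW	1.3	C	G	C	C	G	C	C	G	C	G	T	A	G	A	C/A	C	G/T	G	A	C/T	T	G/T	C	T
S24	T/XII	0.03	C	G	C	C	G	C	C	G	C	G/A	T	A	G	A	C/A	C	G	G	A	C/T	T	G/T	T	G/T
S25	T/XIV	0.01	-	G	C	C	-	C	T	G	C	-	T	A	G	A	C/A	C	T	G	G	C	T	G	C/T	G/T
S26	T/XIV	0.16	C	G	C	C	G	C	C	G	C	G/A	T	A	G	A	C/A	C	T	G	A	C	T	G/T	C	G/T
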