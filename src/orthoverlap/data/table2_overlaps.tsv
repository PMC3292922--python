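# Curated overlapping-regulator table. sequence_names may hold several comma-separated
# worm sequence names when one non-worm source gene expands to a paralogue group.
# source_genes lists the evidence tokens (species:id) shared by every gene in the row;
# where the originating non-worm hit is known it is named, otherwise the worm gene stands in.
sequence_names	gene_names	description	organisms	disease_models	neuronal_expression	source_genes	provenance
Y53C10A.12	hsf-1	Heat-shock transcription factor	worm	Abeta, P, S, SOD, T	yes	worm:Y53C10A.12	overlap row 1
F26D10.3	hsp-1	HSP70 protein family	fly, worm	P, T, S	yes	worm:F26D10.3	overlap row 2
F54D5.8	dnj-13	Molecular chaperone (DnaJ)	fly	P, T	?	fly:CG8863	overlap row 3
K01C8.10	cct-4	Chaperone containing TCP-1	worm	P, SOD	yes	worm:K01C8.10	overlap row 4
C07G2.3	cct-5	Chaperone containing TCP-1	worm	P, SOD	?	worm:C07G2.3	overlap row 5
T09B4.10	chn-1	C-term of HSP-70 interacting protein (E3 ubiquitin ligase)	fly, worm	P, T	yes	worm:T09B4.10	overlap row 6
Y94H6A.6	ubc-8	Ubiquitin conjugating enzyme	fly, yeast	P, S	?	fly:CG2257; yeast:UBC8	overlap row 7
M7.1	let-70	E2 Ubiquitin conjugating enzyme	fly	P	yes	fly:CG5788	overlap row 8
C06A1.1	cdc-48.1	AAA ATPase, functions as a ubiquitin-related chaperone	worm	P	yes	worm:C06A1.1	overlap row 9
F52D10.3, M117.2	ftt-2, par-5	14-3-3 family	fly	P	yes	fly:CG31196	overlap row 10
C39F7.4	rab-1	Small Ras-like GTPase Rab1	fly, yeast, worm	P, S	yes	worm:C39F7.4	overlap row 11
B0361.10	ykt-6	SNARE protein YKT6	yeast	S	?	yeast:YKT6	overlap row 12
C54H2.5	sft-4	SURF-4 related to cargo transport protein ERV29	worm, yeast	S	yes	worm:C54H2.5	overlap row 13
Y54E2A.12	tbc-20	Predicted GTPase activator protein	yeast	S	?	yeast:GYP8	overlap row 14
R11A8.4	sir-2.1	NAD-dependent histone deacetylase	fly, worm	P, S	yes	worm:R11A8.4	overlap row 15
C53A5.3	hda-1	Histone deacetylase 1	fly, worm	P, S	No?	worm:C53A5.3	overlap row 16
F02E9.4	sin-3	SIN3 family of histone deacetylase subunits	fly	P, S	yes	fly:CG8815	overlap row 17
F59F4.1	-	Acyl-CoA oxidase	fly, yeast, worm	P, S, T	?	worm:F59F4.1	overlap row 18
ZK256.1a	pmr-1	Golgi P-type ATPase Ca2+ pump	yeast	S	yes	yeast:PMR1	overlap row 19
W08D2.5,	catp-6	Predicted lysosomal P-type ATPase	worm, yeast	S	?	worm:W08D2.5	overlap row 20
Y43F4B.4	npp-18	Nuclear pore complex protein	fly	P	yes	fly:CG8722	overlap row 21
F49E10.5	ctbp-1	Transcriptional co-repressor homolog	fly	P	?	fly:CG7583	overlap row 22
K08F8.6	let-19	Transcriptional cofactor	fly	P	yes	fly:CG42614	overlap row 23
T17E9.1	kin-18	Serine-threonine protein kinase	fly, worm	P, T	yes	worm:T17E9.1	overlap row 24
H18N23.2	-	Protein phosphatase, regulatory subunit PPP1R3C/D	fly, worm	P, SOD	?	worm:H18N23.2	overlap row 25
T14F9.1	vha-15	Vacuolar ATPase subunit H	worm	P, S	yes	worm:T14F9.1	overlap row 26
T21E12.4	dhc-1	Dynein heavy chain	fly, worm	P	yes	worm:T21E12.4	overlap row 27
Y113G7B.18	mdt-17	MeDiaTor	worm	S, SOD	?	worm:Y113G7B.18	overlap row 28
Y116A8C.35	uaf-2	U2AF splicing factor	worm	P, S	yes	worm:Y116A8C.35	overlap row 29
F56C11.1	bli-3	Homologue of dual oxidase	worm	P, SOD	No	worm:F56C11.1	overlap row 30
C32E8.10c	unc-11	Clathrin-adaptor protein AP180	worm, yeast	Abeta, P	yes	worm:C32E8.10	overlap row 31
JC8.10b	unc-26	Synaptojanin	worm, yeast	Abeta, P	yes	worm:JC8.10	overlap row 32
ZK742.1a	xpo-1	Exportin-1	fly, yeast	Abeta, P	?	fly:CG13387; yeast:CRM1	overlap row 33
C05C8.7	phi-49	Mannose-6-phosphate isomerase	worm	P, SOD	No	worm:C05C8.7	overlap row 34
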