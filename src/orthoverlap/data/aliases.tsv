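# Worm gene-symbol aliases resolving to canonical sequence names.
species	alias	canonical	provenance
worm	hsf-1	Y53C10A.12	curated
worm	hsp-1	F26D10.3	curated
worm	dnj-13	F54D5.8	curated
worm	cct-4	K01C8.10	curated
worm	cct-5	C07G2.3	curated
worm	chn-1	T09B4.10	curated
worm	ubc-8	Y94H6A.6	curated
worm	let-70	M7.1	curated
worm	cdc-48.1	C06A1.1	curated
worm	ftt-2	F52D10.3	curated
worm	par-5	M117.2	curated
worm	rab-1	C39F7.4	curated
worm	ykt-6	B0361.10	curated
worm	sft-4	C54H2.5	curated
worm	tbc-20	Y54E2A.12	curated
worm	sir-2.1	R11A8.4	curated
worm	hda-1	C53A5.3	curated
worm	sin-3	F02E9.4	curated
worm	pmr-1	ZK256.1	curated
worm	catp-6	W08D2.5	curated
worm	npp-18	Y43F4B.4	curated
worm	ctbp-1	F49E10.5	curated
worm	let-19	K08F8.6	curated
worm	kin-18	T17E9.1	curated
worm	vha-15	T14F9.1	curated
worm	phi-52	T14F9.1	curated
worm	dhc-1	T21E12.4	curated
worm	mdt-17	Y113G7B.18	curated
worm	uaf-2	Y116A8C.35	curated
worm	bli-3	F56C11.1	curated
worm	unc-11	C32E8.10	curated
worm	unc-26	JC8.10	curated
worm	xpo-1	ZK742.1	curated
worm	phi-49	C05C8.7	curated
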