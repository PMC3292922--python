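# Human protein labels of the interaction subnetwork and their worm cross-references.
protein	worm_gene	worm_name
HSF1	Y53C10A.12	hsf-1
Hsc70	F26D10.3	hsp-1
DnaJB5	F54D5.8	dnj-13
CHIP	T09B4.10	chn-1
p97	C06A1.1	cdc-48.1
Ube2D2	M7.1	let-70
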