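# Functional class assignments for the overlapping regulators, by curated biological process.
# Gene names are given in canonical worm symbol form (obvious typographical variants in the
# source table -- "sir2.1", "had-1", "fft-2" -- are transcribed as sir-2.1, hda-1, ftt-2).
gene	functional_class	source	provenance
hsf-1	Heat shock transcription factor	curated	class row 1
hsp-1	Molecular chaperones	curated	class row 2
dnj-13	Molecular chaperones	curated	class row 2
cct-4	Molecular chaperones	curated	class row 2
cct-5	Molecular chaperones	curated	class row 2
chn-1	Ubiquitin related	curated	class row 3
ubc-8	Ubiquitin related	curated	class row 3
let-70	Ubiquitin related	curated	class row 3
cdc-48.1	Ubiquitin related	curated	class row 3
sir-2.1	Histone deacetylases	curated	class row 4
hda-1	Histone deacetylases	curated	class row 4
sin-3	Histone deacetylases	curated	class row 4
ftt-2	Signalling/chaperone	curated	class row 5
par-5	Signalling/chaperone	curated	class row 5
ctbp-1	Transcriptional cofactor/regulator	curated	class row 6
let-19	Transcriptional cofactor/regulator	curated	class row 6
mdt-17	Transcriptional cofactor/regulator	curated	class row 6
uaf-2	Transcriptional cofactor/regulator	curated	class row 6
npp-18	Nucleopore/nuclear export	curated	class row 7
xpo-1	Nucleopore/nuclear export	curated	class row 7
rab-1	Vesicular transport	curated	class row 8
sft-4	Vesicular transport	curated	class row 8
tbc-20	Vesicular transport	curated	class row 8
ykt-6	Vesicular transport	curated	class row 8
dhc-1	Vesicular transport	curated	class row 8
unc-11	Endocytosis	curated	class row 9
unc-26	Endocytosis	curated	class row 9
catp-6	Transport ATPase	curated	class row 10
pmr-1	Transport ATPase	curated	class row 10
vha-15	Transport ATPase	curated	class row 10
kin-18	Protein phosphorylation	curated	class row 11
H18N23.2	Protein phosphorylation	curated	class row 11
bli-3	Other cellular processes	curated	class row 12
phi-49	Other cellular processes	curated	class row 12
F59F4.1	Other cellular processes	curated	class row 12
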