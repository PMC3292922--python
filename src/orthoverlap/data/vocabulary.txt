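# Controlled vocabulary of functional classes for regulator annotation.
Heat shock transcription factor
Molecular chaperones
Ubiquitin related
Histone deacetylases
Signalling/chaperone
Transcriptional cofactor/regulator
Nucleopore/nuclear export
Vesicular transport
Endocytosis
Transport ATPase
Protein phosphorylation
Other cellular processes
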