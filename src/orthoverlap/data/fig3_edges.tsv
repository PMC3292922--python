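# Binary protein-protein interactions among the chaperone and ubiquitin-related
# overlapping regulators, labelled by human orthologue name.
protein_a	protein_b	provenance
CHIP	Ube2D2	stated in text
CHIP	p97	stated in text
CHIP	Hsc70	stated in text
CHIP	HSF1	stated in text
Hsc70	DnaJB5	drawn in network figure
Hsc70	HSF1	drawn in network figure
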