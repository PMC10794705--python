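kind	from_name	to_name	to_taxid
rename	Prevotella_copri_clade_A	Prevotella_copri
rename	Clostridium_clostridioforme	Clostridium_clostridiiforme
reclassify	Salmonella enterica subsp. enterica	Salmonella enterica	28901
reclassify	Escherichia coli O157:H7	Escherichia coli	562
merge	Bifidobacterium longum subsp. longum	Bifidobacterium longum
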