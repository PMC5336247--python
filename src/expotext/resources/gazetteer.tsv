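# Built-in baseline named-entity gazetteer: entity_type<TAB>phrase (lowercased).
# Types are the five biomedical entity classes: DNA, RNA, protein, cell_line, cell_type.
protein	hemoglobin
protein	albumin
protein	insulin
protein	ferritin
protein	transferrin
protein	cytokine
protein	cytokines
protein	interleukin
protein	glutathione peroxidase
protein	superoxide dismutase
protein	metallothionein
protein	alpha-fetoprotein
protein	c-reactive protein
DNA	dna
DNA	dna adduct
DNA	dna adducts
DNA	mitochondrial dna
DNA	plasmid
RNA	rna
RNA	mrna
RNA	microrna
RNA	messenger rna
cell_line	hela
cell_line	jurkat
cell_line	hepg2
cell_line	mcf-7
cell_type	lymphocyte
cell_type	lymphocytes
cell_type	erythrocyte
cell_type	erythrocytes
cell_type	hepatocyte
cell_type	hepatocytes
cell_type	monocyte
cell_type	monocytes
cell_type	leukocyte
cell_type	leukocytes
cell_type	neutrophil
cell_type	neutrophils
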