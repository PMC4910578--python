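# Curated ligand-bound template set: one row per (accession, site occurrence).
# het: PDB chemical-component code when pinned; blank = take the largest
#      non-solvent het group in the file.
# expected_class is consultative (used only by tests/analyses that have the
# coordinate files available); the pipeline always classifies from geometry.
accession	het	ligand	expected_class
4COF	BEN	benzamidine	1
4F8H		R-ketamine	2
5AFJ		fragment-1	2
2YN6	BA	barium	3
2YOE		flurazepam	4
5AFM		fragment-4	4
3ZKR		bromoform	5
5AFJ		fragment-1	6
4HFD		bromoform	7
4HFC		bromoethanol	7
4HFE		ethanol	7
3RIF		avermectin	7
4TNW		POPC	7
3P4W		desflurane	8
3P50		propofol	8
4HFH		bromoform	8
3ZKR		bromoform	9
3EAM		lipid	10
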