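# pFLAG pathway definitions: six categories of putative free-living
# associated genes.  Steps are reaction steps; comma-separated entries
# within a step are isofunctional alternatives.  Edit this file to
# redefine pFLAG membership for a specific annotation scheme.
pathway_id	name	category	step_index	alternatives
glycolysis_emp	Embden-Meyerhof-Parnas glycolysis	glycolysis	1	glk,pfkC
glycolysis_emp	Embden-Meyerhof-Parnas glycolysis	glycolysis	2	pgi1,pgi-pmi
glycolysis_emp	Embden-Meyerhof-Parnas glycolysis	glycolysis	3	pfkA,pfkC
glycolysis_emp	Embden-Meyerhof-Parnas glycolysis	glycolysis	4	fbaA
glycolysis_emp	Embden-Meyerhof-Parnas glycolysis	glycolysis	5	tpiA
glycolysis_emp	Embden-Meyerhof-Parnas glycolysis	glycolysis	6	gapA
glycolysis_emp	Embden-Meyerhof-Parnas glycolysis	glycolysis	7	pgk
glycolysis_emp	Embden-Meyerhof-Parnas glycolysis	glycolysis	8	apgM
glycolysis_emp	Embden-Meyerhof-Parnas glycolysis	glycolysis	9	eno
glycolysis_emp	Embden-Meyerhof-Parnas glycolysis	glycolysis	10	pyk
tca_cycle	TCA cycle	TCA	1	gltA
tca_cycle	TCA cycle	TCA	2	acnA
tca_cycle	TCA cycle	TCA	3	icd
tca_cycle	TCA cycle	TCA	4	korA
tca_cycle	TCA cycle	TCA	5	sucC
tca_cycle	TCA cycle	TCA	6	sdhA
tca_cycle	TCA cycle	TCA	7	fumC
tca_cycle	TCA cycle	TCA	8	mdh
purine_synthesis	de novo purine biosynthesis	nucleotide biosynthesis	1	purF
purine_synthesis	de novo purine biosynthesis	nucleotide biosynthesis	2	purD
purine_synthesis	de novo purine biosynthesis	nucleotide biosynthesis	3	purN
purine_synthesis	de novo purine biosynthesis	nucleotide biosynthesis	4	purL
purine_synthesis	de novo purine biosynthesis	nucleotide biosynthesis	5	purS
purine_synthesis	de novo purine biosynthesis	nucleotide biosynthesis	6	purM
purine_synthesis	de novo purine biosynthesis	nucleotide biosynthesis	7	purB
purine_synthesis	de novo purine biosynthesis	nucleotide biosynthesis	8	purH
pyrimidine_synthesis	de novo pyrimidine biosynthesis	nucleotide biosynthesis	1	pyrB
pyrimidine_synthesis	de novo pyrimidine biosynthesis	nucleotide biosynthesis	2	pyrC
pyrimidine_synthesis	de novo pyrimidine biosynthesis	nucleotide biosynthesis	3	pyrD
pyrimidine_synthesis	de novo pyrimidine biosynthesis	nucleotide biosynthesis	4	pyrE
pyrimidine_synthesis	de novo pyrimidine biosynthesis	nucleotide biosynthesis	5	pyrF
amino_acid_synthesis	de novo amino-acid biosynthesis	amino-acid biosynthesis	1	aspB,hisC
amino_acid_synthesis	de novo amino-acid biosynthesis	amino-acid biosynthesis	2	trpB
amino_acid_synthesis	de novo amino-acid biosynthesis	amino-acid biosynthesis	3	hisD
amino_acid_synthesis	de novo amino-acid biosynthesis	amino-acid biosynthesis	4	ilvE
amino_acid_synthesis	de novo amino-acid biosynthesis	amino-acid biosynthesis	5	alaA,ala
amino_acid_synthesis	de novo amino-acid biosynthesis	amino-acid biosynthesis	6	lysA
amino_acid_synthesis	de novo amino-acid biosynthesis	amino-acid biosynthesis	7	thrC
amino_acid_synthesis	de novo amino-acid biosynthesis	amino-acid biosynthesis	8	kbl
amino_acid_synthesis	de novo amino-acid biosynthesis	amino-acid biosynthesis	9	serA
amino_acid_synthesis	de novo amino-acid biosynthesis	amino-acid biosynthesis	10	asnA,asnB
cofactor_synthesis	de novo cofactor biosynthesis	cofactor biosynthesis	1	thiC
cofactor_synthesis	de novo cofactor biosynthesis	cofactor biosynthesis	2	folE
cofactor_synthesis	de novo cofactor biosynthesis	cofactor biosynthesis	3	ribB
cofactor_synthesis	de novo cofactor biosynthesis	cofactor biosynthesis	4	nadA
cofactor_synthesis	de novo cofactor biosynthesis	cofactor biosynthesis	5	hemB
cofactor_synthesis	de novo cofactor biosynthesis	cofactor biosynthesis	6	menA
cofactor_synthesis	de novo cofactor biosynthesis	cofactor biosynthesis	7	coaBC
cofactor_synthesis	de novo cofactor biosynthesis	cofactor biosynthesis	8	panB
membrane_synthesis	archaeal membrane-lipid biosynthesis	membrane biosynthesis	1	ACAT
membrane_synthesis	archaeal membrane-lipid biosynthesis	membrane biosynthesis	2	HMGCS
membrane_synthesis	archaeal membrane-lipid biosynthesis	membrane biosynthesis	3	HMGCR
membrane_synthesis	archaeal membrane-lipid biosynthesis	membrane biosynthesis	4	MVK
membrane_synthesis	archaeal membrane-lipid biosynthesis	membrane biosynthesis	5	PMVK
membrane_synthesis	archaeal membrane-lipid biosynthesis	membrane biosynthesis	6	MVD,ipk
membrane_synthesis	archaeal membrane-lipid biosynthesis	membrane biosynthesis	7	idi
membrane_synthesis	archaeal membrane-lipid biosynthesis	membrane biosynthesis	8	araM
membrane_synthesis	archaeal membrane-lipid biosynthesis	membrane biosynthesis	9	GGGPS
membrane_synthesis	archaeal membrane-lipid biosynthesis	membrane biosynthesis	10	DGGGPS
membrane_synthesis	archaeal membrane-lipid biosynthesis	membrane biosynthesis	11	pssA
membrane_synthesis	archaeal membrane-lipid biosynthesis	membrane biosynthesis	12	dxs
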