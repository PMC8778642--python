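family	database	predicted_name	putative_role
A01	MEROPS	endopeptidase	Nutrition, pathogenicity
A28	MEROPS	retropepsin	Unknown
C110	MEROPS	peptide-N(4)-(N-acetyl-beta-glucosaminyl) asparagine amidase	Protein degradation
C14	MEROPS	caspases	Controlled cell death
C19	MEROPS	ubiquitin-carboxyl-hydrolase	Nutrition
C46	MEROPS	hint domain containing	Putative mating response
G05	MEROPS	type II CAAX-prenyl-endopeptidase	Protein modification
I04	MEROPS	serpin	Peptidase inhibitor
M13	MEROPS	unknown peptidase	Nutrition
M20	MEROPS	N-acyl-L-amino-acid-amidohydrolase	Nutrition
M20	MEROPS	unknown peptidase	Unknown
M24	MEROPS	MAP1	Maturation of the nascent polypeptide during translation
M24	MEROPS	MAP2	Maturation of the nascent polypeptide during translation
M24	MEROPS	Xaa-Pro aminopeptidase	Nutrition
M28	MEROPS	glutamate carboxypeptidase	Unknown
M36	MEROPS	fungalysin	Nutrition, pathogenicity
M38	MEROPS	allantoinase	Uric acid degradation pathway, pathogenicity
M38	MEROPS	unknown peptidase	Uric acid degradation pathway, pathogenicity
M38	MEROPS	dihydroorotase	Uric acid degradation pathway, pathogenicity
M38	MEROPS	guanine deaminase	Uric acid degradation pathway, pathogenicity
M38	MEROPS	urease	Uric acid degradation pathway, pathogenicity
M38	MEROPS	N-acetylglucosamine-6-phosphate-deacetylase	Chitin degradation
S01	MEROPS	serine protease (extracellular)	Nutrition
S08	MEROPS	subtilisin	Nutrition
S54	MEROPS	rhomboid proteases	Mitochondrial endopeptidase
U69	MEROPS	polysaccharide lyases	Nutrition
AA3	CAZY	glucose-methanol-choline (GMC) oxidoreductases	Nutrition
AA5	CAZY	galactose oxidase	Nutrition
AA6	CAZY	1,4-benzoquinone reductase	Nutrition, interaction with insects
AA7	CAZY	glucooligosaccharide-oxidase/chitooligosaccharide-oxidase/cellooligosaccharide-dehydrogenase	Cell wall remodelling
CE1	CAZY	esterase domain containing	Nutrition
CE1	CAZY	feruloyl/acetylxylan esterase	Nutrition
CE1	CAZY	rhamnogalacturonan-acetylesterase	Nutrition
CE12	CAZY	rhamnogalacturonan-acetylesterase	Nutrition
CE16	CAZY	acetylesterase	Nutrition
CE2	CAZY	acetyl-xylan esterase	Nutrition
CE4	CAZY	chitin deacetylase	Cell wall remodelling
CE6	CAZY	acetyl-xylan esterase	Nutrition
GH10	CAZY	xylanase	Nutrition
GH109	CAZY	alpha-N-acetylgalactosaminidase	Glycolipids modification
GH11	CAZY	endo-1-4-beta-xylanase	Nutrition
GH114	CAZY	alpha-galactosidase	Nutrition
GH132	CAZY	beta-glucosidase	Pathogenicity
GH15	CAZY	glucoamylase	Nutrition
GH16	CAZY	endo-beta-glucanase	Nutrition
GH17	CAZY	glucan-1,3-beta-glucosidase	Cell wall remodelling
GH18	CAZY	chitinase	Cell wall remodelling
GH19	CAZY	chitinase	Interaction with insects
GH24	CAZY	lysozyme	Cell wall remodelling
GH26	CAZY	endo-1,4-beta-mannosidase	Cell wall remodelling, nutrition
GH3	CAZY	beta-glucosidase	Nutrition
GH43	CAZY	arabinase/levansucrase/invertase	Nutrition
GH45	CAZY	endoglucanase	Nutrition
GH48	CAZY	cellulase	Nutrition
GH5	CAZY	cellulase	Nutrition
GH5	CAZY	exo-beta-1,3-glucanase	Cell wall remodelling
GH6	CAZY	cellobiohydrolase	Nutrition
GH6	CAZY	endoglucanase	Nutrition
GH72	CAZY	1,3-beta-glucanosyltransferase	Cell wall remodelling
GH9	CAZY	cellulase	Nutrition
GT1	CAZY	UDP-glucuronosyltransferase	Cell wall remodelling
GT15	CAZY	alpha-1,2-mannosyltransferase	Cell wall remodelling, pathogenicity
GT17	CAZY	beta-1,4-mannosyl-glycoprotein-beta-1,4-N-acetylglucosaminyltransferase	Cell wall remodelling
GT2	CAZY	chitin synthase 2	Cell wall remodelling
GT2	CAZY	chitin synthase 6	Cell wall remodelling
GT34	CAZY	galactomannan-alpha-1,6-galactosyltransferase/xyloglucan-alpha-1,6-xylosyltransferase/alpha-1,2-galactosyltransferase	Cell wall remodelling
GT49	CAZY	beta-1,3-N-acetylglucosaminyltransferase	Glycosylation
GT68	CAZY	GT68_protein-O-alpha-fucosyltransferase	Protein modification
GT69	CAZY	alpha-1,3-mannosyltransferase	Cell wall remodelling, pathogenicity
GT71	CAZY	alpha-mannosyltransferase	Cell wall remodelling, protein modification
GT77	CAZY	alpha-xylosyltransferase/alpha-1,3-galactosyltransferase/arabinosyltransferase	Protein modification
PL1	CAZY	pectin lyase	Nutrition
PL3	CAZY	pectate lyase	Nutrition
PL4	CAZY	rhamnogalacturonan endolyase	Nutrition
1.A.1	TCDB	The Voltage-gated Ion Channel (VIC) Superfamily	Response to stress
1.A.105	TCDB	The Mixed Lineage Kinase Domain-like (MLKL) Family	Programmed cell death
1.A.33	TCDB	The Cation Channel-forming Heat Shock Protein-70 (Hsp70) Family	Response to stress
1.A.4	TCDB	The Transient Receptor Potential Ca2+ Channel (TRP-CC) Family	Response to stress
1.C.63	TCDB	The alpha-Latrotoxin (Latrotoxin) Family	Unknown
1.I.1	TCDB	The Nuclear Pore Complex (NPC) Family	Unknown
2.A.1	TCDB	The Major Facilitator Superfamily (MFS)	Nutrition, drug and metabolites transport
2.A.18	TCDB	Vacuolar amino acid transporter	Nutrition
2.A.2	TCDB	The Glycoside-Pentoside-Hexuronide (GPH): Cation Symporter Family	Nutrition
2.A.29	TCDB	The Mitochondrial Carrier (MC) Family	Molecules transfer to mitochondria
2.A.3	TCDB	The Amino Acid-Polyamine-Organocation (APC) Superfamily	Nutrition
2.A.4	TCDB	The Cation Diffusion Facilitator (CDF) Family	Heavy metal transport
2.A.7	TCDB	The Drug/Metabolite Transporter (DMT) Superfamily	Drug/ion resistance, cell wall remodelling
3.A.1	TCDB	The ATP-binding Cassette (ABC) Superfamily	Essential for many processes in the cell
3.A.16	TCDB	The Endoplasmic Reticular Retrotranslocon (ER-RT or ERAD) Family	Protein degradation
3.A.2	TCDB	The H+- or Na+-translocating F-type, V-type and A-type ATPase (F-ATPase) Superfamily	Decomposition of ATP to ADP
8.A.28	TCDB	The Ankyrin (Ankyrin) Family	Unknown
8.A.5	TCDB	The Voltage-gated K+ Channel beta-subunit (Kvbeta) Family	Unknown
8.A.8	TCDB	The Phosphotransferase System HPr (HPr) Family	Unknown
8.A.85	TCDB	The Guanylate Cyclase (GC) Family	Unknown
9.A.1	TCDB	The Non ABC Multidrug Exporter (N-MDE) Family	Drug resistance
9.A.3	TCDB	The Retromer Assembly Apparatus (RetromerAA) Family	Protein recycling
9.A.63	TCDB	The Retromer-dependent Vacuolar Protein Sorting (R-VPS) Family	Intracellular sorting
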