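protein_name	pdb_id	met_pos	reactivity_class
Granulocyte Colony-Stimulating Factor	1CD9	122	low
Granulocyte Colony-Stimulating Factor	1CD9	127	high
Granulocyte Colony-Stimulating Factor	1CD9	138	high
Alpha1-Antitrypsin	1HP7	63	low
Alpha1-Antitrypsin	1HP7	220	low
Alpha1-Antitrypsin	1HP7	221	low
Alpha1-Antitrypsin	1HP7	242	low
Alpha1-Antitrypsin	1HP7	374	low
Alpha1-Antitrypsin	1HP7	385	low
Alpha1-Antitrypsin	1HP7	226	high
Alpha1-Antitrypsin	1HP7	351	high
Alpha1-Antitrypsin	1HP7	358	high
Prion Protein	1B10	154	low
Prion Protein	1B10	206	low
Prion Protein	1B10	213	low
Prion Protein	1B10	129	high
Prion Protein	1B10	134	high
IgG1-Fc	1FC1	358	low
IgG1-Fc	1FC1	428	low
IgG1-Fc	1FC1	252	high
Stem Cell Factor	1EXZ	36	low
Stem Cell Factor	1EXZ	48	low
Stem Cell Factor	1EXZ	27	high
Coagulation Factor VIIa	1QFK	327	low
Coagulation Factor VIIa	1QFK	391	low
Coagulation Factor VIIa	1QFK	298	high
Coagulation Factor VIIa	1QFK	306	high
Growth Hormone	1HGU	170	low
Growth Hormone	1HGU	14	high
Growth Hormone	1HGU	125	high
Chorionic Somatomammotropin	1Z7C	14	low
Chorionic Somatomammotropin	1Z7C	96	low
Chorionic Somatomammotropin	1Z7C	170	low
Chorionic Somatomammotropin	1Z7C	125	high
Chorionic Somatomammotropin	1Z7C	179	high
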