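# Biosynthetic cost of the 20 proteinogenic amino acids under three metrics,
# compiled from the comparative-cost literature (ATP equivalents per molecule):
# energetic_atp        — respiratory energetic cost (Akashi & Gojobori-style accounting)
# fermentative_atp     — opportunity cost under fermentative metabolism (Wagner-style)
# energetic_precursor  — energetic cost including diverted precursor value
amino_acid	energetic_atp	fermentative_atp	energetic_precursor
ala	11.7	2.0	14.5
arg	27.3	13.0	20.5
asn	14.7	6.0	18.5
asp	12.7	3.0	15.5
cys	24.7	13.0	26.5
gln	16.3	3.0	10.5
glu	15.3	2.0	9.5
gly	11.7	1.0	14.5
his	38.3	5.0	29.0
ile	32.3	14.0	38.0
leu	27.3	4.0	37.0
lys	30.3	12.0	36.0
met	34.3	24.0	36.5
phe	52.0	10.0	61.0
pro	20.3	7.0	14.5
ser	11.7	1.0	14.5
thr	18.7	9.0	21.5
trp	74.3	14.0	75.5
tyr	50.0	8.0	59.0
val	23.3	4.0	29.0
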