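id	name	formula	monoisotopic_mass
gly	Glycine	C2H5NO2	75.032028
ala	L-Alanine	C3H7NO2	89.047678
ser	L-Serine	C3H7NO3	105.042593
pro	L-Proline	C5H9NO2	115.063329
val	L-Valine	C5H11NO2	117.078979
thr	L-Threonine	C4H9NO3	119.058243
cys	L-Cysteine	C3H7NO2S	121.019749
leu	L-Leucine	C6H13NO2	131.094629
ile	L-Isoleucine	C6H13NO2	131.094629
asn	L-Asparagine	C4H8N2O3	132.053492
asp	L-Aspartate	C4H7NO4	133.037508
gln	L-Glutamine	C5H10N2O3	146.069142
lys	L-Lysine	C6H14N2O2	146.105528
glu	L-Glutamate	C5H9NO4	147.053158
met	L-Methionine	C5H11NO2S	149.051050
his	L-Histidine	C6H9N3O2	155.069477
phe	L-Phenylalanine	C9H11NO2	165.078979
arg	L-Arginine	C6H14N4O2	174.111676
tyr	L-Tyrosine	C9H11NO3	181.073893
trp	L-Tryptophan	C11H12N2O2	204.089878
akg	2-Oxoglutarate	C5H6O5	146.021523
succ	Succinate	C4H6O4	118.026609
lac	Lactate	C3H6O3	90.031694
orn	L-Ornithine	C5H12N2O2	132.089878
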