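# Synthetic stand-in for a 35-component chemically defined interaction medium
# (CDM35-like): eight amino acids, ammonium as the bulk nitrogen source, a
# sugar, nucleobases, vitamins and salts. Caps in mmol·gDW⁻¹·h⁻¹ are a
# modeling choice, not a measured composition.
metabolite	max_uptake
glc_e	10
nh4_e	10
arg_e	1
asn_e	1
his_e	1
ile_e	1
leu_e	1
met_e	1
val_e	1
tyr_e	1
pi_e	10
so4_e	5
mg2_e	1
k_e	1
na1_e	1
ca2_e	1
cl_e	1
mn2_e	0.1
zn2_e	0.1
fe2_e	0.1
cu2_e	0.1
cobalt2_e	0.1
ade_e	0.5
gua_e	0.5
ura_e	0.5
xan_e	0.5
thm_e	0.1
ribflv_e	0.1
nac_e	0.1
pnto_e	0.1
pydx_e	0.1
btn_e	0.01
fol_e	0.01
4abz_e	0.01
citr_e	0.5
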