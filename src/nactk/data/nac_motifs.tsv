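# NAC domain core consensus motifs, one per line, in canonical N->C order.
# columns: name<TAB>role<TAB>prosite_pattern
# role: core   = NAC-domain signature motif (counted toward a domain call)
#       nes    = nuclear export signal / negative regulatory motif
#       partner= non-NAC signature used for chimeric-architecture flagging
nac_a_pgfrf	core	P-G-F-R-F-H-P-T-D-[DE]-L-[IV]
nac_b_ylk	core	Y-L-x(2)-K
nac_c_dlkpwlp	core	D-L-x-K-x(2)-P-W-x-L-P
nac_d_ewyff	core	E-W-Y-F-F
nac_e_gywk	core	G-Y-W-K-[AT]-T-G-x-D-x(1,2)-[IV]
nac_f_gkklvfy	core	G-x-K-K-x-L-V-F-Y
nac_g_mhey	core	T-x-W-x-M-H-E-Y
nac_h_lvfy	core	L-V-F-Y
nes_lvfy	nes	L-[VI]-[FM]-[YM]
wrky_sig	partner	W-R-K-Y-G-Q-K
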