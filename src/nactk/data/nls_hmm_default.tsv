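# Two-state NLS HMM parameters: section<TAB>key<TAB>value
# sections: initial (state), transition (from,to), emission (state,residue)
initial	BG	0.99
initial	NLS	0.01
transition	BG,BG	0.99
transition	BG,NLS	0.01
transition	NLS,BG	0.10
transition	NLS,NLS	0.90
emission	BG,A	0.05
emission	BG,C	0.05
emission	BG,D	0.05
emission	BG,E	0.05
emission	BG,F	0.05
emission	BG,G	0.05
emission	BG,H	0.05
emission	BG,I	0.05
emission	BG,K	0.05
emission	BG,L	0.05
emission	BG,M	0.05
emission	BG,N	0.05
emission	BG,P	0.05
emission	BG,Q	0.05
emission	BG,R	0.05
emission	BG,S	0.05
emission	BG,T	0.05
emission	BG,V	0.05
emission	BG,W	0.05
emission	BG,Y	0.05
emission	NLS,A	0.022222222222222223
emission	NLS,C	0.022222222222222223
emission	NLS,D	0.022222222222222223
emission	NLS,E	0.022222222222222223
emission	NLS,F	0.022222222222222223
emission	NLS,G	0.022222222222222223
emission	NLS,H	0.022222222222222223
emission	NLS,I	0.022222222222222223
emission	NLS,K	0.3
emission	NLS,L	0.022222222222222223
emission	NLS,M	0.022222222222222223
emission	NLS,N	0.022222222222222223
emission	NLS,P	0.022222222222222223
emission	NLS,Q	0.022222222222222223
emission	NLS,R	0.3
emission	NLS,S	0.022222222222222223
emission	NLS,T	0.022222222222222223
emission	NLS,V	0.022222222222222223
emission	NLS,W	0.022222222222222223
emission	NLS,Y	0.022222222222222223
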