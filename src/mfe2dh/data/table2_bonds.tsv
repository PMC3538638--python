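bond_id	donor_chain	donor_res	donor_atom	acceptor_chain	acceptor_res	acceptor_atom	scope	label	site
T15 N - V97 O	A	15	N	A	97	O	intra_monomer	NAD+ binding site	cofactor
T15 OG1 - N99 N	A	15	OG1	A	99	N	intra_monomer	NAD+ binding site	cofactor
T15 OG1 - A100 N	A	15	OG1	A	100	N	intra_monomer	NAD+ binding site	cofactor
L103 N - F45 O	A	103	N	A	45	O	intra_monomer	Above the catalytic triad	catalytic
H123 NE2 - I102 O	A	123	NE2	A	102	O	intra_monomer	Above the catalytic triad	catalytic
Q141 NE2 - I93 O	A	141	NE2	A	93	O	intra_monomer	On the surface	surface
G160 O - R106 N	A	106	N	A	160	O	intra_monomer	In the loops above the cavity	substrate
K168 NZ - T149 O	A	168	NZ	A	149	O	intra_monomer	K168 belongs to the catalytic triad	catalytic
E232 O - N190 ND2	A	190	ND2	A	232	O	intra_monomer	N190 in Rossmann-fold beta-sheet	cofactor
R251 N - S283 O	A	251	N	A	283	O	intra_monomer	Area important for the substrate binding	substrate
R251 O - S283 N	A	283	N	A	251	O	intra_monomer	Area important for the substrate binding	substrate
N158 O - S177 OG	A	177	OG	B	158	O	inter_monomer	On the top of the cavity	substrate
E181 OE - F108 N	A	108	N	B	181	OE	inter_monomer	Above the cavity	substrate
E181 OE - G160 N	A	160	N	B	181	OE	inter_monomer	Above the cavity	substrate
R251 NH - E238 OE	A	251	NH	B	238	OE	inter_monomer	Area important for the substrate binding	substrate
L253 O - W243 NE1	A	243	NE1	B	253	O	inter_monomer	Catalytic domain and C-terminal subdomain dimerization	dimerization
E267 OE - R32 NH	A	32	NH	B	267	OE	inter_monomer	Catalytic domain and C-terminal subdomain dimerization	dimerization
V257 N - G242 O	A	257	N	B	242	O	inter_monomer	Catalytic domain and C-terminal subdomain dimerization	dimerization
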