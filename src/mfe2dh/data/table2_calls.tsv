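bond_id	NATIVE	T15A	N158D	E232K	R248C	W249G
T15 N - V97 O	+	-	+	+	+	+
T15 OG1 - N99 N	+	-	-	-	-	-
T15 OG1 - A100 N	+	-	-	-	-	-
L103 N - F45 O	+	-	-	-	+	-
H123 NE2 - I102 O	+	+	+	-	+	-
Q141 NE2 - I93 O	+	-	+	+	-	+
G160 O - R106 N	+	-	-	-	-	-
K168 NZ - T149 O	-	-	-	-	+	-
E232 O - N190 ND2	+	+	+	-	+	-
R251 N - S283 O	+	+	-	+	+	+
R251 O - S283 N	+	+	-	+	+	+
N158 O - S177 OG	-	-	-	-	-	+
E181 OE - F108 N	+	-	-	-	-	+
E181 OE - G160 N	+	-	-	-	-	-
R251 NH - E238 OE	-	-	+	-	-	-
L253 O - W243 NE1	-	-	+	-	-	-
E267 OE - R32 NH	+	-	+	-	+	-
V257 N - G242 O	+	+	+	+	+	+
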