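symbol	display_symbol	group_name	contribution_e6_cm3_mol	implied_h	smarts	provenance
A	A	-H	4.0	1		methane/ethane stoichiometric difference
F	F	-Br	26.65	0	[Br]	canonical
I	I	-CH2- (in chain)	11.8	2	[CX4H2]	canonical
J	J	-OH	10.8	1	[OX2H]	canonical
P	P	-Phenyl	50.84	5	c1ccccc1	canonical
Delta	Δ	-(C=NH)	11.1	1	[CX3H1]=[NX2]	canonical
Th	Þ	-OCH3	17.9	3	[OX2][CH3]	canonical
Phi17	Φ17	-O-	4.7	0	[OX2H0]	derived from diethyl ether
CH3	CH3	-CH3	13.4	3	[CX4H3]	diethyl ether arithmetic
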