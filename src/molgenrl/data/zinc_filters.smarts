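# Functional-group exclusion catalog used by the generation reward
# (reactive / promiscuous groups commonly screened out of purchasable
# compound libraries). One pattern per line: <name><TAB><SMARTS>.
# Lines starting with '#' are comments. The catalog is editable; the
# reward grants its filter bonus only to molecules matching none of
# these patterns.
acyl_halide	[CX3](=[OX1])[F,Cl,Br,I]
sulfonyl_halide	[SX4](=[OX1])(=[OX1])[F,Cl,Br,I]
acid_anhydride	[CX3](=[OX1])[OX2][CX3](=[OX1])
peroxide	[OX2][OX2]
isocyanate	[NX2]=[CX2]=[OX1]
isothiocyanate	[NX2]=[CX2]=[SX1]
azide	[NX1]~[NX2]~[NX2,NX1]
diazonium	[NX2+]#[NX1]
diazo	[CX2]=[NX2+]=[NX1-]
nitroso	[NX2](=[OX1])[!#8]
n_nitro	[NX3][NX3+](=[OX1])[O-]
hydrazine	[NX3][NX3]
epoxide	C1OC1
aziridine	C1NC1
thiirane	C1SC1
alpha_halo_ketone	[CX3](=[OX1])[CX4][F,Cl,Br,I]
alkyl_halide_reactive	[CH2X4][Br,I]
aldehyde	[CX3H1](=[OX1])[#6]
thiol	[SX2H]
michael_acceptor_nitrile	C=C[CX2]#N
vinyl_sulfone	C=C[SX4](=[OX1])(=[OX1])
imine_reactive	[CX3]([#6])=[NX2][#6]
phosphonate_ester	[PX4](=[OX1])([OX2][#6])[OX2][#6]
quaternary_nitrogen	[NX4+]
disulfide	[SX2][SX2]
hemiacetal	[OX2H][CX4][OX2][#6]
cyanamide	[NX3][CX2]#[NX1]
four_membered_lactone	O=C1OCC1
beta_lactam	O=C1CCN1
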