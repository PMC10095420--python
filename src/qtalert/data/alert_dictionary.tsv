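# qtalert structural-alert dictionary, version 1.
# One named substructure class per row; patterns are SMARTS and are matched
# against molecules standardized by qtalert.chem_io (RDKit default aromaticity
# model, largest organic fragment kept, stereochemistry ignored).
# The names follow the fragment vocabulary used in QT-prolongation alert
# screening; the SMARTS are this package's documented definitions and may be
# replaced wholesale by users with their own dictionary file.
alert_id	name	class_group	smarts
1	tertiary amines	amines	[NX3;H0;!$([NX3][CX3]=[OX1,SX1,NX2]);!$(N=*)]([#6])([#6])[#6]
2	sp3-hybridized carbon atoms (2)	amines	[CX4;H2]([#6])[#6]
3	tertiary aliphatic amines	amines	[NX3;H0;!$([NX3][CX3]=[OX1,SX1,NX2])]([CX4])([CX4])[CX4]
4	16-tertiary amine	amines	[NX3;H0]([#6])([#6])[#6]
5	amines	amines	[NX3;!$([NX3][CX3]=[OX1,SX1,NX2]);!$(N=*);!$(N~[O])]
6	B3-tertiary amine	amines	[NX3;H0]([CX4])([CX4])[#6]
7	nitrogen atoms (1)	amines	[#7X3;H0;!$([#7]~[O])]
8	36-CH2N	amines	[CX4;H2][NX3]
9	ethers	ethers	[OX2;!$(O[CX3]=[OX1,SX1,NX2])]([#6])[#6]
10	sp3-hybridized carbon atoms (6)	ethers	[CX4]([#6])([#6])[#6]
11	13-ether	ethers	[CX4][OX2][CX4]
12	alkylarylethers	ethers	[CX4][OX2]c
13	arenes	aromatic compounds	c1ccccc1
14	11-AC(3-Aromatic carbon)	aromatic compounds	[cX3;H0]
15	aryl halide	aromatic compounds	c[F,Cl,Br,I]
16	4-aromatic carbon-alkane	aromatic compounds	c[CX4]
17	aromatichalogen	aromatic compounds	a[F,Cl,Br,I]
18	10-ACH (3-aromatic carbon)	aromatic compounds	[cX3;H1]
19	base	others	[$([NX3;!$([NX3][CX3]=[OX1,SX1,NX2]);!$(N=*);!$(N~[O]);!$(Nc)]),$([nX2;H0])]
20	six-membered heterocycles with one heteroatom (LS)	others	[!#6;!#1;r6]1[#6][#6][#6][#6][#6]1
21	2-CH2 (1-Alkane group)	others	[CX4;H2]
22	halogen derivatives	others	[#6][F,Cl,Br,I]
23	halogens	others	[F,Cl,Br,I]
24	NUC	others	[$([NX3;!$([NX3][CX3]=[OX1,SX1,NX2])]),$([OX2;H1]),$([SX2;H1])]
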