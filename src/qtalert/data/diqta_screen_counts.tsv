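# Reference per-alert cohort counts from the DIQTA structural-alert screen:
# number of QT-prolonging drugs (of 144) and no-DIQT-concern drugs (of 95)
# carrying each retained alert. Used to rebuild screen rows without access
# to the underlying structures.
alert_id	class_group	name	n_pos	n_neg
1	amines	tertiary amines	88	12
2	amines	sp3-hybridized carbon atoms (2)	117	36
3	amines	tertiary aliphatic amines	76	9
4	amines	16-tertiary amine	91	19
5	amines	amines	119	38
6	amines	B3-tertiary amine	76	10
7	amines	nitrogen atoms (1)	78	12
8	amines	36-CH2N	65	14
9	ethers	ethers	68	17
10	ethers	sp3-hybridized carbon atoms (6)	86	32
11	ethers	13-ether	65	20
12	ethers	alkylarylethers	49	11
13	aromatic compounds	arenes	127	56
14	aromatic compounds	11-AC(3-Aromatic carbon)	119	55
15	aromatic compounds	aryl halide	54	13
16	aromatic compounds	4-aromatic carbon-alkane	81	31
17	aromatic compounds	aromatichalogen	53	13
18	aromatic compounds	10-ACH (3-aromatic carbon)	129	65
19	others	base	126	49
20	others	six-membered heterocycles with one heteroatom (LS)	69	21
21	others	2-CH2 (1-Alkane group)	130	63
22	others	halogen derivatives	66	22
23	others	halogens	66	22
24	others	NUC	91	40
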