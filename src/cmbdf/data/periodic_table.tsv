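# symbol	Z	period	group (IUPAC 1-18)
H	1	1	1
He	2	1	18
Li	3	2	1
Be	4	2	2
B	5	2	13
C	6	2	14
N	7	2	15
O	8	2	16
F	9	2	17
Ne	10	2	18
Na	11	3	1
Mg	12	3	2
Al	13	3	13
Si	14	3	14
P	15	3	15
S	16	3	16
Cl	17	3	17
Ar	18	3	18
K	19	4	1
Ca	20	4	2
Sc	21	4	3
Ti	22	4	4
V	23	4	5
Cr	24	4	6
Mn	25	4	7
Fe	26	4	8
Co	27	4	9
Ni	28	4	10
Cu	29	4	11
Zn	30	4	12
Ga	31	4	13
Ge	32	4	14
As	33	4	15
Se	34	4	16
Br	35	4	17
Kr	36	4	18
Rb	37	5	1
Sr	38	5	2
Y	39	5	3
Zr	40	5	4
Nb	41	5	5
Mo	42	5	6
Tc	43	5	7
Ru	44	5	8
Rh	45	5	9
Pd	46	5	10
Ag	47	5	11
Cd	48	5	12
In	49	5	13
Sn	50	5	14
Sb	51	5	15
Te	52	5	16
I	53	5	17
Xe	54	5	18
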