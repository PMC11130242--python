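#priority	code	element	smarts
# KEGG atom-type rule table, evaluated per atom in ascending priority order;
# the typed atom is the first atom of each SMARTS pattern.  Codes follow the
# published KEGG atom-type nomenclature (C8x = aromatic CH, C8y = substituted
# aromatic C, C6a = carboxyl C, O1a = hydroxyl O, ...).  Formal charge is NOT
# part of the code: charged atoms receive the code of their neutral
# environment and charge is tracked separately.
10	C6a	C	[CX3](=[OX1])[OX2H1,OX1-]
20	C7x	C	[CX3;R](=[OX1])[OX2H0]
30	C7a	C	[CX3](=[OX1])[OX2H0]
40	C5a	C	[CX3](=[OX1])[NX3]
50	C4a	C	[CX3H1]=[OX1]
60	C5x	C	[CX3;R]=[OX1]
70	C5a	C	[CX3]=[OX1]
80	C8x	C	[cH]
90	C8y	C	[c;H0]
100	C3b	C	[CX2;H0]#*
105	C3b	C	[CX2](=*)=*
110	C3a	C	[CX2H1]#*
120	C2x	C	[CX3H1;R]=*
130	C2y	C	[CX3H0;R]=*
140	C2a	C	[CX3H2]=*
150	C2b	C	[CX3H1]=*
160	C2c	C	[CX3H0]=*
170	C1x	C	[CX4H2;R]
180	C1y	C	[CX4H1;R]
190	C1z	C	[CX4H0;R]
200	C1a	C	[CX4H3]
210	C1b	C	[CX4H2]
220	C1c	C	[CX4H1]
230	C1d	C	[CX4H0]
240	C0	C	[CX4H4]
300	N3a	N	[NX1]#*
310	N5x	N	[n;X2]
320	N4x	N	[nH]
330	N4y	N	[n;X3;H0]
340	N2x	N	[NX2;R]=*
350	N2a	N	[NX2H1]=*
360	N2b	N	[NX2H0]=*
370	N0	N	[NX3H3]
380	N1x	N	[NX3H1;R]
390	N1y	N	[NX3H0;R]
400	N1a	N	[NX3H2]
410	N1b	N	[NX3H1]
420	N1c	N	[NX3H0]
430	N1d	N	[NX4]
500	O6a	O	[OX2H1][CX3]=[OX1]
510	O6a	O	[OX1-][CX3]=[OX1]
520	O6a	O	[OX1]=[CX3][OX2H1,OX1-]
530	O7x	O	[OX2H0;R][CX3]=[OX1]
540	O7a	O	[OX2H0][CX3]=[OX1]
550	O7a	O	[OX1]=[CX3][OX2H0]
560	O4a	O	[OX1]=[CX3H1]
570	O5x	O	[OX1]=[CX3;R]
580	O5a	O	[OX1]=[CX3]
590	O3a	O	[OX1]=[P,S]
600	O2b	O	[OX2H0][P]
610	O1c	O	[OX2H1][P]
620	O0	O	[OX2H2]
630	O1a	O	[OX2H1]
640	O1a	O	[OX1-]
650	O2x	O	[OX2H0;R]
660	O2a	O	[OX2H0]
700	S1a	S	[SX2H1]
710	S2x	S	[SX2H0;R]
720	S2a	S	[SX2H0]
730	S3a	S	[SX3]
740	S4a	S	[SX4]
800	P1a	P	[PX4]
810	P1b	P	[PX3]
900	F0	F	[F]
910	Cl0	Cl	[Cl]
920	Br0	Br	[Br]
930	I0	I	[I]
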