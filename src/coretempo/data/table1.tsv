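otu_id	phylum	type_strain	subject_1	subject_2	subject_3
2	Actinobacteria	Bifidobacterium adolescentis (100)	8.67±7.15 (100)	5.80±11.47 (88)	ND
5	Actinobacteria	Bifidobacterium adolescentis (96)	3.91±3.32 (100)	0.04±0.08 (27)	ND
358	Actinobacteria	Bifidobacterium pseudocatenulatum (99)	0.13±0.26 (42)	3.68±2.89 (100)	ND
11	Actinobacteria	Bifidobacterium longum (99)	1.19±0.92 (97)	0.44±0.47 (94)	0.28±0.42 (84)
928	Actinobacteria	Adlercreutzia equilifaciens (98)	ND	ND	0.39±0.51 (91)
40	Actinobacteria	Collinsella aerofaciens (98)	0.50±0.43 (97)	3.15±5.20 (100)	0.34±0.57 (47)
16/548	Bacteroidetes	Bacteroides thetaiotaomicrom (98)	1.78±0.81 (100)	0.40±0.31 (91)	0.09±0.14 (50)
20	Bacteroidetes	Bacteroides xylanisolvens (99)	4.39±4.49 (100)	0.32±0.38 (79)	ND
273	Bacteroidetes	Bacteroides intestinalis (98)	ND	0.81±0.61 (97)	ND
18	Bacteroidetes	Bacteroides uniformis (99)	3.37±1.78 (100)	1.29±1.14 (100)	0.57±0.70 (66)
1	Bacteroidetes	Bacteroides vulgatus (99)	8.98±5.09 (100)	5.15±3.98 (100)	7.11±8.24 (97)
512	Bacteroidetes	Bacteroides dorei (100)	0.10±0.22 (21)	0.56±0.38 (97)	0.80±1.19 (75)
269	Bacteroidetes	Bacteroides ovatus (97)	0.15±0.20 (67)	0.25±0.33 (82)	0.06±0.09 (50)
118	Bacteroidetes	Odoribacter splanchnicus (99)	0.17±0.14 (88)	0.36±0.33 (82)	0.08±0.15 (44)
226	Bacteroidetes	Parabacteroides distasonis (97)	0.35±0.61 (85)	0.14±0.18 (70)	1.43±2.88 (85)
513	Bacteroidetes	Alistipes shahii (100)	0.03±0.07 (21)	0.22±0.18 (91)	0.14±0.18 (53)
235	Bacteroidetes	Alistipes finegoldii (100)	0.42±0.49 (88)	ND	0.07±0.10 (50)
19	Bacteroidetes	Bacteroides putredinis (99)	2.14±1.16 (100)	1.62±1.33 (100)	5.29±3.80 (100)
479	Bacteroidetes	Bacteroides intestinihominis (99)	0.14±0.30 (24)	0.56±0.47 (97)	ND
4400/4617	Bacteroidetes	Bacteroidales	ND	2.83±2.92 (91)	ND
114	Firmicutes	Flavonifactor	0.11±0.13 (70)	0.04±0.05 (52)	0.40±0.35 (91)
12556	Firmicutes	Ruminococcaceae bacterium D16 (97)	ND	ND	0.44±0.39 (91)
359	Firmicutes	Oscillibacter spp.	0.09±0.09 (67)	0.16±0.15 (82)	0.15±0.16 (66)
5715	Firmicutes	Ruminococcaceae	0.02±0.04 (15)	0.03±0.07 (27)	0.50±0.54 (94)
32	Firmicutes	Butyricicoccus spp.	0.21±0.19 (91)	0.03±0.06 (39)	ND
2817	Firmicutes	Clostridiales	ND	0.55±0.74 (85)	ND
5522	Firmicutes	Ruminococcus bromii (99)	0.80±1.92 (21)	1.02±3.95 (18)	4.90±5.32 (100)
4705	Firmicutes	Ruminococcaceae	0.09±0.25 (21)	0.41±0.46 (85)	0.16±0.28 (50)
4256	Firmicutes	Ruminococcaceae	1.48±3.07 (45)	4.56±3.73 (100)	3.74±3.29 (100)
161/4277	Firmicutes	Clostridiales	0.12±0.12 (85)	0.22±0.18 (88)	ND
2308	Firmicutes	Clostridiales	0.14±0.24 (58)	1.33±0.90 (94)	ND
29	Firmicutes	Faecalibacterium prausnitzii SL3/3 (99)	1.36±1.17 (100)	2.01±1.30 (100)	3.05±2.22 (100)
35	Firmicutes	Faecalibacterium prausnitzii KLE-1255 (98)	0.85±0.77 (97)	0.03±0.04 (45)	0.03±0.07 (22)
6	Firmicutes	Faecalibacterium prausnitzii KLE-1255 (97)	2.72±2.20 (100)	1.51±1.46 (100)	1.60±1.33 (97)
17	Firmicutes	Faecalibacterium prausnitzii A2-165 (97)	4.68±2.23 (100)	3.56±1.67 (100)	2.65±3.10 (100)
31/136	Firmicutes	Dialister spp.	0.41±0.29 (91)	ND	ND
288	Firmicutes	Dialister invisus (100)	ND	ND	3.07±2.68 (91)
66	Firmicutes	Streptococcus salivarius (98)	0.73±0.66 (94)	0.27±0.45 (64)	0.64±0.87 (94)
21	Firmicutes	Streptococcus parasanguinis (99)	0.22±0.36 (88)	0.02±0.05 (24)	0.04±0.07 (34)
22	Firmicutes	Clostridium spiroforme (99)	0.18±0.20 (73)	ND	0.17±0.20 (81)
53	Firmicutes	Erysipelotrichaceae	0.43±0.33 (88)	ND	ND
9864	Firmicutes	Erysipelotrichaceae	ND	2.45±1.97 (100)	1.21±1.35 (100)
9902	Firmicutes	Erysipelotrichaceae	ND	0.14±0.11 (81)	ND
48/23/365/27/262/10	Firmicutes	Ruminococcus obeum (98)	3.13±1.56 (100)	7.46±3.74 (100)	5.73±3.53 (100)
3/7	Firmicutes	Blautia wexlerae (99)	6.62±5.24 (100)	1.87±1.95 (100)	6.02±4.24 (100)
361	Firmicutes	Lachnospiraceae	0.12±0.12 (82)	0.11±0.11 (70)	0.12±0.15 (69)
9873	Firmicutes	Dorea formicigenerans (97)	ND	0.05±0.07 (48)	0.42±0.49 (97)
51	Firmicutes	Dorea formicigenerans (99)	0.79±0.43 (100)	0.62±0.49 (100)	2.62±3.07 (100)
76/4328	Firmicutes	Dorea spp.	0.23±0.21 (85)	0.51±0.25 (100)	1.04±0.81 (100)
78	Firmicutes	Ruminococcus torques (97)	0.04±0.13 (27)	0.04±0.13 (27)	0.89±1.20 (91)
9942	Firmicutes	Ruminococcus torques (99)	ND	0.19±0.17 (88)	0.08±0.13 (50)
24/511/403	Firmicutes	Coprococcus comes (98)	0.57±0.51 (97)	3.01±2.01 (100)	3.86±1.99 (100)
12	Firmicutes	Ruminococcus gnavus (99)	0.36±0.29 (94)	0.07±0.19 (36)	0.14±0.15 (72)
26	Firmicutes	Eubacterium ramulus (99)	0.64±0.34 (97)	0.28±0.29 (91)	0.82±1.04 (91)
42	Firmicutes	Roseburia inulinivorans (100)	0.26±0.27 (91)	0.17±0.37 (55)	1.44±1.55 (91)
120	Firmicutes	Lachnospiraceae	0.36±0.25 (97)	0.04±0.05 (52)	0.09±0.11 (53)
14/1107	Firmicutes	Lachnospiraceae	2.53±1.64 (100)	4.61±2.32 (100)	1.38±1.15 (94)
63/370	Firmicutes	Clostridium clostridiiformes (96)	1.24±1.58 (100)	4.42±3.18 (100)	2.34±2.70 (100)
9865	Firmicutes	Coprococcus euctatus (99)	ND	3.79±2.91 (100)	ND
3927	Firmicutes	Coprococcus catus GD/7 (98)	0.08±0.10 (48)	0.15±0.13 (91)	ND
30	Firmicutes	Lachnospiraceae	0.21±0.27 (82)	0.03±0.11 (18)	0.01±0.03 (25)
9	Firmicutes	Lachnospiraceae	0.83±0.93 (82)	0.04±0.08 (36)	0.13±0.15 (56)
4264	Firmicutes	Eubacterium eligens (100)	0.06±0.16 (41)	0.30±0.25 (91)	0.12±0.11 (63)
4	Firmicutes	Eubacterium rectale (97)	6.49±5.44 (100)	9.07±9.32 (100)	4.06±3.53 (100)
4262/2326	Firmicutes	Roseburia intestinalis (98)	2.26±2.72 (55)	0.56±1.36 (27)	4.26±3.40 (100)
45	Firmicutes	Lachnospiraceae	1.03±0.67 (100)	0.29±0.36 (70)	0.19±0.37 (69)
15	Firmicutes	Clostridium sp. SS2/1 (98)	1.50±1.19 (100)	0.24±0.26 (85)	0.80±1.09 (100)
5348	Firmicutes	Eubacterium ventriosum (97)	0.06±0.16 (18)	0.26±0.22 (79)	0.41±0.48 (88)
36	Verrucomicrobia	Akkermansia muciniphila (98)	4.70±7.15 (67)	0.30±0.94 (36)	5.82±8.92 (100)
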