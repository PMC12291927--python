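# Pig-like mitogenome annotation skeleton, 16,581 bp circle.
# 37 genes (13 PCG, 22 tRNA, 2 rRNA) plus the origin-spanning control region.
# Coordinates are 1-based inclusive; the control region wraps (start > stop).
name	start	stop	strand	class
trnF	345	414	+	tRNA
rrnS	415	1376	+	rRNA
trnV	1376	1443	+	tRNA
rrnL	1442	3013	+	rRNA
trnL2	3014	3088	+	tRNA
nad1	3091	4045	+	PCG
trnI	4046	4114	+	tRNA
trnQ	4112	4184	-	tRNA
trnM	4186	4255	+	tRNA
nad2	4256	5297	+	PCG
trnW	5298	5365	+	tRNA
trnA	5372	5439	-	tRNA
trnN	5441	5515	-	tRNA
trnC	5548	5613	-	tRNA
trnY	5613	5678	-	tRNA
cox1	5680	7224	+	PCG
trnS2	7228	7296	-	tRNA
trnD	7304	7371	+	tRNA
cox2	7372	8059	+	PCG
trnK	8060	8126	+	tRNA
atp8	8128	8331	+	PCG
atp6	8289	8969	+	PCG
cox3	8969	9752	+	PCG
trnG	9753	9821	+	tRNA
nad3	9822	10168	+	PCG
trnR	10169	10237	+	tRNA
nad4l	10238	10534	+	PCG
nad4	10528	11905	+	PCG
trnH	11906	11974	+	tRNA
trnS1	11975	12033	+	tRNA
trnL1	12034	12103	+	tRNA
nad5	12104	13924	+	PCG
nad6	13908	14435	-	PCG
trnE	14436	14504	-	tRNA
cob	14509	15648	+	PCG
trnT	15649	15716	+	tRNA
trnP	15716	15780	-	tRNA
control	15781	344	+	control
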