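# Annotation table of the Liriomyza chinensis mitochondrial genome
# (GenBank MG252777), transcribed from the published annotation.
# Coordinates are 1-based inclusive; strand F/R = majority/minority (J/N).
#genome_length=16175
name	start	end	strand	class	codons
trnI	1	67	F	tRNA	.
trnQ	71	139	R	tRNA	.
trnM	139	207	F	tRNA	.
ND2	208	1228	F	PCG	ATT/T
trnW	1229	1295	F	tRNA	.
trnC	1288	1351	R	tRNA	.
trnY	1353	1416	R	tRNA	.
COI	1414	2953	F	PCG	ATCA/TAA
trnL2	2955	3020	F	tRNA	.
COII	3024	3713	F	PCG	ATG/TAA
trnK	3715	3785	F	tRNA	.
trnD	3788	3854	F	tRNA	.
ATP8	3855	4010	F	PCG	ATT/TAA
ATP6	4004	4678	F	PCG	ATG/TAA
COIII	4678	5469	F	PCG	ATG/TAA
trnG	5475	5539	F	tRNA	.
ND3	5540	5893	F	PCG	ATT/TAA
trnA	5896	5959	F	tRNA	.
trnR	5960	6022	F	tRNA	.
trnN	6029	6094	F	tRNA	.
trnS1	6095	6161	F	tRNA	.
trnE	6162	6228	F	tRNA	.
trnF	6248	6314	R	tRNA	.
ND5	6315	8028	R	PCG	ATT/T
trnH	8044	8109	R	tRNA	.
ND4	8110	9448	R	PCG	ATG/T
ND4L	9449	9738	R	PCG	ATG/TA
trnT	9741	9804	F	tRNA	.
trnP	9805	9870	R	tRNA	.
ND6	9873	10397	F	PCG	ATT/TAA
CYTB	10399	11533	F	PCG	ATG/T
trnS2	11534	11599	F	tRNA	.
ND1	11602	12564	R	PCG	GTG/TAG
trnL1	12566	12629	R	tRNA	.
rrnL	12630	13952	R	rRNA	.
trnV	13952	14023	R	tRNA	.
rrnS	14024	14808	R	rRNA	.
control_region	14809	16175	F	control_region	.
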