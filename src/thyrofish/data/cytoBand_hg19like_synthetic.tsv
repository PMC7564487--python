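chr1	0	2300000	p36.33	gneg
chr1	2300000	5400000	p36.32	gpos25
chr1	5400000	7200000	p36.31	gneg
chr1	7200000	9200000	p36.23	gpos25
chr1	9200000	12700000	p36.22	gneg
chr1	12700000	16200000	p36.21	gpos50
chr1	16200000	20400000	p36.13	gneg
chr1	20400000	23900000	p36.12	gpos25
chr1	23900000	28000000	p36.11	gneg
chr1	28000000	30200000	p35.3	gpos25
chr1	30200000	32400000	p35.2	gneg
chr1	32400000	34600000	p35.1	gpos25
chr1	34600000	40100000	p34.3	gneg
chr1	40100000	44100000	p34.2	gpos25
chr1	44100000	46800000	p34.1	gneg
chr1	46800000	50700000	p33	gpos75
chr1	50700000	56100000	p32.3	gneg
chr1	56100000	59000000	p32.2	gpos50
chr1	59000000	61300000	p32.1	gneg
chr1	61300000	68900000	p31.3	gpos50
chr1	68900000	69700000	p31.2	gneg
chr1	69700000	84900000	p31.1	gpos100
chr1	84900000	88400000	p22.3	gneg
chr1	88400000	92000000	p22.2	gpos50
chr1	92000000	94700000	p22.1	gneg
chr1	94700000	99700000	p21.3	gpos75
chr1	99700000	102200000	p21.2	gneg
chr1	102200000	107200000	p21.1	gpos100
chr1	107200000	111800000	p13.3	gneg
chr1	111800000	116100000	p13.2	gpos50
chr1	116100000	117800000	p13.1	gneg
chr1	117800000	120600000	p12	gpos50
chr1	120600000	121500000	p11.2	gneg
chr1	121500000	125000000	p11.1	acen
chr1	125000000	128900000	q11	acen
chr1	128900000	142600000	q12	gvar
chr1	142600000	155000000	q21	gneg
chr1	155000000	156600000	q22	gpos50
chr1	156600000	160000000	q23	gneg
chr1	160000000	165500000	q24	gpos50
chr1	165500000	173000000	q25	gneg
chr1	173000000	185800000	q31	gpos100
chr1	185800000	198700000	q32	gneg
chr1	198700000	207200000	q41	gpos75
chr1	207200000	224100000	q42	gneg
chr1	224100000	234600000	q43	gpos75
chr1	234600000	249250621	q44	gneg
chr2	0	93300000	p11	gneg
chr2	93300000	243199373	q11	gneg
chr3	0	91000000	p11	gneg
chr3	91000000	198022430	q11	gneg
chr4	0	50400000	p11	gneg
chr4	50400000	191154276	q11	gneg
chr5	0	48400000	p11	gneg
chr5	48400000	180915260	q11	gneg
chr6	0	61000000	p11	gneg
chr6	61000000	171115067	q11	gneg
chr7	0	59900000	p11	gneg
chr7	59900000	159138663	q11	gneg
chr8	0	45600000	p11	gneg
chr8	45600000	146364022	q11	gneg
chr9	0	49000000	p11	gneg
chr9	49000000	141213431	q11	gneg
chr10	0	40200000	p11	gneg
chr10	40200000	135534747	q11	gneg
chr11	0	53700000	p11	gneg
chr11	53700000	135006516	q11	gneg
chr12	0	35800000	p11	gneg
chr12	35800000	133851895	q11	gneg
chr13	0	17900000	p11	gneg
chr13	17900000	115169878	q11	gneg
chr14	0	17600000	p11	gneg
chr14	17600000	107349540	q11	gneg
chr15	0	19000000	p11	gneg
chr15	19000000	102531392	q11	gneg
chr16	0	36600000	p11	gneg
chr16	36600000	90354753	q11	gneg
chr17	0	24000000	p11	gneg
chr17	24000000	81195210	q11	gneg
chr18	0	17200000	p11	gneg
chr18	17200000	78077248	q11	gneg
chr19	0	26500000	p11	gneg
chr19	26500000	59128983	q11	gneg
chr20	0	27500000	p11	gneg
chr20	27500000	63025520	q11	gneg
chr21	0	13200000	p11	gneg
chr21	13200000	48129895	q11	gneg
chr22	0	3800000	p13	gvar
chr22	3800000	8300000	p12	stalk
chr22	8300000	12200000	p11.2	gvar
chr22	12200000	14700000	p11.1	acen
chr22	14700000	17900000	q11.1	acen
chr22	17900000	22200000	q11.21	gneg
chr22	22200000	23500000	q11.22	gpos25
chr22	23500000	25900000	q11.23	gneg
chr22	25900000	27500000	q12.1	gpos50
chr22	27500000	29600000	q12.2	gneg
chr22	29600000	32200000	q12.3	gpos50
chr22	32200000	40600000	q13.1	gneg
chr22	40600000	43800000	q13.2	gpos50
chr22	43800000	46200000	q13.31	gneg
chr22	46200000	48700000	q13.32	gpos50
chr22	48700000	51304566	q13.33	gneg
chrX	0	9500000	p22.3	gneg
chrX	9500000	17100000	p22.2	gpos50
chrX	17100000	24900000	p22.1	gneg
chrX	24900000	37600000	p21	gpos100
chrX	37600000	46400000	p11.4	gneg
chrX	46400000	49800000	p11.3	gpos75
chrX	49800000	58100000	p11.2	gneg
chrX	58100000	60600000	p11.1	acen
chrX	60600000	63000000	q11	acen
chrX	63000000	64600000	q12	gneg
chrX	64600000	76800000	q13	gpos50
chrX	76800000	89500000	q21	gpos100
chrX	89500000	99100000	q22	gneg
chrX	99100000	110400000	q23	gpos50
chrX	110400000	117400000	q24	gneg
chrX	117400000	125800000	q25	gpos100
chrX	125800000	134700000	q26	gneg
chrX	134700000	142100000	q27	gpos75
chrX	142100000	155270560	q28	gneg
chrY	0	2700000	p11.3	gneg
chrY	2700000	10400000	p11.2	gpos50
chrY	10400000	12500000	p11.1	acen
chrY	12500000	28800000	q11	acen
chrY	28800000	59373566	q12	gvar
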