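gene	chrom	pos	dominant_weight	secondary_weight
TET2	4	106157698	16.2	10.8
SF3B1	2	198267483	19.6	3.4
ASXL1	20	31022441	7.6	11.4
SRSF2	17	74732959	8.4	5.6
DNMT3A	2	25463289	7.7	3.3
TP53	17	7577538	5.3	1.7
RUNX1	21	36231771	3.8	3.7
U2AF1	21	44524456	5.3	1.7
ZRSR2	X	15822837	3.0	3.0
STAG2	X	123195650	3.0	3.0
EZH2	7	148508727	2.8	2.7
BCOR	X	39921444	2.5	2.5
CBL	11	119148930	1.1	2.4
IDH2	15	90631934	2.3	1.2
JAK2	9	5073770	1.1	1.9
NRAS	1	115258747	1.0	1.5
ETV6	12	11803061	1.3	1.2
KRAS	12	25398284	0.6	1.4
IDH1	2	209113112	0.8	0.7
FLT3	13	28608258	0.4	0.6
GNB1	1	1747228	0.5	0.5
BCORL1	X	129146538	0.5	0.5
PHF6	X	133547943	0.5	0.5
GATA2	3	128204951	0.4	0.4
NF1	17	29553485	0.4	0.4
PTPN11	12	112888163	0.3	0.5
SETBP1	18	42531907	0.3	0.5
CUX1	7	101459286	0.4	0.4
NPM1	5	170837543	0.3	0.3
DDX41	5	176939243	0.3	0.2
WT1	11	32417945	0.2	0.3
CEBPA	19	33792244	0.2	0.2
MPL	1	43814978	0.2	0.2
CALR	19	13054527	0.2	0.2
CSF3R	1	36933434	0.2	0.2
RAD21	8	117864842	0.2	0.3
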