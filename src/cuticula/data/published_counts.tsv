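species	family	Genome	Ep	PG	He	Mg	FA	MA	CA
A_pernyi	CPR_RR-1	52	42	41	28	22	15	15	NA
A_pernyi	CPR_RR-2	92	33	29	11	6	34	39	NA
A_pernyi	CPR_RR-3	2	2	2	2	2	1	1	NA
A_pernyi	CPR_RR-NC	11	8	6	7	2	2	3	NA
A_pernyi	CPAP1	12	8	4	7	1	6	9	NA
A_pernyi	CPAP3	6	6	6	4	5	3	3	NA
A_pernyi	CPCFC	3	2	3	2	1	2	3	NA
A_pernyi	CPLCP	2	2	1	0	0	1	1	NA
A_pernyi	CPLCA	0	0	0	0	0	0	0	NA
A_pernyi	CPF	1	1	1	1	1	1	1	NA
A_pernyi	CPFL	2	2	1	1	0	1	1	NA
A_pernyi	CPT	4	4	4	1	3	2	3	NA
A_pernyi	CPG	8	4	3	2	1	3	2	NA
A_pernyi	CPH	22	18	17	11	11	15	17	NA
A_pernyi	18aa	0	0	0	0	0	0	0	NA
B_mori	CPR_RR-1	51	36	44	NA	NA	NA	NA	44
B_mori	CPR_RR-2	84	11	60	NA	NA	NA	NA	63
B_mori	CPR_RR-3	4	3	4	NA	NA	NA	NA	4
B_mori	CPR_RR-NC	6	3	5	NA	NA	NA	NA	5
B_mori	CPAP1	14	9	14	NA	NA	NA	NA	13
B_mori	CPAP3	9	8	7	NA	NA	NA	NA	7
B_mori	CPCFC	1	1	1	NA	NA	NA	NA	1
B_mori	CPLCP	6	5	6	NA	NA	NA	NA	6
B_mori	CPLCA	2	2	2	NA	NA	NA	NA	2
B_mori	CPF	1	0	1	NA	NA	NA	NA	1
B_mori	CPFL	4	1	4	NA	NA	NA	NA	4
B_mori	CPT	4	2	4	NA	NA	NA	NA	4
B_mori	CPG	22	14	22	NA	NA	NA	NA	22
B_mori	CPH	23	15	21	NA	NA	NA	NA	22
B_mori	18aa	5	5	2	NA	NA	NA	NA	5
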