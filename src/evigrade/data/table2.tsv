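gene	variant	cancer_type	year	model	ethnicity	or_point	ci_low	ci_high	egger_p	het_p	i_squared	n_studies	n_total	n_cases	n_controls	test_count	calc_low	calc_high	maf	gwas_replicated	bias_override	source	significant	primary	pub_grade	pub_level	pub_power	pub_fprp	pub_evidence
PLCE1	rs3765524	EC	2010	additive	Asian	1.35	1.22	1.49	Na	Na	Na	Na	5417	2115	3302	Na	Na	Na	0.207	true	Na	gwas	true	true	Na	Na	0.982	0.000	Na
PLCE1	rs2274223	EC	2010	additive	Asian	1.43	1.37	1.49	Na	Na	Na	Na	5417	2115	3302	Na	Na	Na	Na	true	Na	gwas	true	true	Na	Na	0.842	0.000	Na
C20orf54	rs13042395	EC	2010	additive	Asian	0.86	0.82	0.90	Na	Na	Na	Na	22336	9053	13283	Na	Na	Na	Na	true	Na	gwas	true	true	Na	Na	1.000	0.000	Na
HEATR	rs4785204	EC	2012	additive	Asian	1.24	1.18	1.29	Na	Na	Na	Na	20787	10123	10664	Na	Na	Na	0.26	true	Na	gwas	true	true	Na	Na	1.000	0.000	Na
HEATR	rs7206735	EC	2012	additive	Asian	1.20	1.15	1.26	Na	Na	Na	Na	20787	10123	10664	Na	Na	Na	0.28	true	Na	gwas	true	true	Na	Na	1.000	0.000	Na
HAP1	rs6503659	EC	2012	additive	Asian	1.27	1.20	1.34	Na	Na	Na	Na	20787	10123	10664	Na	Na	Na	0.13	true	Na	gwas	true	true	Na	Na	1.000	0.000	Na
XBP1	rs2239815	EC	2012	additive	Asian	1.18	1.13	1.23	Na	Na	Na	Na	20787	10123	10664	Na	Na	Na	0.37	true	Na	gwas	true	true	Na	Na	1.000	0.000	Na
ST6GAL1	rs2239612	EC	2012	additive	Asian	1.21	1.15	1.27	Na	Na	Na	Na	20787	10123	10664	Na	Na	Na	0.19	true	Na	gwas	true	true	Na	Na	1.000	0.000	Na
SMG6	rs17761864	EC	2012	additive	Asian	1.21	1.14	1.28	Na	Na	Na	Na	20787	10123	10664	Na	Na	Na	0.14	true	Na	gwas	true	true	Na	Na	1.000	0.000	Na
PTPN2	rs2847281	EC	2012	additive	Asian	1.20	1.14	1.26	Na	Na	Na	Na	20787	10123	10664	Na	Na	Na	0.16	true	Na	gwas	true	true	Na	Na	1.000	0.000	Na
CHEK2	rs4800983	EC	2012	additive	Asian	1.27	1.21	1.34	Na	Na	Na	Na	20787	10123	10664	Na	Na	Na	0.20	true	Na	gwas	true	true	Na	Na	1.000	0.000	Na
CHEK2	rs1033667	EC	2012	additive	Asian	1.25	1.19	1.30	Na	Na	Na	Na	20787	10123	10664	Na	Na	Na	0.25	true	Na	gwas	true	true	Na	Na	1.000	0.000	Na
KLF5	rs1924966	EC	2015	additive	Asian	0.84	0.80	0.89	Na	Na	Na	Na	12356	6177	6179	Na	Na	Na	0.40	true	Na	gwas	true	true	Na	Na	1.000	0.000	Na
KLF5	rs115797771	EC	2015	additive	Asian	0.69	0.62	0.78	Na	Na	Na	Na	12356	6177	6179	Na	Na	Na	0.06	true	Na	gwas	true	true	Na	Na	0.709	0.000	Na
KLF5	rs58090485	EC	2015	additive	Asian	0.69	0.62	0.77	Na	Na	Na	Na	12356	6177	6179	Na	Na	Na	0.07	true	Na	gwas	true	true	Na	Na	0.731	0.000	Na
TMEM173	rs7447927	EC	2014	additive	Asian	0.85	0.82	0.88	Na	Na	Na	Na	30286	15667	14619	Na	Na	Na	Na	true	Na	gwas	true	true	Na	Na	1.000	0.000	Na
ATP1B2	rs1642764	EC	2014	additive	Asian	0.88	0.85	0.91	Na	Na	Na	Na	30281	15474	14807	Na	Na	Na	Na	true	Na	gwas	true	true	Na	Na	1.000	0.000	Na
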