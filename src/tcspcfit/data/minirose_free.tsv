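# Site-specific fluorescence parameters of 2-AP-labeled MiniROSE RNA, free
# (ribosome-unbound) state. site: 2-AP position from the 5' end.
# tau_m: mean fluorescence lifetime (ns); phi_m: mean rotational correlation
# time (ns); kq: bimolecular quenching constant (1e9 /M/s).
site	parameter	condition	value	error
6	tau_m	20C	1.06	0.05
10	tau_m	20C	1.86	0.05
24	tau_m	20C	1.69	0.08
27	tau_m	20C	1.34	0.06
35	tau_m	20C	1.82	0.01
38	tau_m	20C	0.91	0.05
41	tau_m	20C	1.22	0.05
6	tau_m	45C	0.60	0.06
10	tau_m	45C	1.88	0.04
24	tau_m	45C	2.12	0.01
27	tau_m	45C	1.32	0.02
35	tau_m	45C	1.49	0.02
38	tau_m	45C	1.01	0.03
41	tau_m	45C	1.05	0.09
6	tau_m	45C+urea	1.30	0.04
10	tau_m	45C+urea	1.65	0.05
24	tau_m	45C+urea	1.67	0.03
27	tau_m	45C+urea	1.72	0.06
35	tau_m	45C+urea	2.22	0.07
38	tau_m	45C+urea	1.90	0.03
41	tau_m	45C+urea	2.22	0.05
6	phi_m	20C	2.82	0.10
10	phi_m	20C	3.46	0.08
24	phi_m	20C	2.86	0.21
27	phi_m	20C	1.54	0.05
35	phi_m	20C	1.58	0.08
38	phi_m	20C	1.85	0.11
41	phi_m	20C	1.09	0.10
6	phi_m	45C	1.41	0.09
10	phi_m	45C	0.87	0.03
24	phi_m	45C	0.81	0.03
27	phi_m	45C	0.40	0.02
35	phi_m	45C	1.27	0.05
38	phi_m	45C	0.51	0.02
41	phi_m	45C	0.25	0.02
6	phi_m	45C+urea	0.98	0.03
10	phi_m	45C+urea	0.83	0.05
24	phi_m	45C+urea	0.63	0.03
27	phi_m	45C+urea	0.69	0.04
35	phi_m	45C+urea	0.65	0.02
38	phi_m	45C+urea	1.09	0.03
41	phi_m	45C+urea	0.62	0.04
6	kq	20C	4.7	0.3
10	kq	20C	7.0	0.4
24	kq	20C	20.4	0.9
27	kq	20C	20.3	0.5
35	kq	20C	4.2	0.2
38	kq	20C	8.9	0.4
41	kq	20C	6.8	0.3
6	kq	45C	7.5	0.4
10	kq	45C	6.8	0.3
24	kq	45C	9.7	0.2
27	kq	45C	12.6	0.4
35	kq	45C	5.0	0.3
38	kq	45C	10.7	0.5
41	kq	45C	5.5	0.4
6	kq	45C+urea	2.7	0.2
10	kq	45C+urea	2.3	0.1
24	kq	45C+urea	3.0	0.2
27	kq	45C+urea	2.9	0.2
35	kq	45C+urea	2.3	0.1
38	kq	45C+urea	2.7	0.2
41	kq	45C+urea	3.1	0.1
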