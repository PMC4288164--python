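# Site-specific fluorescence parameters of 2-AP-labeled MiniROSE RNA bound
# to ribosome. phi_m was computed with the long (>50 ns) rotational
# correlation time taken at the 50 ns reporting cap.
site	parameter	condition	value	error
6	tau_m	20C	1.36	0.04
10	tau_m	20C	2.00	0.07
24	tau_m	20C	1.03	0.05
27	tau_m	20C	1.10	0.05
35	tau_m	20C	1.31	0.10
38	tau_m	20C	1.95	0.03
41	tau_m	20C	1.75	0.06
6	tau_m	45C	1.04	0.03
10	tau_m	45C	1.88	0.08
24	tau_m	45C	1.66	0.04
27	tau_m	45C	1.53	0.05
35	tau_m	45C	1.47	0.05
38	tau_m	45C	1.72	0.03
41	tau_m	45C	1.65	0.04
6	phi_m	20C	28.5	1.5
10	phi_m	20C	28.8	1.1
24	phi_m	20C	31.4	1.3
27	phi_m	20C	24.3	0.9
35	phi_m	20C	19.0	1.3
38	phi_m	20C	15.6	1.4
41	phi_m	20C	25.4	1.2
6	phi_m	45C	15.6	0.9
10	phi_m	45C	14.8	1.0
24	phi_m	45C	9.7	0.8
27	phi_m	45C	13.7	1.1
35	phi_m	45C	15.3	0.6
38	phi_m	45C	22.8	1.3
41	phi_m	45C	8.7	0.3
6	kq	20C	3.8	0.2
10	kq	20C	2.7	0.1
24	kq	20C	4.4	0.2
27	kq	20C	8.9	0.3
35	kq	20C	5.7	0.2
38	kq	20C	3.1	0.2
41	kq	20C	3.0	0.1
6	kq	45C	5.2	0.3
10	kq	45C	3.3	0.2
24	kq	45C	5.9	0.5
27	kq	45C	4.8	0.2
35	kq	45C	4.2	0.3
38	kq	45C	5.9	0.4
41	kq	45C	4.6	0.3
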