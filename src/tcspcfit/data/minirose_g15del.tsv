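# Mean fluorescence lifetimes (ns) of 2-AP-labeled MiniROSE RNA carrying
# the G15 deletion (the conserved-residue deletion that abolishes
# thermometer function), free and ribosome-bound. Only three 2-AP sites
# were measured in this construct.
site	parameter	condition	value	error
24	tau_m	20C	0.38	0.02
27	tau_m	20C	0.31	0.02
35	tau_m	20C	0.30	0.01
24	tau_m	20C+ribosome	0.87	0.04
27	tau_m	20C+ribosome	0.65	0.03
35	tau_m	20C+ribosome	0.47	0.03
24	tau_m	45C	0.48	0.03
27	tau_m	45C	0.39	0.02
35	tau_m	45C	0.28	0.01
24	tau_m	45C+ribosome	0.57	0.02
27	tau_m	45C+ribosome	0.75	0.04
35	tau_m	45C+ribosome	0.41	0.02
24	tau_m	45C+urea	1.41	0.05
27	tau_m	45C+urea	1.12	0.04
35	tau_m	45C+urea	1.09	0.04
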