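gene	fold_change	p_adj
ANO1	0.48	6.1e-5
CACNA1C	0.56	1.8e-9
CACNA1D	0.54	3.3e-6
CACNA2D2	0.27	7.2e-7
CACNB3	1.48	2.8e-5
CLCC1	1.52	1.6e-8
CLCN3	1.39	5.7e-4
CLCN7	1.80	2.1e-12
CLIC3	0.17	6.6e-13
CLIC4	0.62	8.1e-7
CLIC5	0.06	3.3e-20
CLIC6	3.28	3.7e-8
KCNAB1	0.26	2.1e-12
KCNAB2	0.62	1.2e-5
KCNJ2	0.50	4.8e-5
KCNJ8	0.25	2.8e-15
KCNK1	2.32	5.1e-6
KCNK3	0.09	3.2e-20
KCNK5	4.77	1.5e-12
KCNMB4	0.24	4.3e-8
KCNQ3	2.69	1.4e-8
KCNT2	0.10	2.4e-18
MCOLN1	0.72	6.2e-5
MCOLN2	0.54	1.9e-5
MCOLN3	0.29	6.4e-9
PKD1	0.69	1.6e-7
PKD2	0.64	1.7e-5
SCN4B	0.13	1.5e-14
SCN7A	0.16	4.2e-10
SCNN1B	0.36	1.3e-6
SCNN1G	0.20	6.0e-10
TPCN1	0.76	7.8e-4
TRPC1	0.49	5.3e-8
TRPC6	0.31	4.6e-9
TRPM2	1.53	1.2e-5
TRPV2	0.34	1.2e-13
VDAC1	1.36	6.1e-5
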