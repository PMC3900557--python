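gene	fold_change	p_adj
CACNA1D	8.02	1.2e-8
CACNA2D1	0.37	9.1e-5
CACNA2D2	6.74	8.0e-5
CACNB3	2.35	3.4e-5
CLCC1	1.51	2.5e-5
CLCN7	1.38	6.2e-3
CLIC1	1.13	4.6e-2
CLIC4	0.54	6.0e-4
CLIC5	2.24	1.6e-3
CLIC6	5.10	1.0e-6
GLRB	1.90	1.9e-3
KCNJ2	0.77	5.9e-3
KCNJ8	1.67	2.2e-2
KCNK1	0.61	1.6e-2
KCNK17	2.56	1.7e-2
KCNK5	11.90	8.0e-17
KCNQ3	12.53	2.4e-11
MCOLN3	0.68	1.3e-3
P2RX4	1.64	1.9e-4
SCN7A	8.10	1.0e-6
SCNN1A	3.72	9.1e-5
SCNN1B	6.68	2.2e-7
SCNN1G	3.28	7.4e-4
TPCN1	2.61	4.0e-9
TRPC6	4.24	5.9e-3
TRPM7	0.54	1.1e-6
TRPV2	1.41	2.2e-2
VDAC1	0.79	3.0e-3
VDAC2	0.47	2.9e-8
VDAC3	0.47	1.5e-4
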