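herv_id	baseMean	log2FC	FC	padj	P1	P2	P3	P4	P5	P6
herv_2953	1.42	3	7.99	6.14e-17	0	0	0	0	0	1
herv_4833	507.59	2.4	5.28	2.84e-128	1	1	0	0	0	1
herv_3232	144.11	2.01	4.02	2.33e-29	0	0	0	0	0	1
herv_4873	32.5	1.56	2.94	4.04e-25	0	0	1	1	1	1
herv_6069	677.18	1.31	2.48	3.27e-19	1	1	1	1	1	1
herv_2025	8.18	1.21	2.32	1.05e-11	1	1	1	1	1	1
herv_6079	35.73	1.16	2.23	2.28e-30	0	1	1	1	1	1
herv_2704	28.63	1.1	2.14	3.63e-16	1	1	1	1	1	1
herv_1741	24.46	0.93	1.9	1.70e-14	0	0	1	1	0	1
herv_3192	15.98	0.87	1.82	5.01e-22	1	1	0	1	0	1
herv_3288	24.52	0.83	1.78	1.92e-18	0	0	0	0	0	1
herv_2794	8.4	0.77	1.7	1.49e-13	0	0	0	0	1	0
herv_2288	32.98	0.71	1.64	1.79e-8	0	0	0	0	0	1
herv_2582	8.63	0.69	1.61	9.33e-9	1	1	1	1	1	1
herv_4679	157.18	0.69	1.61	9.88e-29	0	0	0	0	0	1
herv_2476	415.1	0.64	1.56	1.64e-16	0	0	0	0	0	1
herv_4695	30.94	0.6	1.51	4.43e-11	1	1	1	1	1	1
herv_3652	74.36	0.6	1.51	1.61e-13	1	1	1	0	1	1
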