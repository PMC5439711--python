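locus	n_global	m_global	h_global	n_low	n_high	m_low	m_high	h_low	h_high
Lo1-042	5.4	67.5	0.6	0	3	8	0	0	0
Lo1-080	3.0	95.5	0.0	0	2	2	0	0	0
Lo1-123	2.7	93.7	0.6	0	2	3	0	0	0
Lo1-193	1.2	87.7	0.0	0	1	6	0	0	0
Lo1-203	0.0	29.5	0.6	0	0	8	2	0	0
Lo1-225	0.3	82.5	0.3	0	1	5	0	0	0
Lo2-147	1.8	13.0	1.5	0	1	0	6	0	0
Lo2-170	16.9	82.5	0.0	0	1	2	0	0	0
Lo2-181	0.6	80.7	0.6	0	2	6	0	0	0
Lo2-184	1.5	68.7	0.6	0	1	2	2	0	0
Lo2-265	5.1	92.2	0.3	0	1	3	0	0	0
Lo2-292	24.7	25.6	2.1	2	10	1	7	0	0
Lo3-082	16.9	81.9	0.0	0	6	7	0	0	0
Lo3-096	70.2	28.3	1.2	7	2	1	8	0	0
Lo3-100	1.2	97.0	0.0	0	2	3	0	0	0
Lo3-165	14.5	84.3	0.3	0	6	6	0	0	0
Lo3-257	1.2	95.2	0.6	0	1	1	0	0	0
Lo3-300	91.6	7.2	0.3	4	0	0	4	0	0
Lo3-325	0.0	98.2	0.0	0	0	2	0	0	0
Lo3-343	48.8	15.7	6.6	4	6	0	7	0	0
Lo4-075	0.9	57.8	0.3	0	1	9	4	0	0
Lo4-091	0.6	92.5	0.6	0	1	2	0	0	0
Lo4-147	0.0	94.0	0.6	0	0	4	0	0	0
Lo4-235	0.3	74.4	0.0	0	1	6	0	0	0
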