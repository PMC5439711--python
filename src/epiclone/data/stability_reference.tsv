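locus	positional_CG	positional_CHG	seasonal_CG	seasonal_CHG
Lo1-042	92.7	96.9	66.7	58.3
Lo1-080	100	93.8	91.7	66.7
Lo1-123	100	100	75.0	58.3
Lo1-193	95.8	96.9	91.7	66.7
Lo1-203	100	100	100	91.7
Lo1-225	100	95.8	91.7	66.7
Lo2-147	93.9	100	83.3	91.7
Lo2-170	98.1	100	100	100
Lo2-181	98.1	96.9	100	100
Lo2-184	98.1	100	41.7	75.0
Lo2-265	86.6	90.6	75.0	83.3
Lo2-292	100	96.9	75.0	83.3
Lo3-082	86.5	100	83.3	100
Lo3-096	88.0	100	100	100
Lo3-100	83.7	78.1	100	100
Lo3-165	94.2	86.6	100	66.7
Lo3-257	100	90.6	100	83.3
Lo3-300	82.3	87.5	66.7	91.7
Lo3-325	100	88.5	66.7	83.3
Lo3-343	91.7	90.6	91.7	91.7
Lo4-075	90.6	100	100	91.7
Lo4-091	93.8	96.9	83.3	58.3
Lo4-147	90.6	91.7	83.3	83.3
Lo4-235	100	96.9	83.3	75.0
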