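# Poland road approximation: 18 vertices, 24 edges, lengths in ~100 km.
# The incidence is a synthetic best-effort transcription of the published
# map (figure-only); results depending on it are transcription-dependent.
# Row k is edge e{k}; vertices v1..v18 are labelled in generators.ROAD_LABELS.
# u	v	length
v7	v8	1.44
v1	v2	1.87
v2	v3	1.69
v3	v7	1.71
v5	v3	0.69
v6	v5	1.72
v6	v4	2.25
v8	v17	2.11
v8	v6	0.93
v1	v8	2.86
v2	v12	1.84
v6	v15	1.18
v9	v17	2.95
v15	v16	1.4
v3	v11	0.96
v3	v4	0.56
v4	v13	0.75
v4	v14	1.16
v8	v15	1.75
v18	v9	2.45
v18	v1	2.89
v2	v4	2.46
v4	v15	2.82
v1	v10	2.7
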