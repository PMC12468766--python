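# u	v
v1	v4
v2	v4
v3	v4
v4	v5
v5	v6
v6	v7
v6	v8
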