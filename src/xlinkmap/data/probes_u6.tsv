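phosphate_index	strand	promoter	psea_offset
2	template	U6	31
3	non_template	U6	31
4	template	U6	31
5	non_template	U6	31
7	non_template	U6	31
8	template	U6	31
10	template	U6	31
11	non_template	U6	31
12	template	U6	31
13	non_template	U6	31
14	template	U6	31
17	non_template	U6	31
19	non_template	U6	31
22	template	U6	31
24	template	U6	31
25	non_template	U6	31
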