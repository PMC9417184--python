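enzyme	state	kcat_c	K_c	S_co	K_o
wild-type	L6	15.7	172	22.0	92
R98A	L2	11.1	170	25.7	155
R131A	L2	12.3	198	24.9	198
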