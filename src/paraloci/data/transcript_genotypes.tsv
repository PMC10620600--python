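horse	c_pos	ref	transcript	CYP2D50-1	CYP2D50-2	CYP2D50-NCBI
1	111	C	C/A	C/A	C/C	C/A
1	582	C	C/T	C/T	C/C	C/T
1	867	G	G/T	G/T	A/A	G/T
1	1185	C	C/G	C/G	G/G	G/G
1	1198	C	C/A	C/A	A/A	A/A
1	1471	T	G/G	G/G	G/G	G/G
2	517	A	A/C	A/C	C/C	A/C
2	522	C	C/G	C/G	G/G	C/G
2	582	C	C/T	C/T	C/C	C/T
2	867	G	G/T	G/T	A/A	G/T
2	1471	T	T/G	T/G	T/T	T/T
3	111	C	C/A	C/A	C/C	C/A
3	582	C	T/T	T/T	C/C	T/T
3	867	G	T/T	T/T	A/A	T/T
3	1290	C	C/T	C/T	T/T	T/T
3	1471	T	G/G	G/G	G/G	G/G
4	111	C	C/A	C/A	C/C	C/A
4	582	C	C/T	C/T	C/C	C/T
4	867	G	G/T	G/T	A/A	G/T
4	1185	C	C/G	C/G	G/G	G/G
4	1198	C	C/A	C/A	A/A	A/A
4	1471	T	G/G	G/G	G/T	G/T
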