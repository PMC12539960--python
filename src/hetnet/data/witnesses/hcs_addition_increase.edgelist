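# Synthetic searched witness: uniform degree addition (c=1) can increase HCS.
# 12 nodes. Realizing the shifted degree sequence k_i + 1 as a different
# topology (the addition principle does not fix how new edges connect)
# yields spectral irregularity 0.27207 > 0.25986 before addition.
0 2
0 5
0 6
0 10
1 3
1 4
1 6
2 3
2 5
2 11
3 6
3 7
3 8
3 10
4 8
4 10
5 8
5 9
5 11
6 8
6 9
7 10
9 11
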