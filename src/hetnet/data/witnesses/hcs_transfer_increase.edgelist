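# Synthetic searched witness: transfer move increases HCS.
# 11 nodes; rewiring (2,1) to (2,0) raises the spectral radius faster than
# the (unchanged) mean degree: HCS 0.56581 -> 0.57030.
0 3
0 8
1 2
1 4
1 5
1 7
2 3
2 5
2 7
2 8
3 4
3 5
3 6
3 8
3 9
3 10
4 5
4 6
5 6
5 8
6 8
6 9
7 10
8 9
9 10
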