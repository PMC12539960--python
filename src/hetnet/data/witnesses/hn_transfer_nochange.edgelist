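# Synthetic searched witness: transfer move leaves HN unchanged.
# Degrees (4,2,2,1,1), mean 2. Rewiring the edge (0,4) to (0,2) moves the
# degree-4 node to 3 and a degree-2 node to 3; both deviations |k-mean|
# cross the mean symmetrically, so sum|k_i - mean| stays at 4.0.
# A no-change outcome violates the strict-decrease transfer requirement.
0 4
1 4
2 3
2 4
3 4
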