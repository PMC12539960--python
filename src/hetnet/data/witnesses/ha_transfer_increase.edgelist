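# Synthetic searched witness: transfer move increases HA (and HE).
# Degrees (1,3,3,3,4). Rewiring (1,2) to (1,0): the node losing the edge
# sits among high-degree neighbours while the gaining node is the leaf,
# so edge imbalances grow: HA 6.0 -> 8.0.
0 4
1 2
1 3
1 4
2 3
2 4
3 4
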