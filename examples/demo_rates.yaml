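# Ground-truth oxidation rate constants (min^-1) for the demo simulation.
# Ordered label-proximal first; positions are 1-based along the labeled
# strand counted from the labeled end.  The flank thymines (positions 3-7)
# decay in reactivity with distance from the R-loop edge; position 10 is the
# reference thymine shared by all substrates.
substrates:
  - substrate_id: rloop3_nts
    rates: [0.55, 0.40, 0.25, 0.12, 0.06, 0.25]
    positions: [3, 4, 5, 6, 7, 10]
    reference_index: 5
    quench_time: 2.0
  - substrate_id: bubble_ctrl
    rates: [0.70, 0.72, 0.68, 0.71, 0.69, 0.25]
    positions: [3, 4, 5, 6, 7, 10]
    reference_index: 5
    quench_time: 2.0
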