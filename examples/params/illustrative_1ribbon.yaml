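# Illustrative 1-ribbon parameter set (synthetic; not a published
# calibration).  Edge attraction drives aggregation; the two-star penalty
# caps monomer valence near 2, which is what makes chain-like (1-ribbon)
# aggregates the favored local structure.
phi_e: -2.0
phi_2s: 0.6
phi_NSP1: 0.0
phi_NSP2: 0.0
phi_ESP0: 0.0
phi_ESP1: -0.2
phi_C5: 0.0
phi_C6: 0.0
phi_C7: 0.0
T: 1.0
k_B: 1.0
A: 1.0
ref_measure: counting
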