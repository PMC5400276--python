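# Early STAT signaling coupled with the ternary IFN-receptor complex
# formation (closed).  Figure-transcribed reconstruction (see PROVENANCE.md):
# the ternary complex T plays the role of the activated receptor for the
# STAT module.  k29 is the association rate of IFN with receptor subunit R1
# (the ligand-receptor affinity parameter used for bifurcation diagrams).
k29: I + R1 -> IR1
k21: IR1 -> I + R1
k22: I + R2 -> IR2
k23: IR2 -> I + R2
k24: IR1 + R2 -> T
k25: T -> IR1 + R2
k26: IR2 + R1 -> T
k27: T -> IR2 + R1
k1: T + S2 -> TS2
k2: TS2 -> T + S2
k3: TS2 + S1 -> TS2S1
k4: TS2S1 -> TS2 + S1
k5: TS2S1 -> T + S1p + S2p
k6: S1p + S1 -> S1S1p
k7: S1S1p -> S1p + S1
k8: S1S1p -> 2 S1p
k9: 2 S1p -> D11
k10: D11 -> 2 S1p
k11: S1p + S2p -> D12
k12: D12 -> S1p + S2p
k13: P + S1p -> PS1p
k14: PS1p -> P + S1p
k15: PS1p -> P + S1
k16: S2p -> S2
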