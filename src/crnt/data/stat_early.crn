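# Early STAT signaling upon IFN stimulation (closed version).
# Figure-transcribed reconstruction (see PROVENANCE.md): the activated
# receptor complex Ra binds STAT2 and recruits STAT1; both STATs leave the
# complex phosphorylated.  Phosphorylated STAT1 trans-activates further
# STAT1 through a transient mixed dimer (the autocatalytic step), pSTAT1
# forms the S1-S1 homodimer D11 and, with pSTAT2, the S1-S2 heterodimer
# D12.  A phosphatase P deactivates pSTAT1 enzymatically; pSTAT2 relaxes
# first order.
k1: Ra + S2 -> RaS2
k2: RaS2 -> Ra + S2
k3: RaS2 + S1 -> RaS2S1
k4: RaS2S1 -> RaS2 + S1
k5: RaS2S1 -> Ra + S1p + S2p
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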