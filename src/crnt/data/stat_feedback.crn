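# STAT signaling with transcriptional STAT1 feedback via IRF1 and CBP
# (true-reaction subsystem; the packaged fixture is its semi-diffusive
# extension).  Figure-transcribed reconstruction (see PROVENANCE.md):
# the early STAT module plus GAS-driven IRF1 expression induced by the
# S1-S1 homodimer and STAT1 expression driven by the IRF1-CBP complex.
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
k17: D11 -> D11 + IRF1
k18: IRF1 + CBP -> IRF1CBP
k19: IRF1CBP -> IRF1 + CBP
k20: IRF1CBP -> IRF1CBP + S1
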