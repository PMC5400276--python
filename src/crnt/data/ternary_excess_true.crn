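# Ternary complex formation with IFN in excess: the (constant) interferon
# concentration is absorbed into the binding rate constants, so the binary
# complexes form pseudo-first-order from the free receptor subunits.
k1: R1 -> IR1
k2: IR1 -> R1
k3: R2 -> IR2
k4: IR2 -> R2
k5: IR1 + R2 -> T
k6: T -> IR1 + R2
k7: IR2 + R1 -> T
k8: T -> IR2 + R1
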