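# Ternary interferon-receptor complex formation (true reactions only).
# IFN (I) binds either receptor subunit (R1, R2); the binary complexes
# recruit the remaining subunit to form the ternary complex T.
k1: I + R1 -> IR1
k2: IR1 -> I + R1
k3: I + R2 -> IR2
k4: IR2 -> I + R2
k5: IR1 + R2 -> T
k6: T -> IR1 + R2
k7: IR2 + R1 -> T
k8: T -> IR2 + R1
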