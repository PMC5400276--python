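# Protein association/activation example, open version:
# A and B bind to form AB, which converts to its active form AB*;
# both A and B are constitutively expressed and degraded.
A + B -> AB
AB -> A + B
AB -> AB*
0 <-> A
0 <-> B
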