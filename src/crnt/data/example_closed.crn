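# Protein association/activation example, closed version (no exchange with
# the environment): A + B <-> AB -> AB*.
A + B -> AB
AB -> A + B
AB -> AB*
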