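# Signal transduction motif (closed): protein A is activated to A* by enzyme
# E1, deactivated by E2, and activates itself through the intermediate AA*.
# Rate labels use the complex-pair convention k<source><product> with the
# complexes numbered C1={AE1}, C2={A*E2}, C3={AA*}, C4={2A*}, C5={A+E1},
# C6={E1+A*}, C7={A+E2}, C8={E2+A*}, C9={A+A*}.
k51: A + E1 -> AE1
k15: AE1 -> A + E1
k16: AE1 -> E1 + A*
k82: E2 + A* -> A*E2
k28: A*E2 -> E2 + A*
k27: A*E2 -> A + E2
k93: A + A* -> AA*
k39: AA* -> A + A*
k34: AA* -> 2 A*
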