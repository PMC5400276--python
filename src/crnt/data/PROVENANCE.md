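# Fixture provenance

Fixtures marked `text` are fully determined by published in-text reaction
lists and matrix displays; their structural indices (N, R, M, l, s, lambda,
delta) are asserted against those statements in the test suite.

Fixtures marked `figure-transcribed` (`stat_early*`, `stat_feedback`,
`receptor_stat`) are reconstructions of networks whose exact complex/edge
sets are published only as figures that are not enumerable from text alone.
The reconstructions follow the accompanying narrative:

* STAT2 is activated through binding to the activated (ternary
  interferon-receptor) complex, with subsequent recruitment and activation
  of STAT1;
* phosphorylated STATs dissociate from the activating complex and form
  STAT1-STAT1 homodimers and STAT1-STAT2 heterodimers;
* the STAT1-STAT2 heterodimer can recruit and trans-activate additional
  STAT1 (the documented pSTAT2-mediated STAT1 activation step; this step
  carries the positive feedback that the reconstruction needs to host the
  reported bistability);
* the feedback variant adds GAS-driven IRF1 expression induced by the
  STAT1 homodimer and STAT1 expression driven by the IRF1-CBP complex;
* semi-diffusive variants add degradation of all species and basal
  formation of one key species per conserved moiety of the true subsystem
  (the free forms: STAT1/STAT2 and the receptor input; CBP in the feedback
  variant).

Tests on these fixtures assert internal consistency and qualitative search
outcomes (saddle-node found / not found, fold structure, hysteresis), never
structural numbers absent from the text.  The edge lists live in the .crn
files in this directory so they can be corrected against the original
figures without code changes.
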