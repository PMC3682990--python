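glucose_mM,insulin_pM,provenance
5,57.0,Observed peripheral insulin at 5 mM glucose (Polonsky et al. 1988)
7,167.4,Observed peripheral insulin at 7 mM glucose (Polonsky et al. 1988)
16.5,567.4,Observed peripheral insulin at hyperglycemic clamp 16.5 mM (Polonsky et al. 1988)
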