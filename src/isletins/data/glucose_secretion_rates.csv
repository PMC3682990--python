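glucose_mM,rate_pM_per_min,provenance
3,1,Anchor point estimated on the curve and added for fitting
4,10,Anchor point estimated on the curve and added for fitting
5,16,Overnight fast (Polonsky et al. 1988); glucose 4-6 mM after overnight fast; 5 mM assumed
7,33,24-h mixed diet (Polonsky et al. 1988); 7 mM assumed
9,47,Jones et al.
16.5,102,Hyperglycemic clamp at 16.5 mM (Polonsky et al. 1988)
25,103,Anchor point estimated on the curve and added for fitting
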