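receptor,wt_pec50,wt_se,f18a_pec50,f18a_se,pec50_sig,delta_pec50_printed,emax_pct,emax_se,emax_sig,n
AM1,8.89,0.13,7.85,0.11,3,1.04,40.3,9.73,3,4
AM2,8.91,0.24,7.42,0.24,1,1.49,101.7,5.26,0,3
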