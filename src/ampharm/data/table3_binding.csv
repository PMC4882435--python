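construct,receptor,pic50,pic50_se,max_specific_pct,max_specific_se,ci_excludes_100,n
WT,AM1,8.56,0.04,,,0,4
WT,AM2,8.64,0.07,,,0,4
C212A,AM1,8.06,0.16,71.7,20.7,0,3
C212A,AM2,8.35,0.18,145.5,23.4,0,3
Y277A,AM1,8.46,0.35,34.3,11.1,1,3
Y277A,AM2,8.52,0.15,97.4,21.6,0,3
C282A,AM1,8.40,0.15,85.4,24.9,0,3
C282A,AM2,8.31,0.29,180.4,46.6,0,3
I352A,AM1,8.56,0.10,43.5,7.0,1,3
I352A,AM2,8.65,0.21,42.2,13.2,1,3
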