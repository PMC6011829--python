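reaction,dg,dh,minus_tds
non-catalyzed forward,16.89,0.86,16.03
non-catalyzed reverse,48.06,48.66,-0.60
forward beta-CD set 1,22.75,21.29,1.47
reverse beta-CD set 1,47.83,49.44,-1.61
forward beta-CD set 2,24.12,21.14,2.98
reverse beta-CD set 2,48.67,49.92,-1.25
forward dimethyl-beta-CD set 1,13.73,10.05,3.68
reverse dimethyl-beta-CD set 1,48.51,51.50,-2.99
forward dimethyl-beta-CD set 2,19.68,20.18,-0.50
reverse dimethyl-beta-CD set 2,49.48,51.25,-1.77
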