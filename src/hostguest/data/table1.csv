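complex,dg,de_valence,de_coulomb,de_pb,de_np,de_vdw,dh,minus_tds
beta-CD and 1,-2.71,1.96,-8.04,15.69,-2.86,-25.27,-18.52,15.81
dimethyl-beta-CD and 1,-4.09,3.01,-8.50,14.84,-2.91,-26.06,-19.62,15.53
beta-CD and 2a,-6.58,0.39,-5.98,13.23,-2.76,-25.12,-20.23,13.65
dimethyl-beta-CD and 2a,-6.17,2.57,-11.25,15.28,-2.76,-25.22,-21.39,15.21
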