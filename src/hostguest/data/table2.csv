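complex,de_coulomb,de_pb,de_np,de_vdw,dh_mmpbsa
beta-CD with 2a,-7.24,17.23,-2.19,-23.07,-15.27
dimethyl-beta-CD with 2a,-3.38,13.35,-2.18,-24.51,-16.72
beta-CD with 1 and 2a,-16.00,27.79,-2.66,-25.88,-16.75
dimethyl-beta-CD with 1 and 2a,-5.51,19.17,-2.96,-31.09,-20.39
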