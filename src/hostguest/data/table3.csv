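catalyst,metric,md_mean,md_sd,vm2_mean,vm2_sd
beta-CD,d1,1.44,0.70,0.38,0.11
beta-CD,d2,-0.03,0.87,-1.39,0.15
beta-CD,d3,3.35,0.68,2.14,0.11
dimethyl-beta-CD,d1,2.05,0.73,1.42,0.13
dimethyl-beta-CD,d2,0.67,0.87,-0.10,0.17
dimethyl-beta-CD,d3,3.95,0.70,3.37,0.12
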