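condition,group,G0_MPa,Ginf_MPa,beta_per_s
healthy,ECM,24.98,18.81,500
healthy,beam,35.2,20.51,585
glaucoma,ECM,8.15,4.45,510
glaucoma,beam,45.88,19.58,610
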