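condition,group,G0_MPa,Ginf_MPa,beta_per_s
healthy,ECM,21.19,15.98,109
healthy,beam,36.19,19.58,450
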