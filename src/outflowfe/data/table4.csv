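model_id,condition,flow,group,G0_MPa,Ginf_MPa,beta_per_s
125HF,glaucoma,HF,TM,12.51,5.15,109
125HF,glaucoma,HF,JCT,4.18,2.2,109
125HF,glaucoma,HF,SC_wall,6.28,3.18,109
125HF,glaucoma,HF,TM_beam,205.54,109.41,450
125HF,glaucoma,HF,JCT_beam,132.12,55.39,450
125LF,glaucoma,LF,TM,16.11,7.15,109
125LF,glaucoma,LF,JCT,9.05,3.05,109
125LF,glaucoma,LF,SC_wall,12.59,4.16,109
125LF,glaucoma,LF,TM_beam,255.15,152.28,450
125LF,glaucoma,LF,JCT_beam,129.69,85.98,450
126HF,glaucoma,HF,TM,15.14,6.58,109
126HF,glaucoma,HF,JCT,4.52,2.05,109
126HF,glaucoma,HF,SC_wall,6.38,3.88,109
126HF,glaucoma,HF,TM_beam,198.25,98.14,450
126HF,glaucoma,HF,JCT_beam,145.69,68.15,450
126LF,glaucoma,LF,TM,18.88,7.19,109
126LF,glaucoma,LF,JCT,5.18,3.38,109
126LF,glaucoma,LF,SC_wall,7.22,4.97,109
126LF,glaucoma,LF,TM_beam,215.44,113.34,450
126LF,glaucoma,LF,JCT_beam,145.65,75.95,450
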