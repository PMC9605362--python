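model_id,condition,flow,group,G0_MPa,Ginf_MPa,beta_per_s
115HF,healthy,HF,TM,3.85,3.18,109
115HF,healthy,HF,JCT,1.15,1,109
115HF,healthy,HF,SC_wall,2.55,1.12,109
115HF,healthy,HF,TM_beam,92.20,58.51,450
115HF,healthy,HF,JCT_beam,65.20,32.51,450
115LF,healthy,LF,TM,5.10,4.75,109
115LF,healthy,LF,JCT,3.15,1.49,109
115LF,healthy,LF,SC_wall,4.55,2.12,109
115LF,healthy,LF,TM_beam,95.26,70.59,450
115LF,healthy,LF,JCT_beam,75.20,39.51,450
116HF,healthy,HF,TM,3.05,2.26,109
116HF,healthy,HF,JCT,1.02,0.93,109
116HF,healthy,HF,SC_wall,2.14,1.95,109
116HF,healthy,HF,TM_beam,85.14,50.15,450
116HF,healthy,HF,JCT_beam,70.16,40.25,450
116LF,healthy,LF,TM,4.02,2.95,109
116LF,healthy,LF,JCT,2.35,1.55,109
116LF,healthy,LF,SC_wall,3.12,2.08,109
116LF,healthy,LF,TM_beam,90.54,55.15,450
116LF,healthy,LF,JCT_beam,75.75,45.19,450
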