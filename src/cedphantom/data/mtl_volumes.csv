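trial_id,group,region,time_min,infused_uL,measured_uL
MTL1-left,nhp,mtl,1200.0,15.0,221.1
MTL1-right,nhp,mtl,1200.0,15.0,212.2
MTL2-left,nhp,mtl,1200.0,20.0,285.3
MTL3-right,nhp,mtl,1200.0,20.0,204.7
gel1,agar,mtl,36.0,15.0,196.7
gel2,agar,mtl,36.0,15.0,229.2
gel3,agar,mtl,36.0,15.0,260.2
gel4,agar,mtl,36.0,15.0,220.7
gel5,agar,mtl,36.0,15.0,207.0
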