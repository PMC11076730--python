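variable,group,n,mean,sd
height_cm,is,929,156.53,14.45
height_cm,normal,83222,156.84,14.95
sitting_height_cm,is,929,82.48,7.78
sitting_height_cm,normal,83222,83.23,7.57
weight_kg,is,929,46.69,10.91
weight_kg,normal,83222,47.35,10.33
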