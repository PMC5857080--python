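name,units,center,step,clamp_floor
pH,,7.25,0.75,
temperature,degC,20.0,10.0,
diesel,% v/v,2.5,1.5,0.0
NaCl,% w/v,1.0,1.0,0.0
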