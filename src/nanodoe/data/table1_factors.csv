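name,low,center,high,units
lecithin_mg,100,150,200,mg
chitosan_mg,10,25,40,mg
ipm_pct,1,2,3,% w/v
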